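import numpy as np
import pytest

from codonscan import (
    CodingSequence,
    SimulationSpec,
    SiteClassSpec,
    parse_newick,
    simulate_alignment,
)

#: 4-taxon study tree: Caenorhabditis-like divergence (total ~1.1 subs/codon)
FOUR_TAXON_NEWICK = "(a:0.25,b:0.25,(c:0.25,d:0.25):0.1);"


@pytest.fixture
def four_taxon_tree():
    return parse_newick(FOUR_TAXON_NEWICK)


@pytest.fixture
def two_taxon_tree():
    return parse_newick("(a:0.3,b:0.3);")


def simulate_m0(tree, n_codons, omega, kappa=2.0, seed=0):
    spec = SimulationSpec(
        tree=tree,
        n_codons=n_codons,
        kappa=kappa,
        site_classes=SiteClassSpec.m0(omega),
        pi="uniform",
        seed=seed,
    )
    return simulate_alignment(spec)


def make_cds_family(rng: np.random.Generator, n_seqs=3, n_codons=30, with_indels=True):
    """Random homologous CDS set: simulated on a star-ish tree, then codon
    blocks deleted from random sequences so alignments need gaps."""
    labels = [f"s{i}" for i in range(n_seqs)]
    newick = "(" + ",".join(f"{lab}:0.15" for lab in labels) + ");"
    aln, _ = simulate_m0(parse_newick(newick), n_codons, omega=0.5, seed=int(rng.integers(2**31)))
    cds_set = []
    for name, row in aln.rows:
        codons = [row[i : i + 3] for i in range(0, len(row), 3)]
        if with_indels and rng.random() < 0.8:
            for _ in range(rng.integers(1, 3)):
                if len(codons) <= 5:
                    break
                start = int(rng.integers(0, len(codons) - 3))
                width = int(rng.integers(1, 4))
                del codons[start : start + width]
        cds_set.append(CodingSequence(name, "".join(codons)))
    return cds_set
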