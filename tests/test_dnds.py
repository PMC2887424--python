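import math

import numpy as np
import pytest

from codonscan import (
    f3x4_frequencies,
    ng86_diffs,
    ng86_sites,
    pairwise_dnds,
    yn00_kappa,
)
from codonscan.dnds import DEFAULT_KAPPA, _pathway_diffs, jukes_cantor
from codonscan.seqio import STANDARD_CODE

from .conftest import simulate_m0
from .oracles import ng86_diffs_oracle, ng86_sites_oracle


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,s",
        [("TTT", 1 / 3), ("ATG", 0.0), ("TGG", 0.0), ("GGG", 1.0), ("CTA", 4 / 3)],
    )
    def test_known_site_fractions(self, codon, s):
        count = ng86_sites(codon)
        assert count.s == pytest.approx(s)
        assert count.n == pytest.approx(3 - s)

    def test_all_sense_codons_sum_to_three_and_match_oracle(self):
        for codon in STANDARD_CODE.sense_codons:
            count = ng86_sites(codon)
            assert count.s + count.n == pytest.approx(3.0)
            s_ref, n_ref = ng86_sites_oracle(codon)
            assert count.s == pytest.approx(s_ref)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestPathwayCounts:
    @pytest.mark.parametrize(
        "c1,c2,sd,nd",
        [
            ("TTT", "TTT", 0.0, 0.0),
            ("TTT", "TTA", 0.0, 1.0),  # Phe -> Leu, one nonsynonymous step
            ("TTT", "GTA", 0.5, 1.5),  # two pathways, one passing through Val
        ],
    )
    def test_known_pathway_averages(self, c1, c2, sd, nd):
        assert ng86_diffs(c1, c2) == pytest.approx((sd, nd))

    def test_matches_enumeration_oracle_on_sample(self):
        rng = np.random.default_rng(0)
        codons = STANDARD_CODE.sense_codons
        for _ in range(200):
            c1, c2 = rng.choice(codons, size=2)
            assert ng86_diffs(c1, c2) == pytest.approx(ng86_diffs_oracle(c1, c2), abs=1e-12)

    def test_sd_nd_sum_to_diff_count_when_pathway_exists(self):
        rng = np.random.default_rng(1)
        codons = STANDARD_CODE.sense_codons
        for _ in range(100):
            c1, c2 = rng.choice(codons, size=2)
            sd, nd = ng86_diffs(c1, c2)
            k = sum(1 for a, b in zip(c1, c2) if a != b)
            _, _, degenerate = _pathway_diffs(c1, c2, STANDARD_CODE, None, None)
            if not degenerate:
                assert sd + nd == pytest.approx(k)


class TestPairwise:
    def test_identical_rows_have_undefined_omega(self):
        res = pairwise_dnds("ATGAAATGT", "ATGAAATGT")
        assert res.Sd == res.Nd == 0.0
        assert res.dS == res.dN == 0.0
        assert math.isnan(res.omega)
        assert "omega_undefined" in res.flags

    def test_saturated_ps_gives_undefined_ds(self):
        # GGA vs GGC: one synonymous difference over one synonymous site -> pS = 1
        res = pairwise_dnds("GGA", "GGC")
        assert res.pS >= 0.75
        assert math.isnan(res.dS)
        assert "dS_undefined" in res.flags
        assert math.isnan(res.omega)

    def test_zero_ds_with_nonsyn_changes_is_infinite(self):
        res = pairwise_dnds("ATGATG", "ACGACG")
        assert res.dS == 0.0 and res.dN > 0.0
        assert math.isinf(res.omega)
        assert "omega_infinite" in res.flags

    def test_gapped_columns_are_excluded(self):
        res = pairwise_dnds("ATG---TGT", "ATGAAATGT")
        assert res.ncodons_used == 2

    def test_zero_comparable_codons_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_dnds("---", "ATG")

    @pytest.mark.parametrize("method", ["NG86", "YN00"])
    def test_symmetry(self, method, two_taxon_tree):
        aln, _ = simulate_m0(two_taxon_tree, 40, omega=0.5, seed=3)
        (a, ra), (b, rb) = aln.rows
        fwd = pairwise_dnds(ra, rb, method=method)
        rev = pairwise_dnds(rb, ra, method=method)
        for fieldname in ("S", "N", "Sd", "Nd", "pS", "pN", "dS", "dN"):
            assert getattr(fwd, fieldname) == pytest.approx(getattr(rev, fieldname))

    def test_counts_are_additive_over_codon_columns(self, two_taxon_tree):
        aln, _ = simulate_m0(two_taxon_tree, 30, omega=0.5, seed=4)
        ra, rb = aln.rows[0][1], aln.rows[1][1]
        whole = pairwise_dnds(ra, rb)
        parts = [
            pairwise_dnds(ra[i : i + 3], rb[i : i + 3]) for i in range(0, len(ra), 3)
        ]
        assert whole.Sd == pytest.approx(sum(p.Sd for p in parts))
        assert whole.Nd == pytest.approx(sum(p.Nd for p in parts))
        assert whole.S == pytest.approx(sum(p.S for p in parts))

    def test_mean_omega_orders_with_generating_omega(self, two_taxon_tree):
        means = []
        for omega_true in (0.1, 1.0, 3.0):
            vals = []
            for seed in range(5):
                aln, _ = simulate_m0(two_taxon_tree, 200, omega=omega_true, seed=50 + seed)
                res = pairwise_dnds(aln.rows[0][1], aln.rows[1][1])
                if math.isfinite(res.omega):
                    vals.append(res.omega)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestJukesCantor:
    def test_domain(self):
        assert jukes_cantor(0.0) == 0.0
        assert math.isnan(jukes_cantor(0.75))
        assert jukes_cantor(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))


class TestYn00:
    def test_identical_sequences_fall_back_to_default(self, caplog):
        with caplog.at_level("WARNING", logger="codonscan"):
            kappa = yn00_kappa("ATGAAATGT", "ATGAAATGT")
        assert kappa == DEFAULT_KAPPA
        assert "default kappa" in caplog.text

    def test_transversion_only_mismatches_drive_kappa_to_zero(self):
        # fourfold site transversions (GGA vs GGC) against a conserved backdrop
        s1 = "GGA" * 5 + "GGG" * 45
        s2 = "GGC" * 5 + "GGG" * 45
        assert yn00_kappa(s1, s2) < 0.25

    def test_kappa_recovery_from_simulation(self):
        from codonscan import SimulationSpec, SiteClassSpec, parse_newick, simulate_alignment

        spec = SimulationSpec(
            tree=parse_newick("(a:0.2,b:0.2);"),
            n_codons=3000,
            kappa=4.0,
            site_classes=SiteClassSpec.m0(0.3),
            pi="uniform",
            seed=11,
        )
        aln, _ = simulate_alignment(spec)
        est = yn00_kappa(aln.rows[0][1], aln.rows[1][1])
        assert est == pytest.approx(4.0, rel=0.25)

    def test_yn00_result_carries_kappa_and_weighted_counts(self, two_taxon_tree):
        aln, _ = simulate_m0(two_taxon_tree, 150, omega=0.3, kappa=3.0, seed=9)
        res = pairwise_dnds(aln.rows[0][1], aln.rows[1][1], method="YN00")
        assert res.method == "YN00"
        assert res.kappa is not None and res.kappa > 0
        assert res.S + res.N == pytest.approx(3 * res.ncodons_used)
        assert 0 <= res.omega < 1.5


class TestF3x4:
    def test_frequencies_sum_to_one_and_reflect_composition(self):
        rows = ["GGGGGGGGG", "GGGGGGGGG"]  # heavily G-biased
        pi = f3x4_frequencies(rows)
        assert sum(pi.values()) == pytest.approx(1.0)
        assert pi["GGG"] == max(pi.values())
        assert min(pi.values()) > 0
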