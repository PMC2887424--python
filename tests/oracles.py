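"""Independent brute-force oracles used to validate the fast implementations.

Each oracle deliberately avoids the code path it checks: alignment scoring by
exhaustive enumeration of global alignments, NG86 counting via Biopython
translation and naive permutation loops, and tree likelihoods by explicit
summation over all internal-node state assignments with scipy's generic
matrix exponential.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np
from Bio.Seq import Seq
from scipy.linalg import expm

NUC = "ACGT"


# ---------------------------------------------------------------------------
# Global alignment enumeration
# ---------------------------------------------------------------------------


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (gapped_a, gapped_b)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def score_alignment(ga: str, gb: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Affine score: a gap run of length L costs gap_open + (L-1)*gap_extend."""
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for x, y in zip(ga, gb):
        if x == "-":
            score += gap_extend if prev_gap_a else gap_open
            prev_gap_a, prev_gap_b = True, False
        elif y == "-":
            score += gap_extend if prev_gap_b else gap_open
            prev_gap_b, prev_gap_a = True, False
        else:
            score += matrix[x, y]
            prev_gap_a = prev_gap_b = False
    return score


def best_alignment_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    return max(
        score_alignment(ga, gb, matrix, gap_open, gap_extend)
        for ga, gb in enumerate_alignments(a, b)
    )


# ---------------------------------------------------------------------------
# NG86 counting oracle (Biopython translation, naive loops)
# ---------------------------------------------------------------------------


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in NUC:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if _aa(mut) == "*":
                continue
            valid += 1
            if _aa(mut) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def ng86_diffs_oracle(c1: str, c2: str) -> tuple[float, float]:
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return 0.0, float(len(diffs))
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


# ---------------------------------------------------------------------------
# Likelihood by explicit enumeration over internal states
# ---------------------------------------------------------------------------


def brute_force_log_likelihood(tree, aln, probs, omegas, kappa, pi, Qs) -> float:
    """Mixture lnL by summing over every internal-node state assignment.

    ``Qs`` are the (already jointly scaled) per-class generators; transition
    matrices come from scipy.linalg.expm, independent of the spectral path.
    Alignment must be gapless.
    """
    from codonscan.site_models import _CodeTables
    from codonscan.seqio import STANDARD_CODE

    tables = _CodeTables.get(STANDARD_CODE)
    nstates = len(tables.codons)
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    root = tree.root
    rows = dict(aln.rows)
    leaf_states = {
        id(n): [tables.index[rows[n.name][k : k + 3]] for k in range(0, len(rows[n.name]), 3)]
        for n in nodes
        if n.is_leaf
    }
    n_sites = aln.ncodons

    mix = np.zeros(n_sites)
    for k, Q in enumerate(Qs):
        P = {
            id(node): expm(Q * max(node.length or 0.0, 0.0))
            for node in nodes
            if node is not root
        }
        for site in range(n_sites):
            lik = 0.0
            for assignment in product(range(nstates), repeat=len(internals)):
                state_of = {id(n): s for n, s in zip(internals, assignment)}
                for leaf_id, states in leaf_states.items():
                    state_of[leaf_id] = states[site]
                prob = pi[state_of[id(root)]]
                for node in nodes:
                    if node is root:
                        continue
                    prob *= P[id(node)][state_of[id(node.parent)], state_of[id(node)]]
                lik += prob
            mix[site] += probs[k] * lik
    return float(np.log(mix).sum())
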