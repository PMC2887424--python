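"""Pairwise dN/dS estimation by counting methods.

Two estimators are provided on codon-delimited sequence pairs:

* NG86 — Nei-Gojobori pathway counting: each codon contributes synonymous and
  nonsynonymous site fractions (s + n = 3), differences between codons are
  averaged over all orderings of single-nucleotide steps, and proportions are
  corrected for multiple hits with the Jukes-Cantor formula
  d = -(3/4) ln(1 - 4p/3).
* YN00 — an approximate method in the style of Yang & Nielsen (2000): the
  transition/transversion ratio kappa is first estimated from
  fourfold-degenerate and nondegenerate sites with a K80 correction, then
  sites and mutation pathways are weighted by kappa and F3x4 codon
  frequencies before applying the same correction form.

omega = dN/dS can be genuinely undefined (dS = 0 with dN = 0, or the
correction out of domain) or infinite (dS = 0 with dN > 0); the two cases are
kept distinct and never silently collapsed to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .seqio import GAP_CODON, GeneticCode, NUCLEOTIDES, STANDARD_CODE

logger = logging.getLogger("codonscan")

DEFAULT_KAPPA = 2.0

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


@dataclass(frozen=True)
class SiteCount:
    """Synonymous / nonsynonymous site fractions of one codon (s + n = 3)."""

    s: float
    n: float


@dataclass
class PairwiseDnDsResult:
    """Counting-method summary for one sequence pair (or one window of it)."""

    pair: tuple[str, str]
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    kappa: float | None
    ncodons_used: int
    flags: tuple[str, ...] = ()

    @property
    def omega_defined(self) -> bool:
        return math.isfinite(self.omega)


# ---------------------------------------------------------------------------
# NG86 building blocks
# ---------------------------------------------------------------------------


def _single_mutants(codon: str, pos: int) -> list[str]:
    return [codon[:pos] + nt + codon[pos + 1 :] for nt in NUCLEOTIDES if nt != codon[pos]]


def ng86_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> SiteCount:
    """NG86 synonymous/nonsynonymous site fractions of a sense codon.

    Per position, the synonymous fraction is the share of single-nucleotide
    changes that are synonymous, among changes that do not create a stop
    codon (stop-bound mutations are excluded and the fraction renormalized).
    """
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = code.translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for mut in _single_mutants(codon, pos):
            if code.is_stop(mut):
                continue
            valid += 1
            if code.translate_codon(mut) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return SiteCount(s=s, n=3.0 - s)


def _weighted_sites(
    codon: str, code: GeneticCode, kappa: float, pi: dict[str, float]
) -> SiteCount:
    """Sites weighted by transition bias and target-codon frequency (YN00 flavor)."""
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = code.translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn_w = total_w = 0.0
        for mut in _single_mutants(codon, pos):
            if code.is_stop(mut):
                continue
            w = (kappa if is_transition(codon[pos], mut[pos]) else 1.0) * pi.get(mut, 0.0)
            total_w += w
            if code.translate_codon(mut) == aa:
                syn_w += w
        if total_w > 0:
            s += syn_w / total_w
    return SiteCount(s=s, n=3.0 - s)


def ng86_diffs(
    c1: str, c2: str, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    For k differing positions, all k! orderings of single-nucleotide steps are
    averaged; orderings passing through a stop codon are excluded. If every
    ordering hits a stop (degenerate case) all k differences are counted as
    nonsynonymous and a warning is logged.
    """
    sd, nd, _ = _pathway_diffs(c1, c2, code, kappa=None, pi=None)
    return sd, nd


def _pathway_diffs(
    c1: str,
    c2: str,
    code: GeneticCode,
    kappa: float | None,
    pi: dict[str, float] | None,
) -> tuple[float, float, bool]:
    """Pathway averaging; optional (kappa, pi) weights each pathway by its rate.

    Returns (sd, nd, degenerate). Unweighted (kappa=None) is plain NG86.
    """
    if code.is_stop(c1) or code.is_stop(c2):
        raise ValueError(f"stop codon in pair ({c1}, {c2})")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0, False
    total_w = 0.0
    sd_acc = nd_acc = 0.0
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        weight = 1.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if kappa is not None:
                w = kappa if is_transition(cur[pos], c2[pos]) else 1.0
                weight *= w * (pi.get(nxt, 1.0) if pi else 1.0)
            if code.translate_codon(nxt) == code.translate_codon(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if not ok:
            continue
        total_w += weight
        sd_acc += weight * sd
        nd_acc += weight * nd
    if total_w == 0.0:
        logger.warning(
            "all mutation pathways between %s and %s pass through stops; "
            "counting %d differences as nonsynonymous",
            c1,
            c2,
            k,
        )
        return 0.0, float(k), True
    return sd_acc / total_w, nd_acc / total_w, False


def jukes_cantor(p: float) -> float:
    """JC multiple-hit correction; NaN when out of domain (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p == 0.0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan
    return -0.75 * math.log(arg)


# ---------------------------------------------------------------------------
# Codon frequencies (F3x4)
# ---------------------------------------------------------------------------


def f3x4_frequencies(
    rows, code: GeneticCode = STANDARD_CODE, floor: float = 1e-4
) -> dict[str, float]:
    """F3x4 sense-codon equilibrium frequencies from gapped codon rows.

    Nucleotide frequencies are tallied separately at the three codon
    positions (gap codons skipped), floored at ``floor`` so no codon gets
    exactly zero weight, multiplied per codon, zeroed for stops and
    renormalized over the 61 sense codons.
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in rows]
    counts = np.zeros((3, 4))
    idx = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    for seq in seqs:
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == GAP_CODON:
                continue
            for pos in range(3):
                counts[pos, idx[codon[pos]]] += 1
    freqs = np.maximum(counts, 0.0)
    freqs = freqs / np.maximum(freqs.sum(axis=1, keepdims=True), 1.0)
    freqs = np.maximum(freqs, floor)
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = {}
    for codon in code.sense_codons:
        pi[codon] = freqs[0, idx[codon[0]]] * freqs[1, idx[codon[1]]] * freqs[2, idx[codon[2]]]
    total = sum(pi.values())
    return {c: v / total for c, v in pi.items()}


# ---------------------------------------------------------------------------
# kappa estimation (YN00 stage)
# ---------------------------------------------------------------------------


def _position_degeneracy(codon: str, pos: int, code: GeneticCode) -> int:
    """Number of synonymous single-nucleotide changes at a codon position (0..3)."""
    aa = code.translate_codon(codon)
    return sum(
        1
        for mut in _single_mutants(codon, pos)
        if not code.is_stop(mut) and code.translate_codon(mut) == aa
    )


def _k80_kappa(P: float, Q: float) -> float | None:
    """K80 transition/transversion rate ratio from proportions P (ts), Q (tv)."""
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        return None
    alpha = -0.5 * math.log(a1) + 0.25 * math.log(a2)
    beta = -0.25 * math.log(a2)
    if beta <= 0.0:
        return None
    return max(alpha / beta, 0.0)


def yn00_kappa(
    s1: str, s2: str, code: GeneticCode = STANDARD_CODE, default: float = DEFAULT_KAPPA
) -> float:
    """Estimate kappa from fourfold-degenerate and nondegenerate sites.

    Sites where the position is fourfold-degenerate (or nondegenerate) in the
    codons of *both* sequences are pooled; a K80 correction gives a kappa
    estimate per class, combined by site-count weighting. Falls back to
    ``default`` (with a warning) when the data carry no usable signal.
    """
    tallies = {4: [0, 0, 0], 0: [0, 0, 0]}  # class -> [sites, transitions, transversions]
    for i in range(0, min(len(s1), len(s2)) - 2, 3):
        ca, cb = s1[i : i + 3], s2[i : i + 3]
        if ca == GAP_CODON or cb == GAP_CODON:
            continue
        for pos in range(3):
            da = _position_degeneracy(ca, pos, code)
            db = _position_degeneracy(cb, pos, code)
            for cls in (4, 0):
                want = 3 if cls == 4 else 0
                if da == want and db == want:
                    tallies[cls][0] += 1
                    if ca[pos] != cb[pos]:
                        if is_transition(ca[pos], cb[pos]):
                            tallies[cls][1] += 1
                        else:
                            tallies[cls][2] += 1
    estimates = []
    for cls, (L, ts, tv) in tallies.items():
        if L == 0 or (ts == 0 and tv == 0):
            continue
        k = _k80_kappa(ts / L, tv / L)
        if k is not None:
            estimates.append((L, k))
    if not estimates:
        logger.warning("no usable sites for kappa estimation; using default kappa=%s", default)
        return default
    total = sum(L for L, _ in estimates)
    return sum(L * k for L, k in estimates) / total


# ---------------------------------------------------------------------------
# Pairwise dN/dS
# ---------------------------------------------------------------------------


def _comparable_codons(
    s1: str, s2: str, code: GeneticCode
) -> list[tuple[str, str]]:
    if len(s1) != len(s2):
        raise ValueError("rows must have equal length")
    if len(s1) % 3:
        raise ValueError("rows must be codon-delimited (length multiple of 3)")
    out = []
    for i in range(0, len(s1), 3):
        ca, cb = s1[i : i + 3], s2[i : i + 3]
        if ca == GAP_CODON or cb == GAP_CODON:
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            raise ValueError(f"stop codon at alignment codon {i // 3 + 1}")
        out.append((ca, cb))
    return out


def pairwise_dnds(
    s1: str,
    s2: str,
    method: str = "NG86",
    code: GeneticCode = STANDARD_CODE,
    pair: tuple[str, str] = ("seq1", "seq2"),
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PairwiseDnDsResult:
    """Pairwise dN/dS between two gapped codon rows of one alignment.

    Codon columns gapped in either row are excluded (pairwise deletion).
    ``method='NG86'`` uses unweighted counting; ``'YN00'`` estimates kappa,
    weights sites and pathways by kappa and F3x4 frequencies, and iterates
    the weighted counts to a fixed point.
    """
    method = method.upper()
    if method not in ("NG86", "YN00"):
        raise ValueError(f"unknown method {method!r}")
    codons = _comparable_codons(s1, s2, code)
    if not codons:
        raise ValueError("zero comparable codons between the two rows")

    flags: list[str] = []
    kappa: float | None = None
    if method == "NG86":
        S, N, Sd, Nd = _count_pair(codons, code, kappa=None, pi=None)
    else:
        kappa = yn00_kappa(s1, s2, code)
        pi = f3x4_frequencies([s1, s2], code)
        prev = (math.inf, math.inf)
        for _ in range(max_iter):
            S, N, Sd, Nd = _count_pair(codons, code, kappa=kappa, pi=pi)
            pS_it = Sd / S if S > 0 else 0.0
            pN_it = Nd / N if N > 0 else 0.0
            cur = (jukes_cantor(pS_it), jukes_cantor(pN_it))
            if all(
                (math.isnan(a) and math.isnan(b)) or abs(a - b) < tol
                for a, b in zip(cur, prev)
            ):
                break
            prev = cur

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    if math.isnan(dS):
        flags.append("dS_undefined")
    if math.isnan(dN):
        flags.append("dN_undefined")

    if math.isnan(dS) or math.isnan(dN):
        omega = math.nan
        flags.append("omega_undefined")
    elif dS == 0.0 and dN == 0.0:
        omega = math.nan
        flags.append("omega_undefined")
    elif dS == 0.0:
        omega = math.inf
        flags.append("omega_infinite")
    else:
        omega = dN / dS

    return PairwiseDnDsResult(
        pair=pair,
        method=method,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        kappa=kappa,
        ncodons_used=len(codons),
        flags=tuple(flags),
    )


def _count_pair(
    codons: list[tuple[str, str]],
    code: GeneticCode,
    kappa: float | None,
    pi: dict[str, float] | None,
) -> tuple[float, float, float, float]:
    S = N = Sd = Nd = 0.0
    for ca, cb in codons:
        if kappa is None:
            site_a, site_b = ng86_sites(ca, code), ng86_sites(cb, code)
        else:
            site_a = _weighted_sites(ca, code, kappa, pi)
            site_b = _weighted_sites(cb, code, kappa, pi)
        S += 0.5 * (site_a.s + site_b.s)
        N += 0.5 * (site_a.n + site_b.n)
        sd, nd, _ = _pathway_diffs(ca, cb, code, kappa, pi)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd
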