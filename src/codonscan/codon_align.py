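"""Codon-delimited alignment via protein-guided back-translation.

DNA-level alignment of coding sequences can split codons with single-base
gaps, scrambling the reading frame that downstream dN/dS math relies on. The
fix implemented here: translate each CDS, align the proteins (a native
affine-gap Needleman-Wunsch / progressive profile aligner), then map every
aligned residue back onto its source codon. Gaps therefore only ever appear
in whole-codon units, and degapping any row recovers the input CDS exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import trees
from .seqio import (
    GAP,
    GAP_CODON,
    CodingSequence,
    GeneticCode,
    ProteinSequence,
    STANDARD_CODE,
    degap,
    translate_cds,
)

logger = logging.getLogger("codonscan")

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0


class AlignmentError(ValueError):
    pass


@dataclass
class ProteinAlignment:
    """Gapped protein rows, all the same length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        ncols = len(self.rows[0][1])
        for name, seq in self.rows:
            if len(seq) != ncols:
                raise AlignmentError(f"ragged alignment: row {name!r}")

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.rows]

    def row(self, name: str) -> str:
        for n, s in self.rows:
            if n == name:
                return s
        raise KeyError(name)


@dataclass
class CodonAlignment:
    """Gapped nucleotide rows in whole-codon units, with the guiding protein alignment."""

    rows: list[tuple[str, str]]
    guide: ProteinAlignment | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        ncols = len(self.rows[0][1])
        if ncols % 3:
            raise AlignmentError("codon alignment length must be a multiple of 3")
        for name, seq in self.rows:
            if len(seq) != ncols:
                raise AlignmentError(f"ragged alignment: row {name!r}")

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ncodons(self) -> int:
        return self.ncols // 3

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.rows]

    def row(self, name: str) -> str:
        for n, s in self.rows:
            if n == name:
                return s
        raise KeyError(name)

    def codon_columns(self, row: str) -> list[str]:
        return [row[i : i + 3] for i in range(0, len(row), 3)]

    def slice_codons(self, start: int, end: int) -> "CodonAlignment":
        """Codon-unit slice, 1-based inclusive coordinates."""
        if not (1 <= start <= end <= self.ncodons):
            raise ValueError(f"codon slice [{start}, {end}] out of range 1..{self.ncodons}")
        lo, hi = (start - 1) * 3, end * 3
        return CodonAlignment([(n, s[lo:hi]) for n, s in self.rows], guide=None)


# ---------------------------------------------------------------------------
# Affine-gap profile-profile Needleman-Wunsch
# ---------------------------------------------------------------------------


def load_matrix(name_or_matrix=DEFAULT_MATRIX):
    if isinstance(name_or_matrix, str):
        return substitution_matrices.load(name_or_matrix)
    return name_or_matrix


def _column_score(cols_a: Sequence[str], cols_b: Sequence[str], matrix) -> float:
    """Sum-of-pairs substitution score between two profile columns.

    Residue-vs-gap pairs inside profile columns score 0 here; gap costs are
    charged only when the DP opens or extends a new gap between profiles.
    """
    total = 0.0
    for a in cols_a:
        if a == GAP:
            continue
        for b in cols_b:
            if b == GAP:
                continue
            total += matrix[a, b]
    return total


def _align_profiles(
    prof_a: list[str],
    prof_b: list[str],
    matrix,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str], float]:
    """Global affine-gap alignment of two profiles (lists of equal-length rows).

    Returns the gapped profiles and the optimal score. Tie-breaking in the
    traceback is deterministic: match preferred over a gap in the second
    profile, preferred over a gap in the first.
    """
    la = len(prof_a[0]) if prof_a[0] else 0
    lb = len(prof_b[0]) if prof_b[0] else 0
    cols_a = [[row[i] for row in prof_a] for i in range(la)]
    cols_b = [[row[j] for row in prof_b] for j in range(lb)]
    NEG = -np.inf

    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # consume a column of A (gap in B)
    Y = np.full((la + 1, lb + 1), NEG)  # consume a column of B (gap in A)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend

    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _column_score(cols_a[i - 1], cols_b[j - 1], matrix)
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend, Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, X[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)

    # traceback
    i, j = la, lb
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][i, j])
    score = {"M": M, "X": X, "Y": Y}[state][i, j]
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            prev = s = _column_score(cols_a[i - 1], cols_b[j - 1], matrix)
            target = M[i, j] - s
            for cand in ("M", "X", "Y"):
                if np.isclose({"M": M, "X": X, "Y": Y}[cand][i - 1, j - 1], target):
                    ops.append("M")
                    i, j, state = i - 1, j - 1, cand
                    break
            else:  # pragma: no cover - defensive
                raise AlignmentError("traceback failure")
        elif state == "X":
            if i >= 1 and np.isclose(M[i - 1, j] + gap_open, X[i, j]):
                ops.append("X")
                i, state = i - 1, "M"
            elif i >= 1 and np.isclose(X[i - 1, j] + gap_extend, X[i, j]):
                ops.append("X")
                i, state = i - 1, "X"
            else:
                ops.append("X")
                i, state = i - 1, "Y"
        else:  # Y
            if j >= 1 and np.isclose(M[i, j - 1] + gap_open, Y[i, j]):
                ops.append("Y")
                j, state = j - 1, "M"
            elif j >= 1 and np.isclose(X[i, j - 1] + gap_open, Y[i, j]):
                ops.append("Y")
                j, state = j - 1, "X"
            else:
                ops.append("Y")
                j, state = j - 1, "Y"
    ops.reverse()

    out_a = ["" for _ in prof_a]
    out_b = ["" for _ in prof_b]
    ai = bi = 0
    for op in ops:
        if op == "M":
            for k, row in enumerate(prof_a):
                out_a[k] += row[ai]
            for k, row in enumerate(prof_b):
                out_b[k] += row[bi]
            ai += 1
            bi += 1
        elif op == "X":
            for k, row in enumerate(prof_a):
                out_a[k] += row[ai]
            for k in range(len(prof_b)):
                out_b[k] += GAP
            ai += 1
        else:
            for k in range(len(prof_a)):
                out_a[k] += GAP
            for k, row in enumerate(prof_b):
                out_b[k] += row[bi]
            bi += 1
    return out_a, out_b, float(score)


def pairwise_align(
    a: str,
    b: str,
    matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[str, str, float]:
    """Optimal global affine-gap alignment of two ungapped protein strings."""
    if not a or not b:
        raise AlignmentError("cannot align empty sequence")
    matrix = load_matrix(matrix)
    (ga,), (gb,), score = _align_profiles([a], [b], matrix, gap_open, gap_extend)
    return ga, gb, score


def alignment_score(ga: str, gb: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Affine score of a given pairwise alignment (gap run = open + (len-1)*extend)."""
    matrix = load_matrix(matrix)
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ga, gb):
        if x == GAP and y == GAP:
            raise AlignmentError("all-gap column in pairwise alignment")
        if x == GAP:
            score += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            score += gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += matrix[x, y]
            in_gap_a = in_gap_b = False
    return float(score)


def sum_of_pairs_score(rows: Sequence[str], matrix, gap_open: float, gap_extend: float) -> float:
    """Sum of affine pairwise scores over all row pairs (all-gap columns dropped)."""
    matrix = load_matrix(matrix)
    total = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            pa, pb = [], []
            for x, y in zip(rows[i], rows[j]):
                if x == GAP and y == GAP:
                    continue
                pa.append(x)
                pb.append(y)
            total += alignment_score("".join(pa), "".join(pb), matrix, gap_open, gap_extend)
    return total


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


def align_proteins(
    seqs: Sequence[ProteinSequence | tuple[str, str]],
    matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ProteinAlignment:
    """Align proteins: optimal pairwise for 2 sequences, progressive for more.

    Progressive mode computes Poisson-corrected pairwise distances from the
    optimal pairwise alignments, builds a neighbor-joining guide tree, and
    merges profiles in postorder with sum-of-pairs scoring. Deterministic:
    ties break toward the leftmost / lowest-index alternative.
    """
    pairs = [(s.name, s.residues) if isinstance(s, ProteinSequence) else tuple(s) for s in seqs]
    if len(pairs) < 2:
        raise AlignmentError("need at least 2 sequences to align")
    for name, res in pairs:
        if not res:
            raise AlignmentError(f"empty sequence {name!r}")
    matrix = load_matrix(matrix)
    if len(pairs) == 2:
        ga, gb, _ = _align_profiles(
            [pairs[0][1]], [pairs[1][1]], matrix, gap_open, gap_extend
        )
        return ProteinAlignment([(pairs[0][0], ga[0]), (pairs[1][0], gb[0])])

    # guide tree from Poisson distances on optimal pairwise alignments
    n = len(pairs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb, _ = _align_profiles([pairs[i][1]], [pairs[j][1]], matrix, gap_open, gap_extend)
            comparable = sum(1 for x, y in zip(ga[0], gb[0]) if x != GAP and y != GAP)
            mismatch = sum(1 for x, y in zip(ga[0], gb[0]) if x != GAP and y != GAP and x != y)
            p = mismatch / comparable if comparable else 1.0
            p = min(p, 0.95)  # cap so the Poisson correction stays finite
            D[i, j] = D[j, i] = -np.log(1.0 - p)
    guide = trees.neighbor_joining(trees.DistanceMatrix([name for name, _ in pairs], D))
    guide.canonicalize()

    by_name = dict(pairs)
    order = {name: idx for idx, (name, _) in enumerate(pairs)}

    def merge(node: trees.TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [by_name[node.name]]
        names, prof = merge(node.children[0])
        for child in node.children[1:]:
            cnames, cprof = merge(child)
            prof, cprof_aligned, _ = _align_profiles(prof, cprof, matrix, gap_open, gap_extend)
            names += cnames
            prof += cprof_aligned
        return names, prof

    names, prof = merge(guide.root)
    rows = sorted(zip(names, prof), key=lambda item: order[item[0]])
    return ProteinAlignment(list(rows))


# ---------------------------------------------------------------------------
# Back-translation
# ---------------------------------------------------------------------------


def backtranslate(
    guide: ProteinAlignment,
    cds_set: Sequence[CodingSequence],
    code: GeneticCode = STANDARD_CODE,
) -> CodonAlignment:
    """Map a protein alignment back onto the source CDS, codon by codon.

    Residue column i becomes nucleotide columns 3i..3i+2; a gap residue
    becomes the gap codon ``---``. The translation of each CDS must equal its
    degapped guide row exactly.
    """
    cds_by_name = {c.name: c for c in cds_set}
    guide_names = set(guide.names)
    missing = sorted(guide_names.symmetric_difference(cds_by_name))
    if missing:
        raise AlignmentError(f"names do not match between guide and CDS set: {missing}")
    rows = []
    for name, gapped in guide.rows:
        cds = cds_by_name[name]
        protein = translate_cds(cds, code).residues
        degapped = degap(gapped)
        if protein != degapped:
            for idx, (x, y) in enumerate(zip(degapped, protein)):
                if x != y:
                    raise AlignmentError(
                        f"sequence {name!r}: guide residue {x!r} != translated {y!r} "
                        f"at residue {idx + 1}"
                    )
            raise AlignmentError(
                f"sequence {name!r}: guide length {len(degapped)} != translation "
                f"length {len(protein)}"
            )
        codons = cds.codons
        k = 0
        parts = []
        for residue in gapped:
            if residue == GAP:
                parts.append(GAP_CODON)
            else:
                parts.append(codons[k])
                k += 1
        rows.append((name, "".join(parts)))
    return CodonAlignment(rows, guide=guide)


def build_codon_alignment(
    cds_set: Sequence[CodingSequence],
    protein_alignment: ProteinAlignment | None = None,
    code: GeneticCode = STANDARD_CODE,
    matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> CodonAlignment:
    """End-to-end codon-delimited alignment.

    With no ``protein_alignment``, the CDS are translated and aligned
    internally; with one supplied (pre-aligned mode), the aligner is bypassed
    and the given alignment is used verbatim as the guide.
    """
    if protein_alignment is None:
        proteins = [translate_cds(c, code) for c in cds_set]
        protein_alignment = align_proteins(proteins, matrix, gap_open, gap_extend)
    return backtranslate(protein_alignment, cds_set, code)
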