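"""Sliding-window pairwise dN/dS scans over a codon alignment.

Windows are in codon (= amino acid) units with 1-based inclusive
coordinates. A scan computes a pairwise counting-method dN/dS restricted to
each window's codon columns, producing one track per sequence pair.

Sliding-window dN/dS is exploratory: resampling overlapping windows can
produce artifactual peaks, so regional signal found here should be confirmed
with the site-model likelihood-ratio tests (:mod:`codonscan.site_models`).
This caveat is logged once per scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from .codon_align import CodonAlignment
from .dnds import PairwiseDnDsResult, pairwise_dnds
from .seqio import GeneticCode, STANDARD_CODE

logger = logging.getLogger("codonscan")


@dataclass(frozen=True)
class Window:
    """A codon-unit window, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end}]")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class WindowTrack:
    """Per-window dN/dS results for one sequence pair."""

    pair: tuple[str, str]
    method: str
    windows: list[tuple[Window, PairwiseDnDsResult]] = field(default_factory=list)


def make_windows(L: int, w: int, j: int, terminal_window: bool = True) -> list[Window]:
    """Window starts 1, 1+j, 1+2j, ... while a full window fits.

    If the last full window does not reach codon L and ``terminal_window`` is
    set, a right-anchored full-width window [L-w+1, L] is appended (so the
    terminal region is covered at the same window width, keeping per-window
    variance comparable).
    """
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if j < 1:
        raise ValueError("jump must be >= 1")
    if w < 1:
        raise ValueError("window must be >= 1")
    if w > L:
        logger.warning("window %d exceeds alignment length %d; using one window [1, %d]", w, L, L)
        return [Window(1, L)]
    if j > w:
        logger.warning("jump %d exceeds window %d; scan leaves coverage gaps", j, w)
    out = []
    start = 1
    while start + w - 1 <= L:
        out.append(Window(start, start + w - 1))
        start += j
    if terminal_window and out and out[-1].end < L:
        terminal = Window(L - w + 1, L)
        if terminal != out[-1]:
            out.append(terminal)
    return out


def expand_pairs(names: Sequence[str], pairs) -> list[tuple[str, str]]:
    """Resolve a pair selection: ``'all'`` or explicit (name, name) tuples."""
    if pairs == "all" or pairs is None:
        return list(combinations(names, 2))
    out = []
    for a, b in pairs:
        if a not in names or b not in names:
            raise KeyError(f"pair ({a!r}, {b!r}) not in alignment names")
        out.append((a, b))
    return out


def sliding_scan(
    aln: CodonAlignment,
    pairs="all",
    w: int = 100,
    j: int = 10,
    method: str = "NG86",
    code: GeneticCode = STANDARD_CODE,
    terminal_window: bool = True,
) -> list[WindowTrack]:
    """Sliding-window pairwise dN/dS over selected pairs of an alignment.

    Windows where a pair has zero comparable codons (all gapped) yield a
    flagged all-NaN result row and the scan continues. Output is a pure
    function of the inputs: repeated runs are identical.
    """
    logger.info(
        "sliding-window dN/dS is exploratory and prone to resampling artifacts; "
        "confirm regional signal with site-model LRTs"
    )
    pair_list = expand_pairs(aln.names, pairs)
    window_list = make_windows(aln.ncodons, w, j, terminal_window)
    tracks = []
    for a, b in pair_list:
        ra, rb = aln.row(a), aln.row(b)
        track = WindowTrack(pair=(a, b), method=method.upper())
        for win in window_list:
            lo, hi = (win.start - 1) * 3, win.end * 3
            try:
                res = pairwise_dnds(
                    ra[lo:hi], rb[lo:hi], method=method, code=code, pair=(a, b)
                )
            except ValueError:
                res = PairwiseDnDsResult(
                    pair=(a, b),
                    method=method.upper(),
                    S=math.nan,
                    N=math.nan,
                    Sd=math.nan,
                    Nd=math.nan,
                    pS=math.nan,
                    pN=math.nan,
                    dS=math.nan,
                    dN=math.nan,
                    omega=math.nan,
                    kappa=None,
                    ncodons_used=0,
                    flags=("no_comparable_codons",),
                )
            track.windows.append((win, res))
        tracks.append(track)
    return tracks
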