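"""CSV export and track plotting for window scans and site analyses.

CSV conventions: header row always present; an undefined omega (0/0 or a
correction out of domain) renders as ``NA``, an infinite omega (dS = 0 with
dN > 0) as ``Inf`` — the two cases stay distinguishable downstream. Plots
put the codon / amino-acid coordinate (1-based) on x, dN/dS on y, draw a
reference line at omega = 1 and leave gaps (not zeros) where omega is
undefined.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .site_models import LRTResult, SiteModelFit, SitePosterior
from .windows import WindowTrack

_NA = "NA"
_INF = "Inf"


def _render(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return _NA
    if isinstance(x, float) and math.isinf(x):
        return _INF if x > 0 else "-Inf"
    return repr(float(x))


def _parse(value: str) -> float:
    if value == _NA:
        return math.nan
    if value == _INF:
        return math.inf
    if value == "-Inf":
        return -math.inf
    return float(value)


WINDOW_COLUMNS = [
    "pair",
    "method",
    "win_start",
    "win_end",
    "midpoint",
    "S",
    "N",
    "Sd",
    "Nd",
    "dN",
    "dS",
    "omega",
    "kappa",
    "ncodons_used",
    "flags",
]

PAIRWISE_COLUMNS = [
    "pair",
    "method",
    "S",
    "N",
    "Sd",
    "Nd",
    "pS",
    "pN",
    "dS",
    "dN",
    "omega",
    "kappa",
    "ncodons_used",
]

SITE_COLUMNS = [
    "site",
    "posterior_mean_omega",
    "posterior_sd",
    "p_positive",
    "flagged",
    "strong",
]

MODEL_COLUMNS = ["model", "lnL", "kappa", "n_free_params", "converged", "params"]
LRT_COLUMNS = ["null_model", "alt_model", "statistic", "df", "p_value"]


def export_window_csv(tracks: Sequence[WindowTrack], path: str | Path) -> Path:
    """One row per (pair, window); flagged/undefined values rendered NA / Inf."""
    if not tracks:
        raise ValueError("no window tracks to export")
    rows = []
    for track in tracks:
        if not track.windows:
            raise ValueError(f"track {track.pair} has no windows")
        for win, res in track.windows:
            rows.append(
                {
                    "pair": f"{track.pair[0]}:{track.pair[1]}",
                    "method": track.method,
                    "win_start": win.start,
                    "win_end": win.end,
                    "midpoint": win.midpoint,
                    "S": _render(res.S),
                    "N": _render(res.N),
                    "Sd": _render(res.Sd),
                    "Nd": _render(res.Nd),
                    "dN": _render(res.dN),
                    "dS": _render(res.dS),
                    "omega": _render(res.omega),
                    "kappa": _render(res.kappa) if res.kappa is not None else _NA,
                    "ncodons_used": res.ncodons_used,
                    "flags": ";".join(res.flags),
                }
            )
    frame = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_window_csv(path: str | Path) -> pd.DataFrame:
    """Read a window CSV back with NA/Inf decoded into floats."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("midpoint", "S", "N", "Sd", "Nd", "dN", "dS", "omega", "kappa"):
        frame[col] = frame[col].map(_parse)
    for col in ("win_start", "win_end", "ncodons_used"):
        frame[col] = frame[col].astype(int)
    return frame


def export_pairwise_csv(results, path: str | Path) -> Path:
    """Whole-sequence pairwise dN/dS rows (NG86 and/or YN00)."""
    results = list(results)
    if not results:
        raise ValueError("no pairwise results to export")
    rows = []
    for res in results:
        row = {
            "pair": f"{res.pair[0]}:{res.pair[1]}",
            "method": res.method,
            "ncodons_used": res.ncodons_used,
        }
        for colname in ("S", "N", "Sd", "Nd", "pS", "pN", "dS", "dN", "omega"):
            row[colname] = _render(getattr(res, colname))
        row["kappa"] = _render(res.kappa) if res.kappa is not None else _NA
        rows.append(row)
    frame = pd.DataFrame(rows, columns=PAIRWISE_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def export_site_csv(posteriors: Sequence[SitePosterior], path: str | Path) -> Path:
    if not posteriors:
        raise ValueError("no site posteriors to export")
    rows = [
        {
            "site": p.site,
            "posterior_mean_omega": _render(p.posterior_mean_omega),
            "posterior_sd": _render(p.posterior_sd_omega),
            "p_positive": _render(p.p_positive),
            "flagged": int(p.flagged_positive),
            "strong": int(p.strong),
        }
        for p in posteriors
    ]
    frame = pd.DataFrame(rows, columns=SITE_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_site_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("posterior_mean_omega", "posterior_sd", "p_positive"):
        frame[col] = frame[col].map(_parse)
    for col in ("site", "flagged", "strong"):
        frame[col] = frame[col].astype(int)
    return frame


def export_model_csv(
    fits: dict[str, SiteModelFit], lrts: Sequence[LRTResult], path: str | Path
) -> Path:
    """Model fit summary plus LRT rows appended below a blank separator."""
    if not fits:
        raise ValueError("no model fits to export")
    rows = [
        {
            "model": fit.model_id,
            "lnL": _render(fit.lnL),
            "kappa": _render(fit.kappa),
            "n_free_params": fit.n_free_params,
            "converged": int(fit.converged),
            "params": ";".join(
                f"{k}={v:.6g}" for k, v in fit.spec.params.items() if isinstance(v, float)
            ),
        }
        for fit in fits.values()
    ]
    frame = pd.DataFrame(rows, columns=MODEL_COLUMNS)
    lrt_frame = pd.DataFrame(
        [
            {
                "null_model": r.null_model,
                "alt_model": r.alt_model,
                "statistic": _render(r.statistic),
                "df": r.df,
                "p_value": _render(r.p_value),
            }
            for r in lrts
        ],
        columns=LRT_COLUMNS,
    )
    path = Path(path)
    with open(path, "w") as fh:
        frame.to_csv(fh, index=False)
        fh.write("\n")
        lrt_frame.to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------


def plot_window_tracks(
    tracks: Sequence[WindowTrack], path: str | Path, title: str | None = None
) -> Path:
    """Window-scan plot: x = window midpoint (codons), one line per pair.

    Undefined omegas become gaps in the line; infinite omegas are likewise
    omitted from the line (they have no finite y) but are marked at the top
    of the axis.
    """
    if not tracks:
        raise ValueError("no window tracks to plot")
    fig, ax = plt.subplots(figsize=(8, 4))
    finite_max = 0.0
    for track in tracks:
        x = np.array([win.midpoint for win, _ in track.windows])
        y = np.array([res.omega for _, res in track.windows])
        finite = y[np.isfinite(y)]
        if finite.size:
            finite_max = max(finite_max, float(finite.max()))
        masked = np.ma.masked_invalid(y)
        ax.plot(x, masked, marker=".", label=f"{track.pair[0]} vs {track.pair[1]}")
    top = max(finite_max * 1.1, 1.5)
    for track in tracks:
        for win, res in track.windows:
            if math.isinf(res.omega):
                ax.plot([win.midpoint], [top], marker="^", color="black")
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("codon (window midpoint)")
    ax.set_ylabel("dN/dS")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return path


def plot_site_track(
    posteriors: Sequence[SitePosterior], path: str | Path, title: str | None = None
) -> Path:
    """Site plot: posterior mean omega with +/- 1 posterior-SD error bars.

    Sites flagged positive (posterior mass on omega > 1 classes above the
    threshold) are marked.
    """
    if not posteriors:
        raise ValueError("no site posteriors to plot")
    x = np.array([p.site for p in posteriors])
    y = np.array([p.posterior_mean_omega for p in posteriors])
    err = np.array([p.posterior_sd_omega for p in posteriors])
    flagged = np.array([p.flagged_positive for p in posteriors])
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.errorbar(x, y, yerr=err, fmt="-", linewidth=1, elinewidth=0.5, capsize=0, color="C0")
    if flagged.any():
        ax.plot(x[flagged], y[flagged], "r*", markersize=8, label="flagged positive")
        ax.legend(fontsize=8)
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("codon site")
    ax.set_ylabel("posterior mean dN/dS")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return path
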