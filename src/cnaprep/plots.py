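"""Diagnostic plots: GC-effect density map and called-profile overview.

matplotlib is an optional dependency; importing this module without it
installed raises a clear error only when a plot function is called.
"""

from __future__ import annotations

import numpy as np

from .core import RCProfile
from .normalize import GCCurve
from .segment_call import SegmentSet


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install cnaprep[plot])") from exc
    return plt


def plot_gc_fit(
    profile: RCProfile,
    curves: dict[str, GCCurve],
    out_path,
    gridsize: int = 60,
) -> None:
    """Density map of value vs window GC with fitted effect curves overlaid."""
    plt = _pyplot()
    gc = profile.df["gc"].to_numpy(dtype=float)
    values = profile.values
    keep = ~profile.mask & np.isfinite(gc) & np.isfinite(values) & (values > 0)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.hexbin(gc[keep], values[keep], gridsize=gridsize, cmap="Greys", mincnt=1)
    med = float(np.median(values[keep]))
    for label, curve in curves.items():
        ax.plot(curve.gc_grid, med * curve.effect, label=label, linewidth=2)
    ax.set_xlabel("window GC fraction")
    ax.set_ylabel("window value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_profile(
    profile: RCProfile,
    segments: SegmentSet | None,
    out_path,
    thresholds=None,
) -> None:
    """Genome-wide value density with segment means and call thresholds."""
    plt = _pyplot()
    values = profile.values
    keep = ~profile.mask & np.isfinite(values)
    x = np.arange(len(profile))
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(x[keep], values[keep], ".", color="0.6", markersize=1.5, rasterized=True)
    if segments is not None:
        for row in segments.df.itertuples():
            ax.hlines(row.level, row.start_idx, row.end_idx, color="green", linewidth=2)
    if thresholds is not None:
        for t in np.asarray(thresholds, dtype=float):
            ax.axhline(t, color="red", linewidth=0.8, linestyle="--")
    # chromosome boundaries
    chrom = profile.chrom
    for i in range(1, len(chrom)):
        if chrom[i] != chrom[i - 1]:
            ax.axvline(i - 0.5, color="black", linewidth=0.8)
    ax.set_xlabel("window index")
    ax.set_ylabel("value")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
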