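"""Piecewise-constant segmentation and threshold-based copy-number calling.

Segmentation is an exact penalized least-squares changepoint fit per
chromosome (PELT pruning, so it is linear-ish in practice while provably
equal to the full dynamic program).  Masked windows are bridged: segments
are fitted on the unmasked subsequence and may span masked gaps.

Calling maps segment levels to integer copy numbers through explicit
ascending thresholds (left-inclusive bands).  Threshold choice is the
analyst's; ``suggest_thresholds`` offers a data-driven starting point by
anchoring the modal segment level to a baseline copy number, but it is
only ever a suggestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RCProfile, chromosome_slices


@dataclass
class SegmentSet:
    """Piecewise-constant segments over window indices.

    ``df`` columns: chrom, start_idx, end_idx (global window indices,
    inclusive), start, end (bp), n_windows (unmasked members), level
    (median of member values) and optionally call.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def levels(self) -> np.ndarray:
        return self.df["level"].to_numpy(dtype=float)

    def to_seg(self, path) -> None:
        cols = ["chrom", "start", "end", "n_windows", "level"]
        if "call" in self.df.columns:
            cols.append("call")
        self.df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_seg(cls, path) -> "SegmentSet":
        df = pd.read_csv(path, sep="\t")
        if "start_idx" not in df.columns:
            df["start_idx"] = -1
            df["end_idx"] = -1
        return cls(df)


@dataclass
class CNCallSet:
    """Integer copy-number calls with the thresholds that produced them."""

    thresholds: np.ndarray
    calls: np.ndarray
    baseline_cn: int
    segments: SegmentSet


# ---------------------------------------------------------------------------
# changepoint core


def _pelt(x: np.ndarray, beta: float) -> list[int]:
    """Exact penalized least-squares changepoints via PELT.

    Returns sorted interior breakpoints ``b`` such that segments are
    ``x[0:b1], x[b1:b2], ..., x[bk:n]``.  Minimizes
    ``sum(SSE per segment) + beta * (number of segments)``.
    """
    n = len(x)
    if n == 0:
        return []
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(starts: np.ndarray, t: int) -> np.ndarray:
        lens = t - starts
        s = cs[t] - cs[starts]
        return (cs2[t] - cs2[starts]) - s * s / lens

    F = np.empty(n + 1)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=int)
    cands = np.array([0], dtype=int)
    for t in range(1, n + 1):
        costs = F[cands] + sse(cands, t) + beta
        best = int(np.argmin(costs))
        F[t] = costs[best]
        prev[t] = cands[best]
        keep = F[cands] + sse(cands, t) <= F[t]
        cands = np.append(cands[keep], t)
    bps: list[int] = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            bps.append(s)
        t = s
    return sorted(bps)


def default_penalty(values: np.ndarray, chrom=None, mask=None) -> float:
    """Penalty 3 * noise^2 * log(n) with noise from the robust SNR estimator."""
    from .normalize import snr as _snr

    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    n = max(int(keep.sum()), 2)
    try:
        noise = _snr(values, chrom=chrom, mask=~keep).noise
    except ValueError:
        noise = 0.0
    scale = float(np.median(np.abs(values[keep]))) if keep.any() else 1.0
    floor = 1e-9 * (1.0 + scale) ** 2
    return max(3.0 * noise * noise * np.log(n), floor)


def segment(
    profile_or_values,
    penalty: float | None = None,
    chrom=None,
    mask=None,
) -> SegmentSet:
    """Segment a profile into piecewise-constant levels per chromosome.

    Masked or non-finite windows are excluded from the fit; a segment's
    ``start_idx``/``end_idx`` are the global indices of its first and
    last unmasked member, so segments bridge masked gaps.  The default
    penalty is ``3 * noise^2 * log(n)`` with a derivative-based robust
    noise estimate.  Segment ``level`` is the median of member values.
    """
    if isinstance(profile_or_values, RCProfile):
        values = profile_or_values.values
        chrom = profile_or_values.chrom
        mask = profile_or_values.mask
        starts_bp = profile_or_values.df["start"].to_numpy()
        ends_bp = profile_or_values.df["end"].to_numpy()
    else:
        values = np.asarray(profile_or_values, dtype=float)
        if chrom is None:
            chrom = np.array(["chr0"] * len(values), dtype=object)
        chrom = np.asarray(chrom, dtype=object)
        if mask is None:
            mask = np.zeros(len(values), dtype=bool)
        starts_bp = np.arange(len(values)) + 1
        ends_bp = np.arange(len(values)) + 1

    mask = np.asarray(mask, dtype=bool) | ~np.isfinite(values)
    if penalty is None:
        penalty = default_penalty(values, chrom=chrom, mask=mask)

    rows = []
    for name, sl in chromosome_slices(chrom):
        idx = np.arange(sl.start, sl.stop)[~mask[sl]]
        v = values[idx]
        if len(v) == 0:
            continue
        if len(v) < 2:
            bps = []
        else:
            bps = _pelt(v, penalty)
        bounds = [0] + bps + [len(v)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            members = idx[a:b]
            rows.append(
                {
                    "chrom": name,
                    "start_idx": int(members[0]),
                    "end_idx": int(members[-1]),
                    "start": int(starts_bp[members[0]]),
                    "end": int(ends_bp[members[-1]]),
                    "n_windows": int(b - a),
                    "level": float(np.median(v[a:b])),
                }
            )
    return SegmentSet(pd.DataFrame(rows, columns=[
        "chrom", "start_idx", "end_idx", "start", "end", "n_windows", "level",
    ]))


# ---------------------------------------------------------------------------
# calling


def call(segments: SegmentSet, thresholds) -> CNCallSet:
    """Assign integer copy numbers to segments by ascending thresholds.

    A segment with level in ``[thresholds[k], thresholds[k+1])`` receives
    call ``k + 1``; levels below the first threshold get 0.  Boundaries
    are inclusive on the left.
    """
    thr = np.asarray(thresholds, dtype=float)
    if len(thr) == 0:
        raise ValueError("at least one threshold required")
    if not (np.diff(thr) > 0).all():
        raise ValueError("thresholds must be strictly ascending")
    levels = segments.levels
    calls = np.searchsorted(thr, levels, side="right").astype(int)
    out = SegmentSet(segments.df.copy())
    out.df["call"] = calls
    return CNCallSet(
        thresholds=thr, calls=calls, baseline_cn=-1, segments=out
    )


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def suggest_thresholds(
    segments: SegmentSet, baseline_cn: int = 2
) -> np.ndarray | None:
    """Suggest calling thresholds by anchoring the modal level to a baseline.

    Segment levels are clustered (window-weighted); the heaviest cluster
    is taken as the baseline copy number, implying a per-copy step of
    ``mode / baseline_cn``.  Thresholds sit at odd multiples of half the
    step, up to just above the highest level.  Returns None when no mode
    can be picked (single level, or top clusters too close in weight to
    disambiguate) — calling then requires explicit thresholds.
    """
    if len(segments) == 0:
        raise ValueError("no segments")
    levels = segments.levels
    weights = segments.df["n_windows"].to_numpy(dtype=float)
    if levels.max() <= levels.min():
        return None  # single distinct level: step undefined

    # bandwidth from a weighted 5-95% spread so that rare extreme
    # segments (e.g. surviving outlier windows) cannot inflate it
    order = np.argsort(levels)
    cw = np.cumsum(weights[order]) / weights.sum()
    q05 = float(np.interp(0.05, cw, levels[order]))
    q95 = float(np.interp(0.95, cw, levels[order]))
    spread = max(q95 - q05, (levels.max() - levels.min()) * 1e-3)
    if spread <= 0:
        return None

    # window-weighted kernel density over segment levels; the global peak
    # is the modal level, refined to the weighted median of nearby levels
    from scipy.stats import gaussian_kde

    sd = float(np.sqrt(np.cov(levels, aweights=weights)))
    bw_abs = max(0.04 * spread, 1e-12)
    kde = gaussian_kde(levels, weights=weights, bw_method=bw_abs / max(sd, 1e-12))
    grid = np.linspace(levels.min() - bw_abs, levels.max() + bw_abs, 512)
    dens = kde(grid)
    peak = int(np.argmax(dens))

    # flat multimodality: a rival peak of comparable height far from the mode
    is_max = np.flatnonzero(
        (dens >= np.roll(dens, 1)) & (dens >= np.roll(dens, -1))
        & (dens >= 0.9 * dens[peak])
    )
    if np.any(np.abs(grid[is_max] - grid[peak]) > 3 * bw_abs):
        return None

    near = np.abs(levels - grid[peak]) <= 2 * bw_abs
    if not near.any():
        return None
    mode = float(_weighted_median(levels[near], weights[near]))
    if mode <= 0:
        return None
    step = mode / baseline_cn
    k_max = int(np.floor(levels.max() / step + 0.5))
    thr = step * (np.arange(0, k_max + 1) + 0.5)
    return thr


def call_windows(
    profile: RCProfile, callset: CNCallSet
) -> np.ndarray:
    """Per-window integer calls (-1 for windows in no segment)."""
    out = np.full(len(profile), -1, dtype=int)
    for row, c in zip(callset.segments.df.itertuples(), callset.calls):
        out[row.start_idx:row.end_idx + 1] = c
    out[profile.mask] = -1
    return out
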