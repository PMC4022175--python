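"""GC-bias correction and profile quality metrics.

Two correction routes are provided.  ``single_pass_correct`` is the
classical one: a locally weighted regression of (log) counts on GC
content, applied genome-wide.  It is biased whenever copy number and GC
content are correlated, because the regression absorbs copy-number
structure into the GC curve.  ``seqnorm`` removes that bias with a second
pass: the first-pass-corrected profile is segmented into constant-copy
pieces, segments are screened (enough windows, low value variability,
enough GC spread), each surviving segment is centered by its own median —
which cancels copy-number differences — and refit; the pointwise median
of the per-segment curves is a robust estimate of the true GC effect,
which is then applied to the raw counts.

The signal-to-noise metric used throughout is the median working value
over a derivative-based robust noise estimate,
``median(|v[i+1] - v[i]|) / (0.6745 * sqrt(2))`` within chromosomes,
which is insensitive to piecewise-constant copy-number structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import RCProfile, chromosome_slices

#: default GC grid on which effect curves are estimated
DEFAULT_GC_GRID = np.round(np.arange(0.20, 0.70 + 1e-9, 0.005), 4)

_MAD_TO_SD = 0.6745  # |N(0,1)| median


@dataclass
class GCCurve:
    """Multiplicative GC effect on read counts, tabulated on a GC grid.

    The curve is normalized so its value at the median GC of the windows
    it was fitted on equals 1.  ``support`` counts contributing segments
    (or 1/0 for a single genome-wide fit) per grid point; points outside
    the observed GC range carry the nearest estimated value and support 0.
    """

    gc_grid: np.ndarray
    effect: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        if not (np.diff(self.gc_grid) > 0).all():
            raise ValueError("gc_grid must be strictly ascending")
        ok = np.isfinite(self.effect)
        if not ok.any() or (self.effect[ok] <= 0).any():
            raise ValueError("effect must be positive where defined")

    def evaluate(self, gc) -> np.ndarray:
        """Interpolate the effect at arbitrary GC values (NaN stays NaN)."""
        gc = np.asarray(gc, dtype=float)
        out = np.full(gc.shape, np.nan)
        fin = np.isfinite(gc)
        out[fin] = np.interp(gc[fin], self.gc_grid, self.effect)
        return out

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"gc": self.gc_grid, "effect": self.effect, "support": self.support}
        )


@dataclass
class SNRValue:
    """Robust signal-to-noise ratio of a profile."""

    signal: float
    noise: float
    snr: float

    @property
    def infinite(self) -> bool:
        return np.isinf(self.snr)


def snr(profile_or_values, chrom=None, mask=None) -> SNRValue:
    """Signal-to-noise ratio: median value / derivative-based robust sd.

    Noise is ``median(|v[i+1] - v[i]|) / (0.6745 * sqrt(2))`` over
    consecutive unmasked windows within each chromosome; differences
    never straddle chromosome boundaries.  A constant profile yields an
    infinite SNR (signalled via ``SNRValue.infinite``), not an exception.
    """
    if isinstance(profile_or_values, RCProfile):
        values = profile_or_values.values
        chrom = profile_or_values.chrom
        mask = profile_or_values.mask
    else:
        values = np.asarray(profile_or_values, dtype=float)
        if chrom is None:
            chrom = np.zeros(len(values), dtype=object)
        if mask is None:
            mask = np.zeros(len(values), dtype=bool)
    keep = ~np.asarray(mask, dtype=bool) & np.isfinite(values)
    diffs: list[np.ndarray] = []
    kept_values: list[np.ndarray] = []
    for _, sl in chromosome_slices(np.asarray(chrom, dtype=object)):
        v = values[sl][keep[sl]]
        kept_values.append(v)
        if len(v) >= 2:
            diffs.append(np.abs(np.diff(v)))
    if not kept_values or sum(len(v) for v in kept_values) == 0:
        raise ValueError("no usable windows for SNR")
    signal = float(np.median(np.concatenate(kept_values)))
    if not diffs:
        raise ValueError("need >= 2 unmasked windows in some chromosome")
    noise = float(np.median(np.concatenate(diffs)) / (_MAD_TO_SD * np.sqrt(2.0)))
    value = np.inf if noise == 0 else signal / noise
    return SNRValue(signal=signal, noise=noise, snr=value)


# ---------------------------------------------------------------------------
# local regression of the GC effect


def gc_local_fit(
    values,
    gc,
    span: float = 0.3,
    grid=None,
) -> GCCurve:
    """Locally weighted regression of log(value) on GC, as a GCCurve.

    Only finite, positive values with finite GC enter the fit.  The span
    is widened automatically (with a warning) when the data are too
    sparse for a stable fit at the requested span.
    """
    values = np.asarray(values, dtype=float)
    gc = np.asarray(gc, dtype=float)
    grid = DEFAULT_GC_GRID if grid is None else np.asarray(grid, dtype=float)

    ok = np.isfinite(values) & np.isfinite(gc) & (values > 0)
    x, y = gc[ok], np.log(values[ok])
    if len(x) < 10:
        raise ValueError("too few usable (value, gc) pairs for a local fit")
    gc_lo, gc_hi = x.min(), x.max()
    if gc_hi - gc_lo < 1e-6:
        # GC essentially constant: no estimable effect, identity curve
        return GCCurve(
            gc_grid=grid,
            effect=np.ones(len(grid)),
            support=np.zeros(len(grid), dtype=int),
        )
    inside = (grid >= gc_lo) & (grid <= gc_hi)

    frac = span
    min_points = 10
    while frac < 1.0 and frac * len(x) < min_points:
        frac = min(1.0, frac * 1.5)
    if frac != span:
        warnings.warn(
            f"lowess span widened from {span} to {frac:.3g} for data density",
            stacklevel=2,
        )

    log_effect = np.full(len(grid), np.nan)
    if inside.any():
        fit = lowess(y, x, frac=frac, it=2, xvals=grid[inside])
        while np.isnan(fit).any() and frac < 1.0:
            frac = min(1.0, frac * 1.5)
            fit = lowess(y, x, frac=frac, it=2, xvals=grid[inside])
        log_effect[inside] = fit
    else:
        # degenerate: all data between two grid points; constant effect
        log_effect[:] = float(np.median(y))
        inside = np.ones(len(grid), dtype=bool)

    # fill outside-range grid points with the nearest estimated value
    idx_inside = np.flatnonzero(inside & np.isfinite(log_effect))
    if len(idx_inside) == 0:
        raise ValueError("local fit produced no finite estimates")
    first, last = idx_inside[0], idx_inside[-1]
    log_effect[:first] = log_effect[first]
    log_effect[last + 1:] = log_effect[last]
    interior = np.isnan(log_effect)
    if interior.any():
        log_effect[interior] = np.interp(
            grid[interior], grid[~interior], log_effect[~interior]
        )

    effect = np.exp(log_effect)
    anchor = float(np.interp(np.median(x), grid, effect))
    effect = effect / anchor
    support = np.zeros(len(grid), dtype=int)
    support[first:last + 1] = 1
    return GCCurve(gc_grid=grid, effect=effect, support=support)


def _apply_curve(profile: RCProfile, curve: GCCurve, rescale: bool = True) -> RCProfile:
    """Divide working values by the curve; preserve the unmasked median."""
    out = profile.copy()
    values = profile.values.astype(float)
    gc = profile.df["gc"].to_numpy(dtype=float)
    eff = curve.evaluate(gc)
    corrected = values.copy()
    has_gc = np.isfinite(eff)
    corrected[has_gc] = values[has_gc] / eff[has_gc]
    n_missing = int((~has_gc).sum())
    if n_missing:
        out.meta["gc_uncorrected_windows"] = n_missing
    if rescale:
        keep = ~profile.mask & np.isfinite(corrected)
        in_med = np.median(values[keep])
        out_med = np.median(corrected[keep])
        if out_med > 0:
            corrected *= in_med / out_med
    out.set_values(corrected)
    return out


def single_pass_correct(
    profile: RCProfile, span: float = 0.3, rescale: bool = True
) -> RCProfile:
    """One-pass GC correction: genome-wide local regression.

    Masked windows are excluded from the fit but corrected in the output.
    Windows without GC pass through uncorrected (flagged in ``meta``).
    The output median over unmasked windows equals the input median.
    """
    values = profile.values
    gc = profile.df["gc"].to_numpy(dtype=float)
    keep = ~profile.mask
    curve = gc_local_fit(values[keep], gc[keep], span=span)
    out = _apply_curve(profile, curve, rescale=rescale)
    out.meta["normalization"] = "single_pass"
    return out


# ---------------------------------------------------------------------------
# segment selection for the second pass


@dataclass
class SegmentSelection:
    """Per-segment screening result for the second-pass regression."""

    n_windows: np.ndarray
    rc_variability: np.ndarray  #: robust sd (MAD-based) of values per segment
    gc_variability: np.ndarray  #: sd of GC per segment
    selected: np.ndarray
    rc_var_quantile: float
    gc_var_quantile: float
    failed: bool = False


def _robust_sd(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return np.nan
    return float(np.median(np.abs(x - np.median(x))) / _MAD_TO_SD)


def select_segments(
    segments,
    values,
    gc,
    min_windows: int = 20,
    rc_var_quantile: float = 0.75,
    gc_var_quantile: float = 0.25,
) -> SegmentSelection:
    """Screen segments for the segment-wise second-pass regression.

    A segment is selected iff it spans at least ``min_windows`` windows,
    its value variability is at or below the ``rc_var_quantile`` quantile
    of all segments' variabilities (very noisy segments do not give
    robust fits) and its GC variability is at or above the
    ``gc_var_quantile`` quantile (GC-flat segments cannot estimate the
    curve).  Ties are kept.  If fewer than 3 segments survive, the
    quantile cuts are relaxed stepwise by 0.05 until at least 3 survive
    or the cuts are exhausted (``failed=True``).

    ``segments`` is a sequence of (start, stop) half-open index pairs
    into ``values``/``gc`` (as produced by the segmentation module for
    the unmasked windows).
    """
    values = np.asarray(values, dtype=float)
    gc = np.asarray(gc, dtype=float)
    n_seg = len(segments)
    n_win = np.array([stop - start for start, stop in segments])
    rc_var = np.array([_robust_sd(values[a:b]) for a, b in segments])
    gc_var = np.array(
        [float(np.nanstd(gc[a:b])) if b - a > 1 else np.nan for a, b in segments]
    )

    big = n_win >= min_windows
    rcq, gcq = rc_var_quantile, gc_var_quantile
    selected = np.zeros(n_seg, dtype=bool)
    failed = False
    while True:
        rc_cut = np.nanquantile(rc_var, rcq) if np.isfinite(rc_var).any() else np.inf
        gc_cut = np.nanquantile(gc_var, gcq) if np.isfinite(gc_var).any() else -np.inf
        with np.errstate(invalid="ignore"):
            selected = (
                big
                & np.where(np.isfinite(rc_var), rc_var <= rc_cut, False)
                & np.where(np.isfinite(gc_var), gc_var >= gc_cut, False)
            )
        if selected.sum() >= 3:
            break
        if rcq >= 1.0 and gcq <= 0.0:
            failed = True
            break
        rcq = min(1.0, rcq + 0.05)
        gcq = max(0.0, gcq - 0.05)
    return SegmentSelection(
        n_windows=n_win,
        rc_variability=rc_var,
        gc_variability=gc_var,
        selected=selected,
        rc_var_quantile=rcq,
        gc_var_quantile=gcq,
        failed=failed,
    )


# ---------------------------------------------------------------------------
# the two-pass correction


def _segment_median_curve(
    raw: np.ndarray,
    covariate: np.ndarray,
    segments,
    selection: SegmentSelection,
    span: float,
    grid: np.ndarray,
) -> GCCurve:
    """Median across per-segment curves fitted on median-centered raw values."""
    per_seg: list[np.ndarray] = []
    for (a, b), sel in zip(segments, selection.selected):
        if not sel:
            continue
        v = raw[a:b]
        g = covariate[a:b]
        ok = np.isfinite(v) & np.isfinite(g) & (v > 0)
        if ok.sum() < 10:
            continue
        center = np.median(v[ok])
        if center <= 0:
            continue
        centered = v / center
        try:
            with warnings.catch_warnings():
                # span widening is routine for segment-sized fits
                warnings.simplefilter("ignore", UserWarning)
                curve = gc_local_fit(centered[ok], g[ok], span=span, grid=grid)
        except ValueError:
            continue
        eff = curve.effect.copy()
        eff[curve.support == 0] = np.nan  # only within the segment's GC range
        per_seg.append(eff)
    if len(per_seg) < 2:
        raise ValueError("fewer than 2 per-segment curves could be fitted")
    stack = np.log(np.stack(per_seg))
    support = np.isfinite(stack).sum(axis=0)
    # each per-segment curve is the common effect up to a multiplicative
    # constant (its own anchor); align the log-curves to the composite
    # median before combining, otherwise the median mixes scales
    offsets = np.zeros(len(stack))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(4):
            comp = np.nanmedian(stack - offsets[:, None], axis=0)
            new = np.array([
                np.nanmedian(row - comp) if np.isfinite(row - comp).any() else off
                for row, off in zip(stack, offsets)
            ])
            if np.allclose(new, offsets, atol=1e-10):
                offsets = new
                break
            offsets = new
        median = np.exp(np.nanmedian(stack - offsets[:, None], axis=0))
    good = support >= 2
    if not good.any():
        raise ValueError("no grid point supported by >= 2 segments")
    # nearest-supported value elsewhere
    idx = np.flatnonzero(good)
    filled = median.copy()
    for i in np.flatnonzero(~good):
        filled[i] = median[idx[np.argmin(np.abs(idx - i))]]
    return GCCurve(gc_grid=grid, effect=filled, support=support)


def seqnorm(
    profile: RCProfile,
    span: float = 0.3,
    min_windows: int = 20,
    penalty: float | None = None,
    covariate: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    rescale: bool = True,
) -> tuple[RCProfile, GCCurve | None]:
    """Two-pass, segment-wise GC-bias correction.

    Steps: (1) single-pass correction; (2) segmentation of the corrected
    profile; (3) segment screening; (4) per selected segment, raw values
    are divided by the segment's raw median (centering removes copy-number
    differences and with them the copy-number–GC correlation); (5) a local
    regression per segment on a common grid restricted to the segment's
    covariate range; (6) the pointwise median across segments (support >=
    2, nearest value elsewhere) is the final curve; (7) raw values are
    corrected by it and rescaled to the input median.

    If segmentation or selection cannot produce enough usable segments,
    the single-pass result is returned with a warning (``meta`` records
    the fallback); the degradation is never silent.

    ``covariate`` substitutes the regression covariate (e.g. a matched
    normal's values) for GC; ``grid`` must then be supplied to match.
    Returns the corrected profile and the final curve (None on fallback).
    """
    from .segment_call import segment  # local import: avoid cycle

    raw = profile.values.astype(float)
    gc = covariate if covariate is not None else profile.df["gc"].to_numpy(float)
    gc = np.asarray(gc, dtype=float)
    if grid is None:
        grid = DEFAULT_GC_GRID

    # pass 1
    if covariate is None:
        first = single_pass_correct(profile, span=span, rescale=rescale)
    else:
        keep0 = ~profile.mask
        curve0 = gc_local_fit(raw[keep0], gc[keep0], span=span, grid=grid)
        first = profile.copy()
        eff0 = curve0.evaluate(gc)
        v0 = np.where(np.isfinite(eff0), raw / np.where(np.isfinite(eff0), eff0, 1), raw)
        first.set_values(v0)

    def fallback(reason: str) -> tuple[RCProfile, None]:
        warnings.warn(f"seqnorm fell back to single-pass correction: {reason}",
                      stacklevel=2)
        out = first.copy()
        out.meta["normalization"] = "single_pass_fallback"
        out.meta["seqnorm_fallback_reason"] = reason
        return out, None

    keep = ~profile.mask & np.isfinite(first.values) & np.isfinite(gc)
    if keep.sum() < 3 * min_windows:
        return fallback("too few usable windows")

    seg_set = segment(first, penalty=penalty)
    # map segments to (start, stop) index pairs over the kept-window subvectors
    kept_idx = np.flatnonzero(keep)
    pos_of = np.full(len(profile), -1)
    pos_of[kept_idx] = np.arange(len(kept_idx))
    segments: list[tuple[int, int]] = []
    for _, row in seg_set.df.iterrows():
        members = kept_idx[(kept_idx >= row.start_idx) & (kept_idx <= row.end_idx)]
        if len(members):
            segments.append((int(pos_of[members[0]]), int(pos_of[members[-1]]) + 1))
    if len(segments) < 3:
        return fallback(f"only {len(segments)} segments")

    raw_kept = raw[keep]
    gc_kept = gc[keep]
    first_kept = first.values[keep]
    selection = select_segments(
        segments, first_kept, gc_kept, min_windows=min_windows
    )
    if selection.failed or selection.selected.sum() < 3:
        return fallback("segment selection failed")

    try:
        curve = _segment_median_curve(
            raw_kept, gc_kept, segments, selection, span=span, grid=grid
        )
    except ValueError as exc:
        return fallback(str(exc))

    # renormalize the median curve at the median covariate of usable windows
    anchor = float(np.interp(np.median(gc_kept), curve.gc_grid, curve.effect))
    curve = GCCurve(curve.gc_grid, curve.effect / anchor, curve.support)

    out = profile.copy()
    eff = curve.evaluate(gc)
    corrected = np.where(np.isfinite(eff), raw / np.where(np.isfinite(eff), eff, 1), raw)
    if rescale:
        sel = keep & np.isfinite(corrected)
        med_in, med_out = np.median(raw[sel]), np.median(corrected[sel])
        if med_out > 0:
            corrected *= med_in / med_out
    out.set_values(corrected)
    out.meta["normalization"] = "seqnorm"
    return out, curve


# ---------------------------------------------------------------------------
# matched-normal normalization


def paired_normalize(
    tumor: RCProfile, normal: RCProfile, mode: str = "ratio"
) -> RCProfile:
    """Normalize a tumour profile against its matched normal.

    ``mode="ratio"`` divides tumour by normal per window and rescales the
    unmasked median to 1.  Zero-count normal windows receive a 0.5
    pseudocount and are flagged.  ``mode="seqnorm"`` runs the two-pass
    machinery with the normal's values as the regression covariate in
    place of GC.
    """
    tumor.check_same_grid(normal)
    t = tumor.values.astype(float)
    n = normal.values.astype(float)
    out = tumor.copy()
    if mode == "ratio":
        zero = n == 0
        n_adj = np.where(zero, 0.5, n)
        ratio = t / n_adj
        keep = ~tumor.mask & np.isfinite(ratio)
        med = np.median(ratio[keep])
        if med > 0:
            ratio = ratio / med
        out.set_values(ratio)
        out.meta["normalization"] = "paired_ratio"
        if zero.any():
            out.meta["normal_zero_windows"] = int(zero.sum())
        return out
    if mode == "seqnorm":
        zero = n == 0
        n_adj = np.where(zero, 0.5, n)
        lo, hi = np.nanquantile(n_adj, [0.001, 0.999])
        grid = np.linspace(lo, hi, 101)
        corrected, _ = seqnorm(tumor, covariate=n_adj, grid=grid)
        corrected.meta["normalization"] = "paired_seqnorm"
        if zero.any():
            corrected.meta["normal_zero_windows"] = int(zero.sum())
        return corrected
    raise ValueError(f"unknown paired normalization mode {mode!r}")
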