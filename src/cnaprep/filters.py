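"""The five window filters and their orchestration.

Filters operate on an :class:`~cnaprep.core.RCProfile` and each produce a
boolean mask (True = window removed).  They are independent; the combined
mask is their union.  The distinctive filter is the automatic trimming of
extreme values: candidate thresholds are scanned from the distribution
tail inward and a Wald–Wolfowitz runs test on the genome-order positions
of exceeding windows separates scattered outliers (random positions) from
genuine copy-number blocks (adjacent positions), which must survive.
Before trimming, values are corrected once against GC content so that
windows extreme only because of extreme GC content are not trimmed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core import FilterUnavailableError, RCProfile


# ---------------------------------------------------------------------------
# Wald–Wolfowitz runs test


@dataclass(frozen=True)
class RunsTestResult:
    """Normal-approximation runs-test statistic for a binary sequence."""

    n1: int  #: number of successes (ones)
    n0: int  #: number of failures (zeros)
    R: int  #: observed number of runs
    mu_R: float  #: expected runs under randomness
    sigma_R: float  #: standard deviation of runs under randomness
    z: float  #: (R - mu_R) / sigma_R; NaN when degenerate

    @property
    def degenerate(self) -> bool:
        return not math.isfinite(self.z)


def runs_test_z(indicator) -> RunsTestResult:
    """Runs-test z statistic of a binary sequence in genome order.

    With ``n1`` ones, ``n0`` zeros and ``n = n1 + n0``::

        mu_R    = 2 n1 n0 / n + 1
        sigma_R = sqrt(2 n1 n0 (2 n1 n0 - n) / (n^2 (n - 1)))

    An all-zero or all-one sequence is degenerate: counts and ``R`` are
    reported but ``z`` (and the moments, where undefined) are NaN.
    """
    ind = np.asarray(indicator, dtype=bool)
    n = len(ind)
    if n < 2:
        raise ValueError("runs test requires a sequence of length >= 2")
    n1 = int(ind.sum())
    n0 = n - n1
    R = int(1 + np.count_nonzero(ind[1:] != ind[:-1]))
    if n1 == 0 or n0 == 0:
        return RunsTestResult(n1=n1, n0=n0, R=R, mu_R=np.nan, sigma_R=np.nan, z=np.nan)
    mu = 2.0 * n1 * n0 / n + 1.0
    var = 2.0 * n1 * n0 * (2.0 * n1 * n0 - n) / (n * n * (n - 1.0))
    sigma = math.sqrt(var)
    z = (R - mu) / sigma if sigma > 0 else np.nan
    return RunsTestResult(n1=n1, n0=n0, R=R, mu_R=mu, sigma_R=sigma, z=z)


# ---------------------------------------------------------------------------
# automatic trimming


#: default candidate quantiles, scanned from the extreme tail inward
DEFAULT_QUANTILE_GRID = np.linspace(0.9999, 0.95, 200)

#: minimum exceeding windows for a runs test to be meaningful
MIN_EXCEED = 5

#: jump floor on the increase of |z| between consecutive candidates
JUMP_FLOOR = 2.0


@dataclass
class TrimResult:
    """Two-sided trimming thresholds with the |z| traces behind them."""

    lower_threshold: float
    upper_threshold: float
    z_trace: list[tuple[float, float]]  #: (candidate threshold, |z|) pairs, both tails
    mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def auto_trim_threshold(
    values,
    tail: str = "upper",
    quantile_grid=None,
    min_exceed: int = MIN_EXCEED,
    jump_floor: float = JUMP_FLOOR,
    return_trace: bool = False,
):
    """Set a trimming threshold on one tail via the runs test.

    Candidate thresholds are taken at ``quantile_grid`` quantiles of the
    finite values, scanned from the extreme quantile inward.  For every
    candidate with at least ``min_exceed`` exceeding windows the |z| of
    the exceedance indicator (in genome order) is computed.  Scattered
    outliers leave |z| near zero; when the scan reaches a block of
    adjacent windows (a copy-number alteration) |z| rises sharply.  The
    threshold is placed just before that change: at the first increase of
    |z| of at least ``jump_floor`` between consecutive candidates, the
    adjacent exceeders at the post-jump candidate are identified (windows
    with another exceeder within two positions) and the threshold is the
    most extreme candidate still above all of them, so the whole block
    survives.  If no increase reaches the floor, the innermost scanned
    quantile is returned (pure-outlier regime).  If no candidate ever has
    ``min_exceed`` exceeders, the most extreme candidate is returned.

    ``tail="lower"`` applies the identical algorithm to negated values.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 200:
        raise ValueError("automatic trimming requires >= 200 finite values")
    sign = 1.0 if tail == "upper" else -1.0
    w = sign * v[finite]

    grid = DEFAULT_QUANTILE_GRID if quantile_grid is None else np.asarray(quantile_grid)
    cand = np.quantile(w, grid)

    absz = np.full(len(cand), np.nan)
    for j, t in enumerate(cand):
        ind = w > t
        if ind.sum() >= min_exceed:
            r = runs_test_z(ind)
            if not r.degenerate:
                absz[j] = abs(r.z)
    trace = [(sign * float(c), float(z)) for c, z in zip(cand, absz)]

    threshold = _pick_threshold(w, cand, absz, jump_floor)
    threshold = sign * float(threshold)
    if return_trace:
        return threshold, trace
    return threshold


def _clustered_max(w: np.ndarray, threshold: float) -> float | None:
    """Max value among exceeders strictly adjacent to another exceeder."""
    exceed_idx = np.flatnonzero(w > threshold)
    if len(exceed_idx) < 2:
        return None
    gaps = np.diff(exceed_idx)
    near = np.zeros(len(exceed_idx), dtype=bool)
    near[1:] |= gaps <= 1
    near[:-1] |= gaps <= 1
    if not near.any():
        return None
    return float(w[exceed_idx[near]].max())


def _pick_threshold(
    w: np.ndarray, cand: np.ndarray, absz: np.ndarray, jump_floor: float
) -> float:
    """Locate the sudden change of randomness along the candidate scan.

    The scan goes from the extreme tail inward.  While only scattered
    outliers exceed the candidate, |z| stays small; a rise of |z| of at
    least ``jump_floor`` above its running minimum (or an already
    clustered extreme tail, |z| >= 3 at the first usable candidate) marks
    the entry of an adjacent block — cumulative rise, because a block
    entering window by window climbs gradually and single-step
    differences alone would miss it.  The candidate with the largest |z|
    from the change onward has the block maximally included; the
    clustered exceeders there delimit the block, and the threshold is the
    most extreme candidate still above all of them.
    """
    finite = np.flatnonzero(np.isfinite(absz))
    if len(finite) == 0:
        return float(cand[0])  # nothing to trim beyond the extreme candidate
    j0 = finite[0]

    detect: int | None = None
    if absz[j0] >= 3.0:
        detect = j0  # adjacency present from the start: block is the extreme
    else:
        runmin = np.inf
        for j in range(len(cand)):
            if not np.isfinite(absz[j]):
                continue
            runmin = min(runmin, absz[j])
            if absz[j] - runmin >= jump_floor:
                detect = j
                break
    if detect is None:
        return float(cand[-1])  # innermost quantile: pure-outlier regime

    # last candidate before the climb began: the fallback threshold
    low = float(np.nanmin(absz[: detect + 1]))
    jump_at = j0
    for j in range(detect, j0 - 1, -1):
        if np.isfinite(absz[j]) and absz[j] <= low + 0.25 * jump_floor:
            jump_at = j
            break

    rest = absz[jump_at:]
    k = jump_at + int(np.nanargmax(np.where(np.isfinite(rest), rest, -np.inf)))
    block_max = _clustered_max(w, cand[k])
    if block_max is not None:
        above = cand[cand > block_max]
        if len(above):
            return float(above.min())
        return float(np.max(w))  # block is the most extreme feature: trim nothing
    return float(cand[jump_at])


def trim_filter(
    profile: RCProfile,
    normal: RCProfile | None = None,
    pre_correct: bool = True,
    span: float = 0.3,
    quantile_grid=None,
    jump_floor: float = JUMP_FLOOR,
) -> TrimResult:
    """Two-sided trimming of extreme values, GC- and CNA-aware.

    Values are first corrected once against GC content (single-pass local
    regression) so that extreme-GC windows are not mistaken for extreme
    values; if GC is missing on more than half the windows the correction
    is refused and trimming runs on raw values with a warning.

    Windows already masked by other filters are excluded when estimating
    the thresholds; the thresholds are then applied to every window.

    When a matched ``normal`` profile is supplied, thresholds are
    estimated on the normal's corrected values and the mask is the set of
    windows extreme *in the normal* — tumour copy-number alterations have
    no counterpart in the normal and therefore survive.
    """
    from .normalize import single_pass_correct  # local import: avoid cycle

    source = normal if normal is not None else profile
    if normal is not None:
        profile.check_same_grid(normal)

    gc = source.df["gc"].to_numpy(dtype=float)
    if pre_correct and np.isfinite(gc).mean() <= 0.5:
        warnings.warn(
            "GC missing on > 50% of windows: trimming on raw values",
            stacklevel=2,
        )
        pre_correct = False

    if pre_correct:
        corrected = single_pass_correct(source, span=span).values
    else:
        corrected = source.values.astype(float)

    med = np.nanmedian(corrected[~source.mask])
    if med > 0:
        corrected = corrected / med  # scale-free thresholds

    est = corrected.copy()
    est[source.mask] = np.nan  # other filters' windows excluded from estimation

    upper, trace_u = auto_trim_threshold(
        est, tail="upper", quantile_grid=quantile_grid,
        jump_floor=jump_floor, return_trace=True,
    )
    lower, trace_l = auto_trim_threshold(
        est, tail="lower", quantile_grid=quantile_grid,
        jump_floor=jump_floor, return_trace=True,
    )
    with np.errstate(invalid="ignore"):
        mask = (corrected > upper) | (corrected < lower)
    mask &= np.isfinite(corrected)
    return TrimResult(
        lower_threshold=float(lower),
        upper_threshold=float(upper),
        z_trace=trace_u + trace_l,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# the four simple filters


def pem_filter(profile: RCProfile, max_improper_prop: float) -> np.ndarray:
    """Mask windows whose improper-read proportion exceeds the maximum."""
    if not (0 < max_improper_prop <= 1):
        raise ValueError("max_improper_prop must be in (0, 1]")
    if not profile.paired:
        raise FilterUnavailableError(
            "paired-end filter unavailable: profile is single-end"
        )
    prop = profile.df["improper_prop"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mask = prop > max_improper_prop
    return np.where(np.isfinite(prop), mask, False)


def mapq_filter(profile: RCProfile, min_mean_mapq: float) -> np.ndarray:
    """Mask windows by mean proper-read mapping quality.

    Windows with no proper reads are masked too: they carry no evidence
    of mappability.
    """
    mq = profile.df["mean_mapq"].to_numpy(dtype=float)
    proper = profile.df["proper_count"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        low = mq < min_mean_mapq
    mask = np.where(np.isfinite(mq), low, False)
    mask |= proper == 0
    return mask


def cnv_filter(profile: RCProfile, max_cnv_overlap: float = 0.0) -> np.ndarray:
    """Mask windows overlapping common CNV regions beyond the allowed fraction."""
    ov = profile.df["cnv_overlap"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mask = ov > max_cnv_overlap
    return np.where(np.isfinite(ov), mask, False)


def mappability_filter(profile: RCProfile, min_mappability: float) -> np.ndarray:
    """Mask low-mappability windows; missing mappability passes (flagged upstream)."""
    mp = profile.df["mappability"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mask = mp < min_mappability
    return np.where(np.isfinite(mp), mask, False)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class FilterConfig:
    """Which filters to run and with what thresholds.

    ``None`` disables a filter.  There are deliberately no numeric
    defaults for the paired-end and mapping-quality thresholds: suggested
    starting values are 0.5 and 30, but they must be chosen explicitly.
    """

    pem_max: float | None = None
    mapq_min: float | None = None
    trim: bool = False
    cnv_max: float | None = None
    mappability_min: float | None = None
    trim_span: float = 0.3
    skip_unavailable: bool = False


@dataclass
class FilterReport:
    """Per-filter counts, Venn overlap cells and retained fraction."""

    n_windows: int
    applied: list[str]
    skipped: dict[str, str]  #: filter -> reason
    masked_counts: dict[str, int]
    venn: dict[str, int]  #: "a&b" style subset keys -> exclusive cell count
    n_union: int
    retained_fraction: float
    thresholds: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_windows": self.n_windows,
            "applied": self.applied,
            "skipped": self.skipped,
            "masked_counts": self.masked_counts,
            "venn": self.venn,
            "n_union": self.n_union,
            "retained_fraction": self.retained_fraction,
            "thresholds": self.thresholds,
            "flags": self.flags,
        }


def venn_cells(masks: dict[str, np.ndarray]) -> dict[str, int]:
    """Exclusive Venn cell counts for a set of boolean masks.

    Key ``"a&b"`` counts windows masked by exactly {a, b}.  Cell counts
    sum to the size of the union.
    """
    names = sorted(masks)
    cells: dict[str, int] = {}
    if not names:
        return cells
    stack = np.stack([masks[n] for n in names])
    for r in range(1, len(names) + 1):
        for subset in combinations(range(len(names)), r):
            inc = np.ones(stack.shape[1], dtype=bool)
            for i in range(len(names)):
                if i in subset:
                    inc &= stack[i]
                else:
                    inc &= ~stack[i]
            cells["&".join(names[i] for i in subset)] = int(inc.sum())
    return cells


def apply_filters(
    profile: RCProfile,
    config: FilterConfig,
    normal: RCProfile | None = None,
) -> tuple[RCProfile, FilterReport]:
    """Run the configured filters and combine their masks.

    The four marginal filters run first (their order is irrelevant: the
    combined mask is a union); trimming runs last because windows masked
    by the others are excluded from its threshold estimation.  Unavailable
    filters either raise or, with ``skip_unavailable``, are reported as
    skipped with a reason.
    """
    out = profile.copy()
    skipped: dict[str, str] = {}
    thresholds: dict = {}
    flags: dict = {}
    masks: dict[str, np.ndarray] = {}

    def unavailable(name: str, reason: str) -> None:
        if config.skip_unavailable:
            skipped[name] = reason
        else:
            raise FilterUnavailableError(f"{name} filter unavailable: {reason}")

    if config.pem_max is not None:
        if out.paired:
            masks["pem"] = pem_filter(out, config.pem_max)
            thresholds["pem_max"] = config.pem_max
        else:
            unavailable("pem", "single-end data")

    if config.mapq_min is not None:
        masks["mapq"] = mapq_filter(out, config.mapq_min)
        thresholds["mapq_min"] = config.mapq_min

    if config.cnv_max is not None:
        ov = out.df["cnv_overlap"].to_numpy(dtype=float)
        if not np.isfinite(ov).any():
            unavailable("cnv", "no CNV annotation")
        else:
            masks["cnv"] = cnv_filter(out, config.cnv_max)
            thresholds["cnv_max"] = config.cnv_max

    if config.mappability_min is not None:
        mp = out.df["mappability"].to_numpy(dtype=float)
        if not np.isfinite(mp).any():
            unavailable("mappability", "no mappability annotation")
        else:
            masks["mappability"] = mappability_filter(out, config.mappability_min)
            thresholds["mappability_min"] = config.mappability_min
            n_missing = int((~np.isfinite(mp)).sum())
            if n_missing:
                flags["mappability_missing_windows"] = n_missing

    for name, mask in masks.items():
        out.set_mask(name, mask)

    if config.trim:
        try:
            trim = trim_filter(out, normal=normal, span=config.trim_span)
        except ValueError as exc:
            unavailable("trim", str(exc))
        else:
            masks["trim"] = trim.mask
            out.set_mask("trim", trim.mask)
            thresholds["trim_lower"] = trim.lower_threshold
            thresholds["trim_upper"] = trim.upper_threshold
            flags["trim_z_trace"] = [
                (round(t, 6), None if not math.isfinite(z) else round(z, 4))
                for t, z in trim.z_trace
            ]

    cells = venn_cells(masks)
    union = int(out.mask.sum())
    report = FilterReport(
        n_windows=len(out),
        applied=sorted(masks),
        skipped=skipped,
        masked_counts={k: int(v.sum()) for k, v in masks.items()},
        venn=cells,
        n_union=union,
        retained_fraction=1.0 - union / len(out) if len(out) else 1.0,
        thresholds=thresholds,
        flags=flags,
    )
    return out, report
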