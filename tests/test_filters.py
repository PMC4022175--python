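import itertools
import math

import numpy as np
import pytest

from cnaprep.core import FilterUnavailableError
from cnaprep.filters import (
    FilterConfig,
    apply_filters,
    auto_trim_threshold,
    cnv_filter,
    mapq_filter,
    mappability_filter,
    pem_filter,
    runs_test_z,
    trim_filter,
    venn_cells,
)

from conftest import make_profile


# ---------------------------------------------------------------------------
# runs test


def enumerate_runs_moments(n1: int, n0: int) -> tuple[float, float]:
    """Exact mean and sd of run counts over all arrangements (oracle)."""
    runs = []
    n = n1 + n0
    for positions in itertools.combinations(range(n), n1):
        seq = np.zeros(n, dtype=bool)
        seq[list(positions)] = True
        runs.append(1 + int(np.count_nonzero(seq[1:] != seq[:-1])))
    runs = np.asarray(runs, dtype=float)
    return float(runs.mean()), float(runs.std(ddof=0))


class TestRunsTest:
    def test_alternating_example(self):
        r = runs_test_z([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        assert r.R == 10
        assert r.mu_R == pytest.approx(6.0)
        assert r.z == pytest.approx(2.683, abs=1e-3)

    def test_block_example_symmetric(self):
        r = runs_test_z([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        assert r.R == 2
        assert r.z == pytest.approx(-2.683, abs=1e-3)

    def test_degenerate_one_class(self):
        r = runs_test_z([1, 1, 1, 1])
        assert r.degenerate
        assert math.isnan(r.z)

    def test_too_short(self):
        with pytest.raises(ValueError):
            runs_test_z([1])

    @pytest.mark.parametrize("n", range(2, 11))
    def test_moments_match_enumeration(self, n):
        # formula moments equal exact moments of the enumerated runs
        # distribution for every composition of every length <= 10
        for n1 in range(1, n):
            n0 = n - n1
            mu, sigma = enumerate_runs_moments(n1, n0)
            seq = [1] * n1 + [0] * n0
            r = runs_test_z(seq)
            assert r.mu_R == pytest.approx(mu, abs=1e-12)
            assert r.sigma_R == pytest.approx(sigma, rel=1e-12)

    def test_r_counts_runs(self):
        assert runs_test_z([1, 1, 0, 0, 1, 0]).R == 4


# ---------------------------------------------------------------------------
# simple filters


class TestSimpleFilters:
    def test_pem_masks_high_improper(self):
        p = make_profile([10] * 3, improper_prop=[0.6, 0.0, np.nan])
        mask = pem_filter(p, 0.5)
        assert mask.tolist() == [True, False, False]

    def test_pem_unavailable_on_single_end(self):
        p = make_profile([10] * 3, paired=False)
        with pytest.raises(FilterUnavailableError):
            pem_filter(p, 0.5)

    def test_pem_uniform_expectation(self):
        rng = np.random.default_rng(0)
        n = 10_000
        p = make_profile(np.full(n, 10.0), improper_prop=rng.uniform(0, 1, n))
        frac = pem_filter(p, 0.9).mean()
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_mapq_boundary_strict_less_than(self):
        p = make_profile([10] * 3, mean_mapq=[10.0, 30.0, 60.0])
        mask = mapq_filter(p, 30)
        assert mask.tolist() == [True, False, False]

    def test_mapq_masks_no_proper_reads(self):
        p = make_profile([10, 10], mean_mapq=[np.nan, 60.0],
                         proper_count=[0, 10])
        assert mapq_filter(p, 30).tolist() == [True, False]

    def test_mapq_all_high_none_masked(self):
        p = make_profile([10] * 100, mean_mapq=[60.0] * 100)
        assert mapq_filter(p, 30).sum() == 0

    @pytest.mark.parametrize(
        "overlap,thr,expected",
        [(0.5, 0.0, True), (0.0, 0.0, False), (0.3, 0.5, False)],
    )
    def test_cnv_filter(self, overlap, thr, expected):
        p = make_profile([10.0], cnv_overlap=[overlap])
        assert cnv_filter(p, thr)[0] == expected

    @pytest.mark.parametrize(
        "mp,thr,expected",
        [(0.2, 0.5, True), (1.0, 1.0, False), (np.nan, 0.5, False)],
    )
    def test_mappability_filter(self, mp, thr, expected):
        p = make_profile([10.0], mappability=[mp])
        assert mappability_filter(p, thr)[0] == expected


# ---------------------------------------------------------------------------
# automatic trimming


def cna_outlier_values(seed, n=2000, block=20, outliers=6):
    """Baseline 1 +/- 0.05 with an adjacent block at 3 and scattered 6s."""
    rng = np.random.default_rng(seed)
    v = rng.normal(1, 0.05, n + block + outliers)
    start = n // 2
    v[start:start + block] = rng.normal(3, 0.05, block)
    scatter = np.linspace(50, len(v) - 50, outliers).astype(int)
    scatter = scatter[(scatter < start - 5) | (scatter > start + block + 5)]
    v[scatter] = rng.normal(6, 0.05, len(scatter))
    return v, np.arange(start, start + block), scatter


class TestAutoTrim:
    def test_block_survives_outliers_masked(self):
        v, block_idx, scatter_idx = cna_outlier_values(seed=0)
        thr = auto_trim_threshold(v, tail="upper")
        assert 3.2 < thr < 5.5
        assert (v[block_idx] <= thr).all()
        assert (v[scatter_idx] > thr).all()

    def test_pure_noise_masks_at_most_tail(self):
        rng = np.random.default_rng(1)
        v = rng.normal(1, 0.05, 2000)
        thr = auto_trim_threshold(v, tail="upper")
        assert (v > thr).mean() <= 0.055

    def test_shuffled_block_no_longer_protected(self):
        v, block_idx, scatter_idx = cna_outlier_values(seed=0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(v))
        shuffled = v[perm]
        thr = auto_trim_threshold(shuffled, tail="upper")
        # without adjacency the block windows look like outliers: a
        # threshold above their level is no longer required and (some of)
        # them join the masked set
        assert thr < 5.0
        former_block = np.flatnonzero(np.isin(perm, block_idx))
        assert (shuffled[former_block] > thr).sum() >= len(block_idx) // 4

    def test_lower_tail_mirrors_upper(self):
        rng = np.random.default_rng(5)
        v = rng.normal(1, 0.05, 2000)
        deletion = slice(600, 800)
        v[deletion] = rng.normal(0.5, 0.03, 200)
        thr = auto_trim_threshold(v, tail="lower")
        # the deletion block survives almost entirely; the baseline does too
        assert (v[deletion] < thr).sum() <= 2
        assert thr < 0.6

    def test_requires_enough_values(self):
        with pytest.raises(ValueError):
            auto_trim_threshold(np.ones(100), tail="upper")

    def test_tail_validation(self):
        with pytest.raises(ValueError):
            auto_trim_threshold(np.ones(300), tail="middle")


class TestTrimFilter:
    @staticmethod
    def gc_effect_profile(seed=0, n=3000, coef=3.0):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter1d

        gc = 0.45 + 0.06 * gaussian_filter1d(rng.standard_normal(n), 3)
        gc += 0.02 * rng.standard_normal(n)
        values = 100 * np.exp(coef * (gc - 0.45)) * rng.normal(1, 0.03, n)
        return make_profile(values, gc=gc), gc

    def test_gc_precorrection_makes_trimming_gc_neutral(self):
        profile, gc = self.gc_effect_profile()
        lo, hi = np.quantile(gc, [0.05, 0.95])
        gc_extreme = (gc < lo) | (gc > hi)
        with_corr = trim_filter(profile.copy(), pre_correct=True)
        without = trim_filter(profile.copy(), pre_correct=False)
        # on a pure GC-effect profile the extreme values ARE the extreme-GC
        # windows; pre-correction decouples the two
        assert gc_extreme[without.mask].mean() > 0.5
        assert gc_extreme[with_corr.mask].mean() < 0.2

    def test_paired_mode_protects_tumor_amplification(self):
        rng = np.random.default_rng(2)
        n = 2000
        gc = np.full(n, 0.45)
        normal_vals = rng.normal(100, 5, n)
        tumor_vals = rng.normal(100, 5, n)
        artifacts = np.array([50, 300, 550, 1300, 1600, 1850, 1990])
        normal_vals[artifacts] *= 3.0  # shared technical artifacts
        tumor_vals[artifacts] *= 3.0
        # germline-variable regions: adjacent, mildly shifted in the normal
        normal_vals[400:420] *= 1.5
        normal_vals[1450:1470] *= 0.6
        amp = slice(900, 1100)
        tumor_vals[amp] *= 2.0  # 200-window amplification, tumour only
        tumor = make_profile(tumor_vals, gc=gc)
        normal = make_profile(normal_vals, gc=gc)
        result = trim_filter(tumor, normal=normal)
        # thresholds come from the normal: artifacts masked, CNA untouched
        assert result.mask[artifacts].all()
        assert not result.mask[amp].any()

    def test_unpaired_no_outliers_bounded_masking(self):
        rng = np.random.default_rng(3)
        profile = make_profile(rng.normal(100, 5, 2000), gc=np.full(2000, 0.45))
        result = trim_filter(profile, pre_correct=False)
        assert result.mask.mean() <= 2 * (1 - 0.95)

    def test_missing_gc_falls_back_with_warning(self):
        rng = np.random.default_rng(4)
        profile = make_profile(rng.normal(100, 5, 1000))  # no gc at all
        with pytest.warns(UserWarning, match="GC missing"):
            result = trim_filter(profile)
        assert result.upper_threshold > result.lower_threshold

    def test_thresholds_ordered_and_trace_present(self):
        rng = np.random.default_rng(5)
        profile = make_profile(rng.normal(100, 5, 1000), gc=np.full(1000, 0.45))
        result = trim_filter(profile, pre_correct=False)
        assert result.lower_threshold < result.upper_threshold
        assert len(result.z_trace) > 0


# ---------------------------------------------------------------------------
# orchestration


class TestApplyFilters:
    def test_venn_cells_sum_to_union(self):
        masks = {
            "a": np.array([True, True, False, False, False]),
            "b": np.array([False, True, True, False, False]),
        }
        cells = venn_cells(masks)
        assert cells["a"] == 1
        assert cells["b"] == 1
        assert cells["a&b"] == 1
        union = np.logical_or.reduce(list(masks.values())).sum()
        assert sum(cells.values()) == union

    def test_three_filter_venn_brute_force(self):
        rng = np.random.default_rng(0)
        masks = {k: rng.random(200) < 0.3 for k in ("a", "b", "c")}
        cells = venn_cells(masks)
        # brute-force enumeration of exclusive membership per window
        expected: dict[str, int] = {}
        for i in range(200):
            members = [k for k in sorted(masks) if masks[k][i]]
            if members:
                key = "&".join(members)
                expected[key] = expected.get(key, 0) + 1
        assert {k: v for k, v in cells.items() if v} == expected
        union = np.logical_or.reduce(list(masks.values())).sum()
        assert sum(cells.values()) == union

    def test_all_disabled_keeps_everything(self):
        p = make_profile([10.0] * 50)
        out, report = apply_filters(p, FilterConfig())
        assert out.mask.sum() == 0
        assert report.retained_fraction == 1.0

    def test_combined_mask_is_union(self):
        p = make_profile(
            [10.0] * 4,
            improper_prop=[0.9, 0.1, 0.1, 0.1],
            mean_mapq=[60.0, 10.0, 60.0, 60.0],
        )
        out, report = apply_filters(
            p, FilterConfig(pem_max=0.5, mapq_min=30)
        )
        assert out.mask.tolist() == [True, True, False, False]
        assert report.n_union == 2

    def test_order_invariance_of_combined_mask(self):
        rng = np.random.default_rng(1)
        n = 3000
        from scipy.ndimage import gaussian_filter1d

        gc = 0.45 + 0.05 * gaussian_filter1d(rng.standard_normal(n), 3)
        p = make_profile(
            rng.normal(100, 8, n),
            gc=gc,
            improper_prop=rng.beta(2, 20, n),
            mean_mapq=rng.normal(55, 8, n),
            cnv_overlap=(rng.random(n) < 0.02) * rng.random(n),
            mappability=rng.beta(8, 1, n),
        )
        config = FilterConfig(
            pem_max=0.3, mapq_min=40, trim=True, cnv_max=0.0, mappability_min=0.5
        )
        out1, _ = apply_filters(p.copy(), config)
        out2, _ = apply_filters(p.copy(), config)
        assert np.array_equal(out1.mask, out2.mask)
        # union of per-filter masks equals the combined mask, any order
        names = out1.filter_names()
        for perm in ([*reversed(names)], sorted(names)):
            acc = np.zeros(n, dtype=bool)
            for name in perm:
                acc |= out1.get_mask(name)
            assert np.array_equal(acc, out1.mask)

    def test_pem_on_single_end_raises_unless_skipped(self):
        p = make_profile([10.0] * 10, paired=False)
        with pytest.raises(FilterUnavailableError):
            apply_filters(p, FilterConfig(pem_max=0.5))
        out, report = apply_filters(
            p, FilterConfig(pem_max=0.5, skip_unavailable=True)
        )
        assert report.skipped == {"pem": "single-end data"}
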