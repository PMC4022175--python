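"""Pipeline orchestration: input planning, configuration, end-to-end runs.

The planner inspects what is available — paired-end flags, annotation,
matched normal — and selects the applicable steps, logging each skipped
step with its reason.  ``run_pipeline`` executes the plan
deterministically; the per-chromosome segmentation stage may fan out over
a worker pool but results are merged in chromosome order, so outputs are
identical for any worker count.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import filters, normalize, segment_call
from .core import CnaprepError, RCProfile, chromosome_slices
from .summarize import (
    DEFAULT_WINDOW_SIZE,
    annotate,
    read_annotation_table,
    read_bed,
    summarize as summarize_sam,
)

logger = logging.getLogger("cnaprep")


class PlanError(CnaprepError):
    """The requested analysis cannot be planned from the available inputs."""


@dataclass
class PipelineConfig:
    """Flat, serializable pipeline configuration.

    Unset paths/thresholds disable the corresponding step.  The config
    round-trips through a ``key = value`` text file.
    """

    sam: str = ""
    profile: str = ""  # pre-summarized profile TSV (alternative to sam)
    normal_sam: str = ""
    normal_profile: str = ""
    annot: str = ""
    cnv_bed: str = ""
    out_prefix: str = "cnaprep_out"
    window_size: int = DEFAULT_WINDOW_SIZE
    pem_max: float = float("nan")
    mapq_min: float = float("nan")
    trim: bool = True
    cnv_max: float = 0.0
    mappability_min: float = float("nan")
    method: str = "seqnorm"  # or "loess" (single pass) or "ratio"
    span: float = 0.3
    penalty: float = float("nan")
    thresholds: str = ""  # comma-separated; empty -> suggested
    baseline_cn: int = 2
    seed: int = 0
    workers: int = 1
    skip_unavailable: bool = True

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise PlanError(f"unknown config key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(raw)
                elif isinstance(current, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class PlanStep:
    name: str
    run: bool
    reason: str = ""


def plan(
    paired: bool,
    has_gc: bool,
    has_mappability: bool,
    has_cnv: bool,
    has_normal: bool,
    config: PipelineConfig,
) -> list[PlanStep]:
    """Choose analysis steps from the input inventory.

    Raises :class:`PlanError` when normalization is impossible (no GC
    annotation and no matched normal).
    """
    steps: list[PlanStep] = []
    want_pem = not np.isnan(config.pem_max)
    want_mapq = not np.isnan(config.mapq_min)
    want_mappability = not np.isnan(config.mappability_min)

    if want_pem and paired:
        steps.append(PlanStep("pem_filter", True))
    elif want_pem:
        steps.append(PlanStep("pem_filter", False, "single-end data"))
    if want_mapq:
        steps.append(PlanStep("mapq_filter", True))
    if config.trim:
        if has_normal:
            steps.append(PlanStep("trim_filter", True, "thresholds from matched normal"))
        elif has_gc:
            steps.append(PlanStep("trim_filter", True))
        else:
            steps.append(PlanStep("trim_filter", True, "no GC: trimming on raw values"))
    if has_cnv:
        steps.append(PlanStep("cnv_filter", True))
    else:
        steps.append(PlanStep("cnv_filter", False, "no CNV annotation"))
    if want_mappability and has_mappability:
        steps.append(PlanStep("mappability_filter", True))
    elif want_mappability:
        steps.append(PlanStep("mappability_filter", False, "no mappability annotation"))

    if has_normal:
        mode = config.method if config.method in ("ratio", "seqnorm") else "ratio"
        steps.append(PlanStep(f"paired_normalize[{mode}]", True))
    elif has_gc:
        method = "seqnorm" if config.method == "seqnorm" else "single_pass"
        steps.append(PlanStep(f"normalize[{method}]", True))
    else:
        raise PlanError(
            "normalization impossible: no GC annotation and no matched normal"
        )
    steps.append(PlanStep("segment", True))
    steps.append(PlanStep("call", True))
    for s in steps:
        if not s.run:
            logger.info("skipping %s: %s", s.name, s.reason)
    return steps


def _segment_parallel(
    profile: RCProfile, penalty: float | None, workers: int
) -> segment_call.SegmentSet:
    """Per-chromosome segmentation over a worker pool, merged in order."""
    names = [name for name, _ in chromosome_slices(profile.chrom)]
    if penalty is None:
        penalty = segment_call.default_penalty(
            profile.values, chrom=profile.chrom, mask=profile.mask
        )

    def one(name: str) -> pd.DataFrame:
        sl = next(s for n, s in chromosome_slices(profile.chrom) if n == name)
        sub = RCProfile(
            profile.df.iloc[sl].copy(), profile.window_size, dict(profile.meta)
        )
        seg = segment_call.segment(sub, penalty=penalty)
        seg.df["start_idx"] += sl.start
        seg.df["end_idx"] += sl.start
        return seg.df

    if workers <= 1:
        parts = [one(n) for n in names]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            parts = list(pool.map(one, names))
    return segment_call.SegmentSet(pd.concat(parts, ignore_index=True))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the planned pipeline; returns paths of written artifacts.

    Deterministic given the config (and its seed); any stage failure is
    re-raised with the stage name after flushing partial artifacts.
    """
    out_prefix = Path(config.out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "plan"
    try:
        # --- inputs
        stage = "summarize"
        if config.profile:
            profile = RCProfile.from_tsv(config.profile)
        elif config.sam:
            profile = summarize_sam(config.sam, window_size=config.window_size)
        else:
            raise PlanError("either 'sam' or 'profile' input is required")

        normal = None
        if config.normal_profile:
            normal = RCProfile.from_tsv(config.normal_profile)
        elif config.normal_sam:
            normal = summarize_sam(
                config.normal_sam, window_size=config.window_size
            )

        if config.annot:
            table = read_annotation_table(config.annot)
            cnv = read_bed(config.cnv_bed) if config.cnv_bed else None
            profile = annotate(profile, gc_table=table, cnv_bed=cnv)
            if normal is not None:
                normal = annotate(normal, gc_table=table, cnv_bed=cnv)

        gc_vec = profile.df["gc"].to_numpy(dtype=float)
        has_gc = bool(np.isfinite(gc_vec).any())
        mp_vec = profile.df["mappability"].to_numpy(dtype=float)
        steps = plan(
            paired=profile.paired,
            has_gc=has_gc,
            has_mappability=bool(np.isfinite(mp_vec).any()),
            has_cnv=bool(config.cnv_bed),
            has_normal=normal is not None,
            config=config,
        )
        step_names = {s.name for s in steps if s.run}

        # --- filters
        stage = "filter"
        fconf = filters.FilterConfig(
            pem_max=None if np.isnan(config.pem_max) else config.pem_max,
            mapq_min=None if np.isnan(config.mapq_min) else config.mapq_min,
            trim=any(s.startswith("trim") for s in step_names),
            cnv_max=config.cnv_max if "cnv_filter" in step_names else None,
            mappability_min=(
                None if np.isnan(config.mappability_min) else config.mappability_min
            ),
            trim_span=config.span,
            skip_unavailable=config.skip_unavailable,
        )
        profile, report = filters.apply_filters(profile, fconf, normal=normal)
        report_path = out_prefix.with_suffix(".report.json")
        with open(report_path, "w") as fh:
            json.dump(
                {"steps": [asdict(s) for s in steps], "filters": report.to_dict()},
                fh, indent=1, default=str,
            )
        artifacts["report"] = report_path

        # --- normalization
        stage = "normalize"
        penalty = None if np.isnan(config.penalty) else config.penalty
        if normal is not None:
            mode = config.method if config.method in ("ratio", "seqnorm") else "ratio"
            profile = normalize.paired_normalize(profile, normal, mode=mode)
        elif config.method == "seqnorm":
            profile, _curve = normalize.seqnorm(
                profile, span=config.span, penalty=penalty
            )
        else:
            profile = normalize.single_pass_correct(profile, span=config.span)

        profile_path = out_prefix.with_suffix(".profile.tsv")
        profile.to_tsv(profile_path)
        artifacts["profile"] = profile_path

        # --- segmentation + calling
        stage = "segment"
        segs = _segment_parallel(profile, penalty, config.workers)
        seg_path = out_prefix.with_suffix(".seg")
        stage = "call"
        if config.thresholds:
            thr = np.array([float(t) for t in config.thresholds.split(",")])
        else:
            thr = segment_call.suggest_thresholds(segs, config.baseline_cn)
        if thr is not None:
            callset = segment_call.call(segs, thr)
            callset.segments.to_seg(seg_path)
        else:
            logger.warning("no threshold suggestion possible; segments left uncalled")
            segs.to_seg(seg_path)
        artifacts["seg"] = seg_path
        return artifacts
    except PlanError:
        raise
    except Exception as exc:
        raise CnaprepError(f"pipeline stage {stage!r} failed: {exc}") from exc
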