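"""Read summarization: SAM parsing, flag-based classification, windowed counts.

Reads are classified from their SAM flags into ``proper`` (counted and
contributing to window mapping-quality statistics), ``improper`` (paired
reads whose pair lacks correct separation/orientation — counted, and the
per-window improper proportion feeds the paired-end filter) and
``discarded`` (unmapped, secondary, supplementary, duplicate).  Reads are
never dropped for low mapping quality at this stage; quality handling is
deferred to the window-level filters.

The SAM reader is a minimal line-level reader on purpose: it accepts
arbitrary text streams, tolerates records whose reference name is absent
from the header (warn and skip, with a count in the summary), and needs
only five fields per record.  Tests cross-check it against pysam on toy
files.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .core import (
    InvalidRecordError,
    RCProfile,
    WindowGrid,
    chromosome_slices,
)

DEFAULT_WINDOW_SIZE = 200_000

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

_DISCARD_BITS = FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_DUP | FLAG_SUPPLEMENTARY

PROPER = "proper"
IMPROPER = "improper"
DISCARDED = "discarded"


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment record: position, flag and mapping quality."""

    chrom: str
    pos: int  # 1-based leftmost mapping position
    flag: int
    mapq: int

    def __post_init__(self) -> None:
        if self.flag < 0:
            raise InvalidRecordError(f"negative SAM flag {self.flag}")
        if not (0 <= self.mapq <= 255):
            raise InvalidRecordError(f"mapq {self.mapq} outside [0, 255]")
        if self.pos < 1 and not self.flag & FLAG_UNMAPPED:
            raise InvalidRecordError(f"mapped read with pos {self.pos} < 1")


def classify_read(read: AlignedRead, min_keep_mapq: int = 0) -> str:
    """Classify a read as ``proper``, ``improper`` or ``discarded``.

    ``min_keep_mapq`` is accepted for interface stability but never used
    to discard reads: low-quality reads are counted, and quality is acted
    on per window by the mapping-quality filter (read-level removal
    degrades the profile's signal-to-noise ratio).
    """
    if read.flag < 0:
        raise InvalidRecordError(f"negative SAM flag {read.flag}")
    if read.flag & _DISCARD_BITS:
        return DISCARDED
    if read.flag & FLAG_PAIRED:
        return PROPER if read.flag & FLAG_PROPER_PAIR else IMPROPER
    return PROPER  # mapped single-end read


def _open_stream(sam) -> IO[str]:
    if hasattr(sam, "read"):
        return sam
    return open(sam)


def parse_sam(sam) -> tuple[dict[str, int], Iterator[AlignedRead]]:
    """Parse a SAM path or text stream.

    Returns the ``@SQ`` chromosome lengths and an iterator of records.
    The header is consumed eagerly; records are yielded lazily.
    """
    fh = _open_stream(sam)
    chrom_lengths: dict[str, int] = {}
    first_record: str | None = None
    for line in fh:
        if line.startswith("@"):
            if line.startswith("@SQ"):
                fields = dict(
                    f.split(":", 1) for f in line.rstrip("\n").split("\t")[1:] if ":" in f
                )
                if "SN" in fields and "LN" in fields:
                    chrom_lengths[fields["SN"]] = int(fields["LN"])
            continue
        first_record = line
        break

    def records() -> Iterator[AlignedRead]:
        lines: Iterable[str]
        if first_record is None:
            lines = ()
        else:
            lines = _chain_first(first_record, fh)
        for raw in lines:
            raw = raw.rstrip("\n")
            if not raw:
                continue
            f = raw.split("\t")
            if len(f) < 11:
                raise InvalidRecordError(
                    f"SAM record with {len(f)} fields (11 required)"
                )
            yield AlignedRead(
                chrom=f[2], pos=int(f[3]), flag=int(f[1]), mapq=int(f[4])
            )

    return chrom_lengths, records()


def _chain_first(first: str, rest: IO[str]) -> Iterator[str]:
    yield first
    yield from rest


def summarize(
    sam,
    window_size: int = DEFAULT_WINDOW_SIZE,
    chrom_lengths: Mapping[str, int] | None = None,
) -> RCProfile:
    """Summarize a SAM stream into a per-window read-count profile.

    Each retained read is assigned to exactly one window by its 1-based
    leftmost position (window index ``(pos - 1) // window_size``); the
    profile records total and proper counts, the improper-read proportion
    and the mean mapping quality of proper reads per window.  Input order
    does not matter.

    Parameters
    ----------
    sam:
        Path or text stream of SAM records.  Records on chromosomes not
        declared in the header (or ``chrom_lengths``) are skipped with a
        warning; the skip count is stored in ``profile.meta``.
    window_size:
        Window width in bases.
    chrom_lengths:
        Optional explicit chromosome lengths overriding the ``@SQ`` header.
    """
    header_lengths, records = parse_sam(sam)
    lengths = dict(chrom_lengths) if chrom_lengths is not None else header_lengths
    if not lengths:
        raise ValueError("no chromosome lengths: SAM header lacks @SQ lines")

    grid = WindowGrid.from_chrom_lengths(lengths, window_size)
    n = len(grid)
    offsets: dict[str, tuple[int, int]] = {}  # chrom -> (first window idx, n windows)
    for name, sl in chromosome_slices(grid.chrom):
        offsets[name] = (sl.start, sl.stop - sl.start)

    count = np.zeros(n, dtype=np.int64)
    proper = np.zeros(n, dtype=np.int64)
    improper = np.zeros(n, dtype=np.int64)
    mapq_sum = np.zeros(n, dtype=np.float64)
    n_discarded = 0
    n_skipped_chrom = 0
    n_records = 0
    saw_paired = False

    for read in records:
        n_records += 1
        cls = classify_read(read)
        if read.flag & FLAG_PAIRED:
            saw_paired = True
        if cls == DISCARDED:
            n_discarded += 1
            continue
        loc = offsets.get(read.chrom)
        if loc is None:
            n_skipped_chrom += 1
            continue
        base, n_win = loc
        widx = (read.pos - 1) // window_size
        if widx >= n_win:
            # position beyond declared chromosome length: clamp to last window
            widx = n_win - 1
        gidx = base + widx
        count[gidx] += 1
        if cls == PROPER:
            proper[gidx] += 1
            mapq_sum[gidx] += read.mapq
        else:
            improper[gidx] += 1

    if n_skipped_chrom:
        warnings.warn(
            f"skipped {n_skipped_chrom} records on chromosomes absent from the header",
            stacklevel=2,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        improper_prop = np.where(count > 0, improper / np.maximum(count, 1), np.nan)
        mean_mapq = np.where(proper > 0, mapq_sum / np.maximum(proper, 1), np.nan)
    improper_prop[count == 0] = np.nan

    df = pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.start,
            "end": grid.end,
            "count": count,
            "proper_count": proper,
            "improper_prop": improper_prop,
            "mean_mapq": mean_mapq,
            "value": count.astype(float),
        }
    )
    meta = {
        "paired": saw_paired,
        "n_records": n_records,
        "n_discarded": n_discarded,
        "n_skipped_chrom": n_skipped_chrom,
    }
    return RCProfile(df, window_size=window_size, meta=meta)


# ---------------------------------------------------------------------------
# annotation


def read_annotation_table(path) -> pd.DataFrame:
    """Read a `chrom start end gc mappability` table (1-based inclusive).

    A header line is optional; it is detected by a non-numeric second
    column.  The ``mappability`` column may be absent.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if not str(df.iloc[0, 1]).lstrip("-").replace(".", "", 1).isdigit():
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [c.lower() for c in df.columns]
    else:
        names = ["chrom", "start", "end", "gc", "mappability"][: df.shape[1]]
        df.columns = names
    required = {"chrom", "start", "end", "gc"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    return df


def read_bed(path) -> pd.DataFrame:
    """Read a BED file, converting to 1-based inclusive coordinates."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    df["start"] = df["start"].astype(np.int64) + 1  # 0-based half-open -> 1-based
    df["end"] = df["end"].astype(np.int64)
    return df


def _interval_overlap_stats(
    win_start: np.ndarray,
    win_end: np.ndarray,
    iv_start: np.ndarray,
    iv_end: np.ndarray,
    iv_value: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coverage-weighted value mean and covered-base count per window.

    All coordinates 1-based inclusive.  Runs in O(intervals x overlapping
    windows); annotation tables are expected to be window-scale.
    """
    n = len(win_start)
    weight = np.zeros(n)
    weighted = np.zeros(n)
    covered = np.zeros(n)
    order = np.argsort(win_start, kind="stable")
    ws = win_start[order]
    for j in range(len(iv_start)):
        lo = int(np.searchsorted(ws, iv_start[j], side="right")) - 1
        lo = max(lo, 0)
        for k in range(lo, n):
            i = order[k]
            if win_start[i] > iv_end[j]:
                break
            ov = min(win_end[i], iv_end[j]) - max(win_start[i], iv_start[j]) + 1
            if ov <= 0:
                continue
            covered[i] += ov
            if iv_value is not None and np.isfinite(iv_value[j]):
                weight[i] += ov
                weighted[i] += ov * iv_value[j]
    with np.errstate(invalid="ignore"):
        mean = np.where(weight > 0, weighted / np.maximum(weight, 1e-300), np.nan)
    return mean, covered


def _merge_intervals(start: np.ndarray, end: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(start) == 0:
        return start, end
    order = np.argsort(start, kind="stable")
    s, e = start[order], end[order]
    ms, me = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= me[-1] + 1:
            me[-1] = max(me[-1], e[i])
        else:
            ms.append(s[i])
            me.append(e[i])
    return np.asarray(ms), np.asarray(me)


def annotate(
    profile: RCProfile,
    gc_table: pd.DataFrame | None = None,
    mappability_table: pd.DataFrame | None = None,
    cnv_bed: pd.DataFrame | None = None,
) -> RCProfile:
    """Attach GC, mappability and common-CNV overlap annotation to windows.

    GC and mappability are attached by coverage-weighted mean over
    overlapping annotation intervals (an exact window match reduces to
    identity).  Windows with no overlapping annotation keep a missing
    value — never a silent zero.  ``cnv_overlap`` is the fraction of the
    window covered by any CNV interval (intervals merged first).

    ``mappability_table`` defaults to ``gc_table`` when that table carries
    a ``mappability`` column.
    """
    out = profile.copy()
    if mappability_table is None and gc_table is not None and "mappability" in gc_table:
        mappability_table = gc_table

    for table, column in ((gc_table, "gc"), (mappability_table, "mappability")):
        if table is None:
            continue
        if column not in table.columns:
            raise ValueError(f"annotation table lacks column {column!r}")
        result = np.full(len(out), np.nan)
        for name, sl in chromosome_slices(out.chrom):
            sub = table[table["chrom"] == name]
            if not len(sub):
                continue
            mean, _ = _interval_overlap_stats(
                out.df["start"].to_numpy()[sl],
                out.df["end"].to_numpy()[sl],
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub[column].to_numpy(float),
            )
            result[sl] = mean
        out.df[column] = result

    if cnv_bed is not None:
        frac = np.zeros(len(out))
        for name, sl in chromosome_slices(out.chrom):
            sub = cnv_bed[cnv_bed["chrom"] == name]
            if not len(sub):
                continue
            ms, me = _merge_intervals(
                sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
            )
            _, covered = _interval_overlap_stats(
                out.df["start"].to_numpy()[sl],
                out.df["end"].to_numpy()[sl],
                ms, me, None,
            )
            widths = (out.df["end"].to_numpy()[sl] - out.df["start"].to_numpy()[sl] + 1)
            frac[sl] = covered / widths
        out.df["cnv_overlap"] = frac

    return out
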