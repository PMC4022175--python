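"""Core data structures shared across the pipeline.

The central object is :class:`RCProfile`, a per-window read-count profile
backed by a :class:`pandas.DataFrame` with one row per genomic window.
All stages of the pipeline (summarization, filtering, normalization,
segmentation) consume and produce ``RCProfile`` objects; on disk they are
plain tab-delimited tables so every intermediate is inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical column order for profile tables
PROFILE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "gc",
    "mappability",
    "cnv_overlap",
    "count",
    "proper_count",
    "improper_prop",
    "mean_mapq",
    "value",
]

#: prefix of per-filter boolean mask columns
FILTER_PREFIX = "flt_"

#: combined filter mask column (logical OR of every ``flt_*`` column)
COMBINED_MASK = "filtered"


class CnaprepError(Exception):
    """Base class for errors raised by this package."""


class InvalidRecordError(CnaprepError):
    """An alignment record violates basic SAM invariants."""


class FilterUnavailableError(CnaprepError):
    """A filter was requested but its required inputs are absent."""


class GridMismatchError(CnaprepError):
    """Two profiles do not share the same window grid."""


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-width genomic windows, 1-based inclusive coordinates.

    Windows within a chromosome are contiguous, non-overlapping and of
    width ``window_size`` except possibly the last one, which may be
    truncated at the chromosome end.
    """

    window_size: int
    chrom: np.ndarray  # str per window
    start: np.ndarray  # int, 1-based inclusive
    end: np.ndarray  # int, inclusive

    def __post_init__(self) -> None:
        if len(self.chrom) != len(self.start) or len(self.start) != len(self.end):
            raise ValueError("grid arrays must have equal length")
        widths = self.end - self.start + 1
        if len(widths) and (widths > self.window_size).any():
            raise ValueError("window wider than window_size")
        if len(widths) and (widths < 1).any():
            raise ValueError("window with non-positive width")

    def __len__(self) -> int:
        return len(self.chrom)

    @classmethod
    def from_chrom_lengths(
        cls, chrom_lengths: Mapping[str, int], window_size: int
    ) -> "WindowGrid":
        """Tile each chromosome with ``window_size``-wide windows."""
        if window_size < 1:
            raise ValueError("window_size must be >= 1")
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        for name, length in chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            n_win = -(-length // window_size)  # ceil division
            for i in range(n_win):
                chroms.append(name)
                starts.append(i * window_size + 1)
                ends.append(min((i + 1) * window_size, length))
        return cls(
            window_size=window_size,
            chrom=np.asarray(chroms, dtype=object),
            start=np.asarray(starts, dtype=np.int64),
            end=np.asarray(ends, dtype=np.int64),
        )

    def equals(self, other: "WindowGrid") -> bool:
        return (
            self.window_size == other.window_size
            and len(self) == len(other)
            and bool(np.array_equal(self.chrom, other.chrom))
            and bool(np.array_equal(self.start, other.start))
            and bool(np.array_equal(self.end, other.end))
        )


class RCProfile:
    """Per-window read-count profile with annotation and filter masks.

    Parameters
    ----------
    df:
        One row per window.  Required columns: ``chrom``, ``start``,
        ``end``.  Missing optional columns are created filled with NaN
        (``count`` defaults to 0).
    window_size:
        Nominal window width in bases.
    meta:
        Free-form metadata (``paired`` flag, skipped-record counts,
        processing notes).  Serialized to a JSON header line on export.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        window_size: int,
        meta: dict | None = None,
    ) -> None:
        df = df.copy()
        for col in PROFILE_COLUMNS:
            if col not in df.columns:
                if col == "count" or col == "proper_count":
                    df[col] = 0
                elif col in ("chrom", "start", "end"):
                    raise ValueError(f"profile requires column {col!r}")
                else:
                    df[col] = np.nan
        if COMBINED_MASK not in df.columns:
            df[COMBINED_MASK] = False
        front = PROFILE_COLUMNS + sorted(
            c for c in df.columns if c.startswith(FILTER_PREFIX)
        )
        df = df[front + [COMBINED_MASK]]
        df = df.reset_index(drop=True)
        self.df = df
        self.window_size = int(window_size)
        self.meta: dict = dict(meta or {})

    # -- construction ------------------------------------------------------

    @classmethod
    def from_grid(cls, grid: WindowGrid, meta: dict | None = None) -> "RCProfile":
        df = pd.DataFrame(
            {"chrom": grid.chrom, "start": grid.start, "end": grid.end}
        )
        return cls(df, window_size=grid.window_size, meta=meta)

    def copy(self) -> "RCProfile":
        return RCProfile(self.df.copy(), self.window_size, dict(self.meta))

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def grid(self) -> WindowGrid:
        return WindowGrid(
            window_size=self.window_size,
            chrom=self.df["chrom"].to_numpy(dtype=object),
            start=self.df["start"].to_numpy(dtype=np.int64),
            end=self.df["end"].to_numpy(dtype=np.int64),
        )

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy(dtype=object)

    @property
    def values(self) -> np.ndarray:
        """Current working values (raw counts until a stage overwrites)."""
        v = self.df["value"].to_numpy(dtype=float)
        if np.isnan(v).all():
            v = self.df["count"].to_numpy(dtype=float)
        return v

    def set_values(self, values: Sequence[float]) -> None:
        values = np.asarray(values, dtype=float)
        if len(values) != len(self):
            raise ValueError("value vector length mismatch")
        self.df["value"] = values

    @property
    def paired(self) -> bool:
        return bool(self.meta.get("paired", False))

    # -- filter masks ------------------------------------------------------

    def filter_names(self) -> list[str]:
        return [
            c[len(FILTER_PREFIX):]
            for c in self.df.columns
            if c.startswith(FILTER_PREFIX)
        ]

    def get_mask(self, name: str) -> np.ndarray:
        col = FILTER_PREFIX + name
        if col not in self.df.columns:
            raise KeyError(f"no filter mask {name!r}")
        return self.df[col].to_numpy(dtype=bool)

    def set_mask(self, name: str, mask: Sequence[bool]) -> None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(self):
            raise ValueError("mask length mismatch")
        self.df[FILTER_PREFIX + name] = mask
        self._refresh_combined()

    def drop_mask(self, name: str) -> None:
        self.df = self.df.drop(columns=[FILTER_PREFIX + name])
        self._refresh_combined()

    def _refresh_combined(self) -> None:
        cols = [c for c in self.df.columns if c.startswith(FILTER_PREFIX)]
        if cols:
            combined = self.df[cols].to_numpy(dtype=bool).any(axis=1)
        else:
            combined = np.zeros(len(self), dtype=bool)
        self.df[COMBINED_MASK] = combined

    @property
    def mask(self) -> np.ndarray:
        """Combined filter mask: True means the window is filtered out."""
        return self.df[COMBINED_MASK].to_numpy(dtype=bool)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the profile as a tab-delimited table.

        Metadata (window size, pairedness, notes) goes into a single
        ``#cnaprep`` JSON comment line so the file round-trips.
        """
        header = {"window_size": self.window_size, "meta": self.meta}
        with open(path, "w") as fh:
            fh.write("#cnaprep " + json.dumps(header, sort_keys=True) + "\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "RCProfile":
        window_size = 0
        meta: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#cnaprep "):
                header = json.loads(first[len("#cnaprep "):])
                window_size = int(header.get("window_size", 0))
                meta = dict(header.get("meta", {}))
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        if not window_size:
            widths = df["end"] - df["start"] + 1
            window_size = int(widths.max()) if len(df) else 1
        prof = cls(df, window_size=window_size, meta=meta)
        # restore boolean dtype lost through CSV round-trip
        for col in prof.df.columns:
            if col.startswith(FILTER_PREFIX) or col == COMBINED_MASK:
                prof.df[col] = prof.df[col].astype(bool)
        return prof

    def check_same_grid(self, other: "RCProfile") -> None:
        if not self.grid.equals(other.grid):
            raise GridMismatchError("profiles do not share the same window grid")


def chromosome_slices(chrom: np.ndarray) -> list[tuple[str, slice]]:
    """Contiguous per-chromosome slices of a window-ordered chrom vector."""
    out: list[tuple[str, slice]] = []
    if len(chrom) == 0:
        return out
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            out.append((chrom[start], slice(start, i)))
            start = i
    return out
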