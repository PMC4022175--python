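import io

import numpy as np
import pandas as pd
import pytest

from cnaprep.core import RCProfile


TOY_SAM = "\n".join(
    [
        "@HD\tVN:1.6\tSO:unsorted",
        "@SQ\tSN:chr1\tLN:2000000",
        "@SQ\tSN:chr2\tLN:1000000",
        # window 1 of chr1: 3 proper + 1 improper
        "r1\t99\tchr1\t100\t60\t4M\t=\t400\t400\tAAAA\tIIII",
        "r2\t99\tchr1\t150\t40\t4M\t=\t450\t400\tAAAA\tIIII",
        "r3\t99\tchr1\t250\t20\t4M\t=\t550\t400\tAAAA\tIIII",
        "r4\t97\tchr1\t120\t60\t4M\t=\t50120\t50100\tAAAA\tIIII",
        # window 2 of chr1: 1 proper
        "r5\t99\tchr1\t1000050\t60\t4M\t=\t1000350\t400\tAAAA\tIIII",
        # discarded: unmapped, duplicate, secondary
        "r6\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\tIIII",
        "r7\t1123\tchr1\t500\t60\t4M\t=\t800\t400\tAAAA\tIIII",
        "r8\t355\tchr1\t600\t60\t4M\t=\t900\t400\tAAAA\tIIII",
        # chr2: 1 proper single-window read
        "r9\t99\tchr2\t10\t60\t4M\t=\t310\t400\tAAAA\tIIII",
    ]
) + "\n"


@pytest.fixture
def toy_sam_text() -> str:
    return TOY_SAM


@pytest.fixture
def toy_sam_path(tmp_path):
    path = tmp_path / "toy.sam"
    path.write_text(TOY_SAM)
    return path


def make_profile(
    values,
    gc=None,
    chrom=None,
    window_size=1000,
    paired=True,
    **columns,
) -> RCProfile:
    """Build an in-memory profile from plain vectors (test helper)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if chrom is None:
        chrom = np.array(["chr1"] * n, dtype=object)
    chrom = np.asarray(chrom, dtype=object)
    starts = np.empty(n, dtype=np.int64)
    pos = {}
    for i, c in enumerate(chrom):
        k = pos.get(c, 0)
        starts[i] = k * window_size + 1
        pos[c] = k + 1
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size - 1,
            "count": np.round(values).astype(np.int64),
            "proper_count": np.round(values).astype(np.int64),
            "value": values,
        }
    )
    if gc is not None:
        df["gc"] = np.asarray(gc, dtype=float)
    df["mean_mapq"] = 60.0
    for name, col in columns.items():
        df[name] = col
    return RCProfile(df, window_size=window_size, meta={"paired": paired})
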