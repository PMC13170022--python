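"""RPKM quantification and simple two-group comparisons of expression.

RPKM (reads per kilobase of transcript per million mapped reads) is
computed from the raw contig length and the per-library total of mapped
reads. Contigs attracting fewer than one read are dropped before any
cross-species comparison.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def rpkm(read_count: float, length_nt: int, total_mapped: float) -> float:
    """RPKM = read_count * 1e9 / (total_mapped * length_nt)."""
    if length_nt <= 0:
        raise ValueError("contig length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return read_count * 1e9 / (total_mapped * length_nt)


def rpkm_table(counts: pd.DataFrame, total_mapped: float) -> pd.DataFrame:
    """Add an ``rpkm`` column to a (contig_id, count, length) table."""
    out = counts.copy()
    out["rpkm"] = [
        rpkm(c, l, total_mapped) for c, l in zip(out["count"], out["length"])
    ]
    return out


def filter_low(records: pd.DataFrame, min_count: float = 1.0) -> pd.DataFrame:
    """Drop contigs with a read count below `min_count` (fractional counts
    from ambiguous assignment are allowed and filtered as written)."""
    return records.loc[records["count"] >= min_count].reset_index(drop=True)


def group_mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample SD / sqrt(n)); n >= 2."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("standard error needs at least two observations")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def two_sample_t(
    a_values: Sequence[float],
    b_values: Sequence[float],
    welch: bool = True,
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; Welch by default, pooled with welch=False.

    Returns (t, df, p). Degenerate input with zero variance in both groups
    and equal means yields (0, df, 1).
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)
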