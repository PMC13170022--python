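"""Chi-square tests on count pairs and 2x2 tables, and report assembly.

Species-specific count comparisons (did one species express more?) use a
goodness-of-fit test against a 1:1 expectation; proportion comparisons
(TE-containing contigs, pseudogene fractions) use the Pearson 2x2
homogeneity test. Yates continuity correction is off by default,
matching an uncorrected Pearson chi-square.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


def chisq_gof_1to1(count_a: float, count_b: float) -> tuple[float, int, float]:
    """Chi-square goodness of fit of (a, b) against equal expected counts.

    Returns (chi2, df=1, p)."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        raise ValueError("degenerate test: both counts are zero")
    expected = total / 2.0
    chi2 = (count_a - expected) ** 2 / expected + (count_b - expected) ** 2 / expected
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


def chisq_2x2(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 table, closed form.

    chi2 = N (ad - bc)^2 / (r1 r2 c1 c2); with `yates` the absolute
    cross-product difference is reduced by N/2 (floored at 0) first.
    Returns (chi2, df=1, p); any zero margin raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate test: zero row or column margin")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff**2 / (r1 * r2 * c1 * c2)
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


def build_report(
    stage_outputs: Mapping[str, object], out_dir: str | Path
) -> dict[str, object]:
    """Write stage outputs deterministically as TSV + a JSON summary.

    DataFrame values are written as ``<name>.tsv`` with sorted columns
    preserved in insertion order and rows sorted by the first column;
    scalar mappings are merged into ``report.json``. Returns the JSON
    payload. Running twice on the same inputs produces byte-identical
    files.
    """
    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {}
    for name in sorted(stage_outputs):
        value = stage_outputs[name]
        if isinstance(value, pd.DataFrame):
            frame = value.sort_values(list(value.columns[:1]), kind="mergesort")
            frame.to_csv(out_path / f"{name}.tsv", sep="\t", index=False)
            summary[name] = f"{name}.tsv"
        else:
            summary[name] = value
    payload = json.dumps(summary, indent=2, sort_keys=True, default=_jsonify)
    (out_path / "report.json").write_text(payload + "\n")
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
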