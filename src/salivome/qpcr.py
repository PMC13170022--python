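"""Efficiency-corrected qPCR quantification with multiple reference genes.

Amplification efficiency E comes from the slope of the standard curve
(log10 template amount on x, Ct on y): E = 10^(-1/slope) - 1, so a
perfectly doubling reaction (slope ~ -3.32) has E = 1. The normalized
expression of a target is

    (1 + E_target)^(-Ct_target)
    ---------------------------------------------
    geomean_refs (1 + E_ref)^(-Ct_ref)

with the geometric mean over the reference genes (three by default:
ribosomal proteins L13 and L32 and beta-tubulin roles). Cross-species
fold change is the ratio of per-species means of normalized levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import group_mean_se, two_sample_t


@dataclass(frozen=True)
class StandardCurve:
    """Standard-curve regression for one gene; E on the 0-1 scale."""

    gene_id: str
    slope: float

    @property
    def efficiency(self) -> float:
        return efficiency_from_slope(self.slope)


def efficiency_from_slope(slope: float) -> float:
    """E = 10^(-1/slope) - 1; a valid curve has slope < 0."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if slope > 0:
        warnings.warn(
            f"positive standard-curve slope {slope}: invalid curve",
            stacklevel=2,
        )
    return 10.0 ** (-1.0 / slope) - 1.0


def slope_for_efficiency(efficiency: float) -> float:
    """Inverse of :func:`efficiency_from_slope` (used to build curves)."""
    if efficiency <= -1:
        raise ValueError("efficiency must exceed -1")
    return -1.0 / math.log10(1.0 + efficiency)


def normalized_expression(
    ct_target: float,
    e_target: float,
    refs: Sequence[tuple[float, float]],
) -> float:
    """Target level normalized to the geometric mean of reference signals.

    `refs` is a list of (ct, E) pairs for the reference genes; the n-th
    root of the product generalizes the printed three-reference cube
    root. Computed in log space for stability at large Ct.
    """
    if not refs:
        raise ValueError("at least one reference gene is required")
    log_num = -ct_target * math.log(1.0 + e_target)
    log_den = sum(-ct * math.log(1.0 + e) for ct, e in refs) / len(refs)
    return math.exp(log_num - log_den)


def fold_change(mean_a: float, mean_b: float, decimals: int = 2) -> float | None:
    """mean_a / mean_b rounded to `decimals`; None when mean_b is zero."""
    if mean_b == 0:
        return None
    return round(mean_a / mean_b, decimals)


def quantify(
    measurements: pd.DataFrame,
    curves: pd.DataFrame,
    reference_genes: Sequence[str],
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Normalized expression per sample x target gene.

    `measurements` columns: sample_id, species, gene_id, replicate, ct.
    `curves` columns: gene_id, slope. Replicate Cts are averaged per
    sample x gene before normalization by default; with
    ``per_replicate=True`` each replicate index is normalized against the
    same-index reference Cts and the levels are then averaged.
    """
    eff = {
        str(r.gene_id): efficiency_from_slope(float(r.slope))
        for r in curves.itertuples()
    }
    ref_set = set(reference_genes)
    targets = [g for g in measurements["gene_id"].unique() if g not in ref_set]
    rows = []
    for (sample, species), grp in measurements.groupby(["sample_id", "species"]):
        cts = grp.pivot_table(index="gene_id", columns="replicate", values="ct")

        def level(target: str, ct_of) -> float:
            refs = [(ct_of(r), eff[r]) for r in reference_genes]
            return normalized_expression(ct_of(target), eff[target], refs)

        for target in targets:
            if per_replicate:
                reps = cts.columns
                vals = [
                    level(target, lambda g, rep=rep: float(cts.loc[g, rep]))
                    for rep in reps
                ]
                value = float(np.mean(vals))
            else:
                mean_ct = cts.mean(axis=1)
                value = level(target, lambda g: float(mean_ct.loc[g]))
            rows.append(
                {
                    "sample_id": sample,
                    "species": species,
                    "gene_id": target,
                    "level": value,
                }
            )
    return pd.DataFrame.from_records(rows)


def species_fold_changes(
    levels: pd.DataFrame, decimals: int = 2
) -> pd.DataFrame:
    """Per-gene species means +/- SE, A/B fold change and Welch t-test p."""
    rows = []
    for gene, grp in levels.groupby("gene_id"):
        a = grp.loc[grp["species"] == "A", "level"].to_numpy()
        b = grp.loc[grp["species"] == "B", "level"].to_numpy()
        mean_a, se_a = group_mean_se(a)
        mean_b, se_b = group_mean_se(b)
        _, _, p = two_sample_t(a, b)
        rows.append(
            {
                "gene_id": gene,
                "mean_a": mean_a,
                "se_a": se_a,
                "mean_b": mean_b,
                "se_b": se_b,
                "fold": fold_change(mean_a, mean_b, decimals),
                "p": p,
            }
        )
    return pd.DataFrame.from_records(rows).sort_values("gene_id").reset_index(
        drop=True
    )
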