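"""Putative secreted protein calling from predictor annotations.

A translated contig is called secreted when it carries a classical signal
peptide OR a non-classical secretion neural-network score above the
cutoff, AND it carries no transmembrane helix AND no GPI anchor (membrane
retention overrides any secretion signal). The predictors themselves
(signal peptide, non-classical score, TM helices, GPI) run upstream;
their outputs are consumed as an annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .enrichment import size_ratio
from .homology import UnigeneCluster


@dataclass(frozen=True)
class SecretionAnnotation:
    """Predictor outputs for one translated contig."""

    contig_id: str
    signal_peptide: bool
    nn_score: float
    tm_helix_count: int
    gpi_anchor: bool
    tm_helix_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.tm_helix_count < 0:
            raise ValueError("tm_helix_count must be non-negative")
        if self.nn_score != self.nn_score:  # NaN
            raise ValueError("nn_score must be finite")


def call_secreted(
    ann: SecretionAnnotation,
    nn_cutoff: float = 0.5,
    ignore_nterm_helices: bool = False,
    nterm_window: int = 60,
) -> tuple[bool, str]:
    """Apply the secretion decision cascade to one annotation row.

    Returns (secreted, reason) with reason in {classical, non_classical,
    rejected_no_signal, rejected_tm, rejected_gpi}. The NN cutoff is
    strict (> nn_cutoff). With ``ignore_nterm_helices``, helices whose
    start lies within the first `nterm_window` residues (where a signal
    peptide can masquerade as a helix) are discounted, provided positions
    are annotated.
    """
    has_signal = ann.signal_peptide or ann.nn_score > nn_cutoff
    if not has_signal:
        return False, "rejected_no_signal"
    tm_count = ann.tm_helix_count
    if ignore_nterm_helices and ann.tm_helix_positions:
        tm_count = sum(1 for pos in ann.tm_helix_positions if pos >= nterm_window)
    if tm_count > 0:
        return False, "rejected_tm"
    if ann.gpi_anchor:
        return False, "rejected_gpi"
    return True, ("classical" if ann.signal_peptide else "non_classical")


def call_table(
    annotations: pd.DataFrame, nn_cutoff: float = 0.5, **kwargs
) -> pd.DataFrame:
    """Vector version of :func:`call_secreted` over an annotation table.

    Expects columns contig_id, signal_peptide, nn_score, tm_helix_count,
    gpi_anchor; rows are deduplicated by contig_id (first wins).
    """
    rows = []
    for r in annotations.drop_duplicates("contig_id").itertuples():
        ann = SecretionAnnotation(
            contig_id=str(r.contig_id),
            signal_peptide=bool(r.signal_peptide),
            nn_score=float(r.nn_score),
            tm_helix_count=int(r.tm_helix_count),
            gpi_anchor=bool(r.gpi_anchor),
        )
        secreted, reason = call_secreted(ann, nn_cutoff=nn_cutoff, **kwargs)
        rows.append(
            {"contig_id": ann.contig_id, "secreted": secreted, "reason": reason}
        )
    return pd.DataFrame.from_records(rows)


def secretome_sizes(
    calls: pd.DataFrame,
    homology_calls: pd.DataFrame,
    clusters: Sequence[UnigeneCluster],
) -> dict[str, object]:
    """Shared / species-specific secreted-gene counts and their ratio.

    A gene (unigene cluster) is secreted if at least one member contig is
    called secreted. Returns counts plus ratio = a_specific / b_specific
    (None when b_specific is zero).
    """
    secreted_contigs = set(calls.loc[calls["secreted"], "contig_id"])
    shared = a_specific = b_specific = 0
    for cluster in clusters:
        member_ids = [c for ids in cluster.members.values() for c in ids]
        if not any(c in secreted_contigs for c in member_ids):
            continue
        in_a = bool(cluster.members.get("A"))
        in_b = bool(cluster.members.get("B"))
        if in_a and in_b:
            shared += 1
        elif in_a:
            a_specific += 1
        elif in_b:
            b_specific += 1
    return {
        "shared": shared,
        "a_specific": a_specific,
        "b_specific": b_specific,
        "ratio": size_ratio(a_specific, b_specific),
    }
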