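"""Read quality filtering and transposable-element masking of contigs.

Raw reads are dropped when they are low quality (at least half of their
bases at or below a Phred cutoff) or contain a poly-N run. Assembled
contigs carrying TE insertions are hard-masked over the annotated
intervals, contigs that are TE from end to end are removed, and the
per-species TE-containing/TE-free counts feed a 2x2 chi-square
comparison downstream.

Intervals are 0-based half-open internally; the TSV reader converts from
1-based inclusive file coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: bases (may contain N) and per-base Phred Q values."""

    id: str
    bases: str
    quals: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: bases/quals length mismatch "
                f"({len(self.bases)} vs {len(self.quals)})"
            )


@dataclass(frozen=True)
class TEInterval:
    """A transposable-element annotation on a contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class MaskedContig:
    contig_id: str
    masked_sequence: str
    masked_fraction: float


def filter_reads(
    reads: Iterable[ReadRecord],
    q_cutoff: int = 10,
    low_frac: float = 0.5,
    polyn_run: int = 5,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Drop low-quality and poly-N reads, preserving input order.

    A read is removed iff the fraction of bases with Q <= `q_cutoff` is
    >= `low_frac` (inclusive at the boundary), or it contains a run of
    >= `polyn_run` consecutive N/n bases. Returns the retained reads and
    a tally of rejections by reason (a read failing both rules is counted
    under ``low_quality``).
    """
    kept: list[ReadRecord] = []
    tally = {"low_quality": 0, "poly_n": 0, "kept": 0}
    needle = "N" * polyn_run
    for read in reads:
        n = len(read.bases)
        if n == 0:
            tally["low_quality"] += 1
            continue
        n_low = sum(1 for q in read.quals if q <= q_cutoff)
        if n_low / n >= low_frac:
            tally["low_quality"] += 1
        elif needle in read.bases.upper():
            tally["poly_n"] += 1
        else:
            kept.append(read)
            tally["kept"] += 1
    return kept, tally


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length covered by a union of 0-based half-open intervals."""
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for start, end in sorted(intervals):
        if cur_start is None or start > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def mask_te(
    contig_id: str,
    sequence: str,
    intervals: Iterable[TEInterval],
    mask_char: str = "N",
    soft: bool = False,
) -> MaskedContig:
    """Mask the union of TE intervals on a contig.

    Hard masking substitutes `mask_char`; `soft=True` lowercases instead.
    Out-of-bounds intervals raise ValueError.
    """
    n = len(sequence)
    spans = []
    for iv in intervals:
        if iv.contig_id != contig_id:
            continue
        if iv.end > n:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) out of bounds for "
                f"{contig_id} (length {n})"
            )
        spans.append((iv.start, iv.end))
    masked = list(sequence)
    for start, end in spans:
        for i in range(start, end):
            masked[i] = masked[i].lower() if soft else mask_char
    covered = interval_union_length(spans)
    fraction = covered / n if n else 0.0
    return MaskedContig(contig_id, "".join(masked), fraction)


def filter_te_only(
    masked: Iterable[MaskedContig], te_only_frac: float = 1.0
) -> tuple[list[MaskedContig], list[str]]:
    """Remove contigs whose masked fraction is >= `te_only_frac` (TE-only)."""
    kept, removed = [], []
    for contig in masked:
        if contig.masked_fraction >= te_only_frac:
            removed.append(contig.contig_id)
        else:
            kept.append(contig)
    return kept, removed


def te_containing_table(
    te_flags_a: Iterable[bool], te_flags_b: Iterable[bool]
) -> np.ndarray:
    """2x2 counts [species x (TE-containing, TE-free)] for the chi-square test.

    A contig counts as TE-containing if it has at least one TE interval
    (callers pass per-contig booleans, e.g. ``masked_fraction > 0``).
    """
    flags_a = np.fromiter((bool(f) for f in te_flags_a), dtype=bool)
    flags_b = np.fromiter((bool(f) for f in te_flags_b), dtype=bool)
    if flags_a.size == 0 or flags_b.size == 0:
        raise ValueError("both species need at least one contig")
    return np.array(
        [
            [int(flags_a.sum()), int((~flags_a).sum())],
            [int(flags_b.sum()), int((~flags_b).sum())],
        ]
    )


def read_te_intervals(path) -> list[TEInterval]:
    """Read a TE interval TSV (contig_id, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    return [
        TEInterval(str(r.contig_id), int(r.start) - 1, int(r.end))
        for r in df.itertuples()
    ]
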