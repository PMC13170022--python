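"""Orthologue / species-specific / paralogue / allele classification.

The two species' TE-masked contig sets are compared by a reciprocal
cross-species search plus a search of both sets against a reference
protein/nucleotide database. The rule set:

* contig pairs that are reciprocal best matches AND whose best reference
  hits agree (same subject, similar identity and e-value) are orthologues;
* contigs with no retained cross-species hit whose reference subject is
  hit by no contig of the other species are species-specifically expressed;
* contigs with no cross-species hit that nevertheless agree on a reference
  subject with an other-species contig are orthologues transcribed from
  different regions of the same gene;
* remaining (non-best-matching) contigs that agree on a reference subject
  with an other-species contig are paralogues below 98% cross-species
  nucleotide identity and alleles at or above 98%.

Contigs above 94% mutual identity are grouped into single-linkage clusters
("unigenes"), each representing one expressed gene.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

#: BLAST tabular (outfmt 6) column order used for all hit tables.
HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_EVALUE_FLOOR = 1e-200
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Cutoffs of the homology rule set.

    allele_min_identity: percent identity at and above which same-gene
        cross-species contigs are alleles (below: paralogues).
    unigene_min_identity: contigs strictly above this identity are
        clustered into one unigene.
    max_evalue / min_bitscore: hit retention filter (both strict).
    subject_agreement_*: how close two contigs' reference hits must be
        (percentage points of identity; orders of magnitude of e-value)
        to count as hitting "the same subject with similar identity and
        e-value".
    """

    allele_min_identity: float = 98.0
    unigene_min_identity: float = 94.0
    max_evalue: float = 1e-5
    min_bitscore: float = 60.0
    subject_agreement_identity_tol: float = 2.0
    subject_agreement_evalue_tol: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.unigene_min_identity < self.allele_min_identity <= 100:
            raise ValueError(
                "need 0 < unigene_min_identity < allele_min_identity <= 100"
            )


@dataclass
class UnigeneCluster:
    """A single-linkage identity cluster representing one expressed gene."""

    cluster_id: str
    members: dict[str, list[str]]  # species -> contig ids
    representative: str
    allele_count: dict[str, int] = field(default_factory=dict)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Needleman-Wunsch with match +1, mismatch -1, gap -2 (linear); among
    co-optimal alignments the one with the most matches, then the fewest
    columns, is scored. Identity = 100 * matches / alignment columns.

    Quadratic pure-Python dynamic program: intended for short sequences
    and as the exact reference for :func:`fast_identity`.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    # DP over (score, matches, -columns), maximized lexicographically; all
    # three components are additive along an alignment path.
    prev = [(-2 * j, 0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(-2 * i, 0, -i)]
        ai = a[i - 1]
        for j in range(1, m + 1):
            match = ai == b[j - 1]
            ds, dm, dc = prev[j - 1]
            diag = (ds + (1 if match else -1), dm + (1 if match else 0), dc - 1)
            us, um, uc = prev[j]
            up = (us - 2, um, uc - 1)
            ls, lm, lc = cur[j - 1]
            left = (ls - 2, lm, lc - 1)
            cur.append(max(diag, up, left))
        prev = cur
    _, matches, neg_cols = prev[m]
    return 100.0 * matches / (-neg_cols)


def fast_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of full contigs, fast enough for all-pairs use.

    Equal-length pairs above 75% ungapped identity score without gaps:
    in that regime the ungapped alignment is the optimum of the
    match +1 / mismatch -1 / gap -2 scoring (an inserted gap pair costs
    4 and can recover at most ~2 per converted mismatch, which cannot
    pay off when mismatches are sparse), so the result equals
    :func:`pairwise_identity` exactly. All other pairs fall back to a
    minimum-edit global alignment (edlib), scoring identity as
    100 * (columns - edits) / columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("fast_identity requires nonempty sequences")
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) == len(b):
        arr_a = np.frombuffer(a.encode(), dtype="S1")
        arr_b = np.frombuffer(b.encode(), dtype="S1")
        ungapped = 100.0 * float((arr_a == arr_b).mean())
        if ungapped >= 75.0:
            return ungapped
    result = edlib.align(a, b, mode="NW", task="path")
    columns = sum(int(n) for n, _ in _CIGAR_RE.findall(result["cigar"]))
    return 100.0 * (columns - result["editDistance"]) / columns


def read_hit_table(path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular hit file (no header)."""
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None)


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def filter_hits(hits: pd.DataFrame, thresholds: ClassifierThresholds) -> pd.DataFrame:
    """Retain hits with evalue < max_evalue and bitscore > min_bitscore (strict)."""
    if (hits["evalue"] < 0).any():
        raise ValueError("negative e-value in hit table")
    keep = (hits["evalue"] < thresholds.max_evalue) & (
        hits["bitscore"] > thresholds.min_bitscore
    )
    return hits.loc[keep].reset_index(drop=True)


def best_hit(hits: pd.DataFrame) -> pd.DataFrame:
    """One best hit per query: max bitscore, then min e-value, then max
    identity, then lexicographically smallest subject id."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "pident", "sseqid"],
        ascending=[True, False, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("qseqid", keep="first").reset_index(drop=True)


def reciprocal_best_pairs(
    best_a_to_b: pd.DataFrame, best_b_to_a: pd.DataFrame
) -> set[tuple[str, str]]:
    """Pairs (a, b) where a's best hit is b and b's best hit is a."""
    if best_a_to_b.empty or best_b_to_a.empty:
        return set()
    fwd = dict(zip(best_a_to_b["qseqid"], best_a_to_b["sseqid"]))
    rev = dict(zip(best_b_to_a["qseqid"], best_b_to_a["sseqid"]))
    return {(a, b) for a, b in fwd.items() if rev.get(b) == a}


def subject_agreement(ref_hit_a, ref_hit_b, thresholds: ClassifierThresholds) -> bool:
    """Do two best reference hits name the same subject with similar
    identity and e-value?

    E-values are floored at 1e-200 before taking log10.
    """
    if ref_hit_a.sseqid != ref_hit_b.sseqid:
        return False
    if abs(ref_hit_a.pident - ref_hit_b.pident) > thresholds.subject_agreement_identity_tol:
        return False
    log_a = math.log10(max(ref_hit_a.evalue, _EVALUE_FLOOR))
    log_b = math.log10(max(ref_hit_b.evalue, _EVALUE_FLOOR))
    return abs(log_a - log_b) <= thresholds.subject_agreement_evalue_tol


def classify(
    contigs_a: Iterable[str],
    contigs_b: Iterable[str],
    rbh_pairs: set[tuple[str, str]],
    cross_hits: pd.DataFrame,
    ref_hits: pd.DataFrame,
    thresholds: ClassifierThresholds | None = None,
) -> pd.DataFrame:
    """Assign every contig exactly one homology category.

    Parameters
    ----------
    contigs_a, contigs_b
        Contig ids of species A and B (TE-masked, expression-filtered).
    rbh_pairs
        Reciprocal best cross-species pairs (a_id, b_id).
    cross_hits
        Filtered cross-species hits, both directions, outfmt-6 columns.
    ref_hits
        Filtered reference-database hits for contigs of both species.

    Returns a DataFrame with columns contig_id, species, category,
    gene_id, partner_ids (comma-joined) and different_region.
    """
    thr = thresholds or ClassifierThresholds()
    set_a, set_b = set(contigs_a), set(contigs_b)
    species_of = {c: "A" for c in set_a}
    species_of.update({c: "B" for c in set_b})
    known = set(species_of)

    for table, name in ((cross_hits, "cross"), (ref_hits, "reference")):
        unknown = set(table["qseqid"]) - known
        if unknown:
            raise ValueError(
                f"{name} hit table queries absent from contig sets: "
                f"{sorted(unknown)[:5]}..."
            )

    best_ref = {row.qseqid: row for row in best_hit(ref_hits).itertuples()}
    best_cross = {row.qseqid: row for row in best_hit(cross_hits).itertuples()}
    has_cross = set(cross_hits["qseqid"])

    # reference subject -> contigs of each species whose best hit names it
    by_subject: dict[str, dict[str, list[str]]] = {}
    for contig, row in best_ref.items():
        by_subject.setdefault(row.sseqid, {"A": [], "B": []})[
            species_of[contig]
        ].append(contig)

    partner_of: dict[str, str] = {}
    for a, b in rbh_pairs:
        partner_of[a] = b
        partner_of[b] = a

    def agreeing_partners(contig: str) -> list[str]:
        row = best_ref.get(contig)
        if row is None:
            return []
        other = "B" if species_of[contig] == "A" else "A"
        return sorted(
            c
            for c in by_subject.get(row.sseqid, {}).get(other, [])
            if subject_agreement(row, best_ref[c], thr)
        )

    records = []
    for contig in sorted(known):
        ref_row = best_ref.get(contig)
        gene_id = ref_row.sseqid if ref_row is not None else f"gene:{contig}"
        partner = partner_of.get(contig)
        category, partners, diff_region = None, [], False

        if (
            partner is not None
            and ref_row is not None
            and partner in best_ref
            and subject_agreement(ref_row, best_ref[partner], thr)
        ):
            category, partners = "orthologue", [partner]
        elif contig in has_cross:
            agreeing = agreeing_partners(contig)
            if agreeing:
                pident = best_cross[contig].pident
                category = (
                    "allele" if pident >= thr.allele_min_identity else "paralogue"
                )
                partners = agreeing
            else:
                category, gene_id = "species_specific", gene_id
        else:
            agreeing = agreeing_partners(contig)
            if agreeing:
                category, partners, diff_region = "orthologue", agreeing, True
            else:
                category = "species_specific"

        records.append(
            {
                "contig_id": contig,
                "species": species_of[contig],
                "category": category,
                "gene_id": gene_id,
                "partner_ids": ",".join(partners),
                "different_region": diff_region,
            }
        )
    return pd.DataFrame.from_records(records)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def allele_count(
    members: Mapping[str, Sequence[str]],
    representative: str,
    identities: Mapping[frozenset, float],
    allele_min_identity: float = 98.0,
) -> dict[str, int]:
    """Alleles per species in one cluster: members at >= allele_min_identity
    to the representative (the representative counts in its own species)."""
    counts = {}
    for species, ids in members.items():
        n = 0
        for contig in ids:
            if contig == representative:
                ident = 100.0
            else:
                ident = identities.get(frozenset((contig, representative)), 0.0)
            if ident >= allele_min_identity:
                n += 1
        counts[species] = n
    return counts


def cluster_unigenes(
    contigs: pd.DataFrame,
    identities: Iterable[tuple[str, str, float]],
    thresholds: ClassifierThresholds | None = None,
) -> list[UnigeneCluster]:
    """Single-linkage clustering of contigs into unigenes.

    Parameters
    ----------
    contigs
        DataFrame with columns contig_id, species, length.
    identities
        (id1, id2, percent identity) for compared pairs; pairs absent
        from the list are treated as unrelated. Edges require identity
        strictly above ``unigene_min_identity``.

    The cluster representative is the longest member (ties broken by
    lexicographically smallest id); allele counts follow
    :func:`allele_count`.
    """
    thr = thresholds or ClassifierThresholds()
    ids = list(contigs["contig_id"])
    uf = _UnionFind(ids)
    lookup: dict[frozenset, float] = {}
    for id1, id2, pident in identities:
        lookup[frozenset((id1, id2))] = pident
        if pident > thr.unigene_min_identity:
            uf.union(id1, id2)

    info = {
        r.contig_id: (r.species, int(r.length)) for r in contigs.itertuples()
    }
    groups: dict[str, list[str]] = {}
    for contig in ids:
        groups.setdefault(uf.find(contig), []).append(contig)

    clusters = []
    for i, root in enumerate(sorted(groups, key=lambda r: sorted(groups[r])[0])):
        member_ids = sorted(groups[root])
        members: dict[str, list[str]] = {}
        for contig in member_ids:
            members.setdefault(info[contig][0], []).append(contig)
        rep = min(member_ids, key=lambda c: (-info[c][1], c))
        counts = allele_count(members, rep, lookup, thr.allele_min_identity)
        clusters.append(
            UnigeneCluster(
                cluster_id=f"UG{i + 1:06d}",
                members=members,
                representative=rep,
                allele_count=counts,
            )
        )
    return clusters


def venn_counts(
    calls: pd.DataFrame, clusters: Sequence[UnigeneCluster] | None = None
) -> dict[str, float]:
    """Shared / species-specific counts at contig and gene level.

    Contig level mirrors the total-minus-orthologous arithmetic of the
    study design: "shared" counts orthologue-called contigs (reported per
    species and as the pair count), and every other contig, alleles and
    paralogues of shared genes included, contributes to its species'
    specific-contig total. Gene level comes from species presence in the
    unigene clusters (or, without clusters, in the per-call gene ids).
    """
    orth_a = int(((calls.category == "orthologue") & (calls.species == "A")).sum())
    orth_b = int(((calls.category == "orthologue") & (calls.species == "B")).sum())
    n_a = int((calls.species == "A").sum())
    n_b = int((calls.species == "B").sum())
    out: dict[str, float] = {
        "contig_shared_a": orth_a,
        "contig_shared_b": orth_b,
        "contig_shared_pairs": (orth_a + orth_b) / 2,
        "contig_a_specific": n_a - orth_a,
        "contig_b_specific": n_b - orth_b,
    }

    if clusters is not None:
        presence = [
            (bool(c.members.get("A")), bool(c.members.get("B"))) for c in clusters
        ]
    else:
        gene_species = calls.groupby("gene_id")["species"].agg(set)
        presence = [("A" in s, "B" in s) for s in gene_species]
    out["gene_shared"] = sum(1 for a, b in presence if a and b)
    out["gene_a_specific"] = sum(1 for a, b in presence if a and not b)
    out["gene_b_specific"] = sum(1 for a, b in presence if b and not a)
    return out
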