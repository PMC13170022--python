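"""End-to-end runs of the comparative pipeline on synthetic datasets.

Chains generation, hit filtering, reciprocal-best-hit classification,
unigene clustering, expression quantification, secretome calling, label
propagation, enrichment, TE comparison and qPCR normalization, and
scores every recoverable stage against the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import enrichment, expression, qpcr, secretome, stats_report, synthetic_data
from .homology import (
    ClassifierThresholds,
    best_hit,
    classify,
    cluster_unigenes,
    fast_identity,
    filter_hits,
    reciprocal_best_pairs,
    venn_counts,
)


def truth_label_lists(catalog: synthetic_data.TruthCatalog) -> dict[str, set[str]]:
    """Reference gene lists (essential / environment-response) implied by
    the generator truth, keyed by reference subject id."""
    frame = catalog.contigs
    return {
        "essential": set(frame.loc[frame["essential"], "reference_subject_id"]),
        "environmental": set(
            frame.loc[frame["environmental"], "reference_subject_id"]
        ),
    }


def guided_within_species_identities(
    catalog_sequences: dict[str, dict[str, str]],
    best_ref: pd.DataFrame,
) -> list[tuple[str, str, float]]:
    """Within-species pairwise identities for candidate same-gene pairs.

    All-against-all comparison of full contig sets is quadratic; instead,
    contigs of one species sharing a best reference subject are the
    candidate same-gene pairs, and only those are aligned (edit-distance
    global alignment).
    """
    seq_of = {
        cid: seq
        for per_species in catalog_sequences.values()
        for cid, seq in per_species.items()
    }
    species_of = {
        cid: sp
        for sp, per_species in catalog_sequences.items()
        for cid in per_species
    }
    edges = []
    for _, grp in best_ref.groupby("sseqid"):
        ids = sorted(grp["qseqid"])
        for i, c1 in enumerate(ids):
            for c2 in ids[i + 1 :]:
                if species_of[c1] != species_of[c2]:
                    continue
                edges.append((c1, c2, fast_identity(seq_of[c1], seq_of[c2])))
    return edges


@dataclass
class PipelineResult:
    catalog: synthetic_data.TruthCatalog
    calls: pd.DataFrame
    agreement: float
    venn: dict[str, float] = field(default_factory=dict)
    truth_venn: dict[str, float] = field(default_factory=dict)
    secretome_recovery: float = float("nan")
    secretome_sizes: dict = field(default_factory=dict)
    te_table: object = None
    te_chi2: tuple[float, int, float] | None = None
    label_accuracy: dict[str, float] = field(default_factory=dict)
    enrichment_results: pd.DataFrame | None = None
    qpcr_folds: pd.DataFrame | None = None
    rpkm_by_species: dict[str, pd.DataFrame] = field(default_factory=dict)


def truth_venn_counts(catalog: synthetic_data.TruthCatalog) -> dict[str, float]:
    """Ground-truth shared/specific counts at contig and gene level."""
    frame = catalog.contigs
    orth_a = int(
        ((frame.true_category == "orthologue") & (frame.species == "A")).sum()
    )
    orth_b = int(
        ((frame.true_category == "orthologue") & (frame.species == "B")).sum()
    )
    genes = frame.drop_duplicates("gene_id")
    return {
        "contig_shared_a": orth_a,
        "contig_shared_b": orth_b,
        "contig_shared_pairs": (orth_a + orth_b) / 2,
        "contig_a_specific": int((frame.species == "A").sum()) - orth_a,
        "contig_b_specific": int((frame.species == "B").sum()) - orth_b,
        "gene_shared": int((genes.gene_class == "shared").sum()),
        "gene_a_specific": int((genes.gene_class == "a_specific").sum()),
        "gene_b_specific": int((genes.gene_class == "b_specific").sum()),
    }


def run(
    config: synthetic_data.GeneratorConfig,
    thresholds: ClassifierThresholds | None = None,
    dropout: float = 0.0,
    cluster: bool = True,
    full: bool = True,
) -> PipelineResult:
    """Simulate one dual-species dataset and analyze it end to end.

    With ``cluster=False`` the (slower) sequence emission and unigene
    clustering are skipped; with ``full=False`` only classification and
    its truth agreement are computed.
    """
    thr = thresholds or ClassifierThresholds()
    catalog = synthetic_data.generate_truth(config)
    cross, ref = synthetic_data.emit_hit_tables(catalog, config, dropout=dropout)
    cross_f = filter_hits(cross, thr)
    ref_f = filter_hits(ref, thr)

    ids_a = catalog.species_ids("A")
    ids_b = catalog.species_ids("B")
    set_a = set(ids_a)
    a_to_b = cross_f.loc[cross_f["qseqid"].isin(set_a)]
    b_to_a = cross_f.loc[~cross_f["qseqid"].isin(set_a)]
    rbh = reciprocal_best_pairs(best_hit(a_to_b), best_hit(b_to_a))
    calls = classify(ids_a, ids_b, rbh, cross_f, ref_f, thr)

    truth = catalog.contigs[["contig_id", "true_category"]]
    merged = calls.merge(truth, on="contig_id", validate="one_to_one")
    agreement = float((merged["category"] == merged["true_category"]).mean())
    result = PipelineResult(
        catalog=catalog,
        calls=calls,
        agreement=agreement,
        truth_venn=truth_venn_counts(catalog),
    )
    if not full:
        return result

    best_ref = best_hit(ref_f)
    clusters = None
    if cluster:
        seqs = synthetic_data.emit_sequences(catalog, config)
        seq_map = {
            sp: {rec.id: str(rec.seq) for rec in records}
            for sp, records in seqs.items()
        }
        edges = guided_within_species_identities(seq_map, best_ref)
        edges += list(
            zip(cross_f["qseqid"], cross_f["sseqid"], cross_f["pident"])
        )
        members = catalog.contigs[["contig_id", "species", "length"]]
        clusters = cluster_unigenes(members, edges, thr)
    result.venn = venn_counts(calls, clusters)

    # --- secretome ---
    sec_ann, term_df, te_df = synthetic_data.emit_annotations(catalog, config)
    sec_calls = secretome.call_table(sec_ann)
    sec_merged = sec_calls.merge(
        catalog.contigs[["contig_id", "true_secreted"]], on="contig_id"
    )
    result.secretome_recovery = float(
        (sec_merged["secreted"] == sec_merged["true_secreted"]).mean()
    )
    if clusters is not None:
        result.secretome_sizes = secretome.secretome_sizes(
            sec_calls, calls, clusters
        )

    # --- TE comparison ---
    te_contigs = set(te_df["contig_id"])
    flags_a = [c in te_contigs for c in ids_a]
    flags_b = [c in te_contigs for c in ids_b]
    from .preprocess import te_containing_table

    result.te_table = te_containing_table(flags_a, flags_b)
    result.te_chi2 = stats_report.chisq_2x2(result.te_table)

    # --- labels ---
    lists = truth_label_lists(catalog)
    labeled = enrichment.propagate_labels(best_ref, lists)
    truth_labels = catalog.contigs[["contig_id", "essential", "environmental"]]
    lab = labeled.merge(
        truth_labels, on="contig_id", suffixes=("_called", "_true")
    )
    result.label_accuracy = {
        "essential": float(
            (lab["essential_called"] == lab["essential_true"]).mean()
        ),
        "environmental": float(
            (lab["environmental_called"] == lab["environmental_true"]).mean()
        ),
    }

    # --- enrichment: secreted contigs against all contigs ---
    secreted_ids = sec_calls.loc[sec_calls["secreted"], "contig_id"]
    background = catalog.contigs["contig_id"]
    sizes = enrichment.term_sizes(term_df, secreted_ids, background)
    result.enrichment_results = enrichment.enrich(sizes)

    # --- expression ---
    counts, totals = synthetic_data.emit_counts(catalog, config)
    for species in ("A", "B"):
        sub = counts.loc[counts["species"] == species]
        filtered = expression.filter_low(sub)
        result.rpkm_by_species[species] = expression.rpkm_table(
            filtered, totals[species]
        )

    # --- qPCR ---
    plate = synthetic_data.emit_qpcr(config)
    levels = qpcr.quantify(plate.measurements, plate.curves, plate.reference_genes)
    result.qpcr_folds = qpcr.species_fold_changes(levels)
    result.qpcr_folds["true_fold"] = result.qpcr_folds["gene_id"].map(
        plate.fold_truths
    )
    return result
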