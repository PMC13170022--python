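"""Homology classification: orthologues, species-specific genes,
paralogues and alleles from the hit tables, scored against truth.

Reads the simulated cross-species and reference hit tables, applies the
e-value/bitscore filter, forms reciprocal best pairs, classifies every
contig, clusters contigs into unigenes and reports the shared /
species-specific partition at contig and gene level.
"""

import pandas as pd
from Bio import SeqIO

from _common import SCRATCH_DATA, TABLES, ensure_dirs, load_config
from salivome.homology import (
    ClassifierThresholds,
    best_hit,
    classify,
    cluster_unigenes,
    filter_hits,
    read_hit_table,
    reciprocal_best_pairs,
    venn_counts,
)
from salivome.pipeline import guided_within_species_identities, truth_venn_counts
from salivome.synthetic_data import generate_truth


def main() -> None:
    ensure_dirs()
    config = load_config()
    catalog = generate_truth(config)
    thr = ClassifierThresholds()

    cross = filter_hits(read_hit_table(SCRATCH_DATA / "cross_hits.tsv"), thr)
    ref = filter_hits(read_hit_table(SCRATCH_DATA / "ref_hits.tsv"), thr)
    ids_a, ids_b = catalog.species_ids("A"), catalog.species_ids("B")

    in_a = cross["qseqid"].isin(set(ids_a))
    rbh = reciprocal_best_pairs(best_hit(cross[in_a]), best_hit(cross[~in_a]))
    calls = classify(ids_a, ids_b, rbh, cross, ref, thr)
    calls.to_csv(SCRATCH_DATA / "homology_calls.tsv", sep="\t", index=False)

    merged = calls.merge(
        catalog.contigs[["contig_id", "true_category"]], on="contig_id"
    )
    agreement = (merged.category == merged.true_category).mean()
    print(f"classified {len(calls)} contigs; truth agreement {agreement:.1%}")
    print(calls.category.value_counts().to_string())

    seq_map = {
        sp: {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(SCRATCH_DATA / f"contigs_{sp}.fasta", "fasta")
        }
        for sp in ("A", "B")
    }
    edges = guided_within_species_identities(seq_map, best_hit(ref))
    edges += list(zip(cross["qseqid"], cross["sseqid"], cross["pident"]))
    clusters = cluster_unigenes(
        catalog.contigs[["contig_id", "species", "length"]], edges, thr
    )

    venn = venn_counts(calls, clusters)
    truth_venn = truth_venn_counts(catalog)
    rows = [
        {"quantity": k, "observed": venn[k], "truth": truth_venn[k]}
        for k in sorted(venn)
    ]
    pd.DataFrame(rows).to_csv(TABLES / "venn_counts.tsv", sep="\t", index=False)
    print(pd.DataFrame(rows).to_string(index=False))

    allele_rows = []
    for sp in ("A", "B"):
        counts = [c.allele_count[sp] for c in clusters if sp in c.members]
        allele_rows.append(
            {"species": sp, "genes": len(counts),
             "mean_alleles_per_gene": sum(counts) / len(counts)}
        )
    alleles = pd.DataFrame(allele_rows)
    alleles.to_csv(TABLES / "allele_counts.tsv", sep="\t", index=False)
    print(alleles.to_string(index=False))

    members = [
        {"cluster_id": c.cluster_id, "contig_id": cid, "species": sp,
         "representative": c.representative}
        for c in clusters
        for sp, ids in c.members.items()
        for cid in ids
    ]
    pd.DataFrame(members).to_csv(
        SCRATCH_DATA / "unigene_clusters.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
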