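"""Simulate the paired-species salivary-gland dataset.

Generates the ground-truth catalog, per-species contig FASTA, the
reciprocal cross-species and reference hit tables, secretion/term/TE
annotations, read counts and the qPCR plate, and writes them under
scratch/data/ (bulky raw data) with the config and a summary under
results/.
"""

from Bio import SeqIO

from _common import CONFIG_PATH, DEFAULT_CONFIG, SCRATCH_DATA, TABLES, ensure_dirs
from salivome.homology import write_hit_table
from salivome.synthetic_data import (
    emit_annotations,
    emit_counts,
    emit_hit_tables,
    emit_qpcr,
    emit_sequences,
    generate_truth,
)


def main() -> None:
    ensure_dirs()
    config = DEFAULT_CONFIG
    config.to_yaml(CONFIG_PATH)

    catalog = generate_truth(config)
    catalog.to_tsv(SCRATCH_DATA / "truth_catalog.tsv")

    seqs = emit_sequences(catalog, config)
    for species, records in seqs.items():
        SeqIO.write(records, SCRATCH_DATA / f"contigs_{species}.fasta", "fasta")

    cross, ref = emit_hit_tables(catalog, config)
    write_hit_table(cross, SCRATCH_DATA / "cross_hits.tsv")
    write_hit_table(ref, SCRATCH_DATA / "ref_hits.tsv")

    secretion, terms, te = emit_annotations(catalog, config)
    secretion.to_csv(SCRATCH_DATA / "secretion.tsv", sep="\t", index=False)
    terms.to_csv(SCRATCH_DATA / "terms.tsv", sep="\t", index=False)
    te.to_csv(SCRATCH_DATA / "te_intervals.tsv", sep="\t", index=False)

    counts, totals = emit_counts(catalog, config)
    counts.to_csv(SCRATCH_DATA / "counts.tsv", sep="\t", index=False)

    plate = emit_qpcr(config)
    plate.measurements.to_csv(SCRATCH_DATA / "qpcr_ct.tsv", sep="\t", index=False)
    plate.curves.to_csv(SCRATCH_DATA / "qpcr_curves.tsv", sep="\t", index=False)

    frame = catalog.contigs
    summary = (
        frame.groupby(["species", "true_category"]).size().rename("contigs").reset_index()
    )
    summary.to_csv(TABLES / "dataset_summary.tsv", sep="\t", index=False)

    print(f"simulated {len(frame)} contigs over {frame.gene_id.nunique()} genes")
    print(summary.to_string(index=False))
    print(f"mapped reads: {totals}")


if __name__ == "__main__":
    main()
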