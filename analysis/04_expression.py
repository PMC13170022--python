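"""RPKM quantification and cross-species expression comparison.

Applies the read-count floor, converts counts to RPKM against each
species' own library size, and compares mean expression of shared
versus species-specific contigs between the two species.
"""

import pandas as pd

from _common import SCRATCH_DATA, TABLES, ensure_dirs
from salivome.expression import filter_low, group_mean_se, rpkm_table, two_sample_t


def main() -> None:
    ensure_dirs()
    counts = pd.read_csv(SCRATCH_DATA / "counts.tsv", sep="\t")
    calls = pd.read_csv(SCRATCH_DATA / "homology_calls.tsv", sep="\t")
    shared_ids = set(calls.loc[calls.category == "orthologue", "contig_id"])

    rows, rpkm_values = [], {}
    for species, grp in counts.groupby("species"):
        total = int(grp["count"].sum())
        kept = filter_low(grp)
        quantified = rpkm_table(kept, total)
        quantified.to_csv(
            SCRATCH_DATA / f"rpkm_{species}.tsv", sep="\t", index=False
        )
        rpkm_values[species] = quantified
        for label, subset in (
            ("shared", quantified[quantified.contig_id.isin(shared_ids)]),
            ("specific", quantified[~quantified.contig_id.isin(shared_ids)]),
        ):
            mean, se = group_mean_se(subset["rpkm"])
            rows.append(
                {
                    "species": species,
                    "subset": label,
                    "contigs_kept": len(subset),
                    "filtered_out": len(grp) - len(kept),
                    "mean_rpkm": round(mean, 3),
                    "se_rpkm": round(se, 3),
                }
            )

    summary = pd.DataFrame(rows)
    for label in ("shared", "specific"):
        a = rpkm_values["A"].loc[
            rpkm_values["A"].contig_id.isin(shared_ids) == (label == "shared"), "rpkm"
        ]
        b = rpkm_values["B"].loc[
            rpkm_values["B"].contig_id.isin(shared_ids) == (label == "shared"), "rpkm"
        ]
        t, _, p = two_sample_t(a, b)
        summary.loc[summary.subset == label, "t_vs_other_species"] = round(t, 3)
        summary.loc[summary.subset == label, "p"] = p

    summary.to_csv(TABLES / "expression_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
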