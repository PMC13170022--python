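"""Secretome calling and shared / species-specific secreted-gene sizes.

Runs the secretion decision cascade over the predictor annotation table,
scores it against the generator truth, and aggregates secreted contigs
to secreted genes through the unigene clusters.
"""

import pandas as pd

from _common import SCRATCH_DATA, TABLES, ensure_dirs, load_config
from salivome.homology import UnigeneCluster
from salivome.secretome import call_table, secretome_sizes
from salivome.stats_report import chisq_gof_1to1
from salivome.synthetic_data import generate_truth


def load_clusters() -> list[UnigeneCluster]:
    frame = pd.read_csv(SCRATCH_DATA / "unigene_clusters.tsv", sep="\t")
    clusters = []
    for (cid, rep), grp in frame.groupby(["cluster_id", "representative"]):
        members: dict[str, list[str]] = {}
        for row in grp.itertuples():
            members.setdefault(row.species, []).append(row.contig_id)
        clusters.append(UnigeneCluster(cid, members, rep))
    return clusters


def main() -> None:
    ensure_dirs()
    config = load_config()
    catalog = generate_truth(config)
    annotations = pd.read_csv(SCRATCH_DATA / "secretion.tsv", sep="\t")

    calls = call_table(annotations)
    merged = calls.merge(
        catalog.contigs[["contig_id", "true_secreted"]], on="contig_id"
    )
    recovery = (merged.secreted == merged.true_secreted).mean()
    print(f"secretion cascade: {int(calls.secreted.sum())} of {len(calls)} "
          f"contigs called secreted; truth recovery {recovery:.1%}")
    print(calls.reason.value_counts().to_string())

    homology_calls = pd.read_csv(SCRATCH_DATA / "homology_calls.tsv", sep="\t")
    sizes = secretome_sizes(calls, homology_calls, load_clusters())
    chi2, _, p = chisq_gof_1to1(sizes["a_specific"], sizes["b_specific"])
    out = pd.DataFrame(
        [
            {
                "shared_secreted_genes": sizes["shared"],
                "a_specific": sizes["a_specific"],
                "b_specific": sizes["b_specific"],
                "a_over_b_ratio": sizes["ratio"],
                "chi2_1to1": round(chi2, 2),
                "p": p,
            }
        ]
    )
    out.to_csv(TABLES / "secretome_sizes.tsv", sep="\t", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
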