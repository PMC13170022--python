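"""Label propagation and hypergeometric term enrichment.

Carries essential / environment-response labels from the reference gene
lists onto contigs via best reference hits, then tests the secreted
contig set for term over-representation against the full background
(the generator plants one secretion-associated term).
"""

import pandas as pd

from _common import SCRATCH_DATA, TABLES, ensure_dirs, load_config
from salivome.enrichment import enrich, propagate_labels, term_sizes, top_terms
from salivome.homology import ClassifierThresholds, best_hit, filter_hits, read_hit_table
from salivome.pipeline import truth_label_lists
from salivome.secretome import call_table
from salivome.synthetic_data import SECRETED_TERM, generate_truth


def main() -> None:
    ensure_dirs()
    config = load_config()
    catalog = generate_truth(config)
    thr = ClassifierThresholds()
    ref = filter_hits(read_hit_table(SCRATCH_DATA / "ref_hits.tsv"), thr)
    best_ref = best_hit(ref)

    lists = truth_label_lists(catalog)
    labeled = propagate_labels(best_ref, lists)
    print(
        f"labels: {int(labeled.essential.sum())} essential and "
        f"{int(labeled.environmental.sum())} environment-response contigs "
        f"({len(lists['essential'])} / {len(lists['environmental'])} reference genes)"
    )

    terms = pd.read_csv(SCRATCH_DATA / "terms.tsv", sep="\t")
    secreted = call_table(pd.read_csv(SCRATCH_DATA / "secretion.tsv", sep="\t"))
    subset = secreted.loc[secreted.secreted, "contig_id"]
    background = catalog.contigs["contig_id"]
    results = enrich(term_sizes(terms, subset, background))
    best = top_terms(results, top_n=10)
    best.to_csv(TABLES / "enrichment_top_terms.tsv", sep="\t", index=False)
    print(best.to_string(index=False))
    planted = best.term_id.iloc[0] if len(best) else None
    print(f"top enriched term: {planted} "
          f"(planted secretion-associated term is {SECRETED_TERM})")


if __name__ == "__main__":
    main()
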