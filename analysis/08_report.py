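"""Assemble the final report: published ratio arithmetic plus the
summary tables of the simulated analysis chain."""

import pandas as pd

from _common import REPO, TABLES, ensure_dirs
from salivome.enrichment import size_ratio
from salivome.qpcr import fold_change
from salivome.stats_report import build_report
from salivome.study_counts import QPCR_FOLD_OPERANDS, SIZE_RATIO_OPERANDS


def main() -> None:
    ensure_dirs()
    ratio_rows = [
        {"quantity": name, "count_a": a, "count_b": b, "a_over_b": size_ratio(a, b)}
        for name, (a, b) in SIZE_RATIO_OPERANDS.items()
    ] + [
        {"quantity": f"qpcr_{name}", "count_a": a, "count_b": b,
         "a_over_b": fold_change(a, b)}
        for name, (a, b) in QPCR_FOLD_OPERANDS.items()
    ]
    ratios = pd.DataFrame(ratio_rows)

    outputs: dict[str, object] = {"published_ratios": ratios}
    for table in sorted(TABLES.glob("*.tsv")):
        outputs[table.stem] = pd.read_csv(table, sep="\t")

    summary = build_report(outputs, REPO / "results" / "report")
    print("report sections:", ", ".join(sorted(summary)))
    print(ratios.to_string(index=False))


if __name__ == "__main__":
    main()
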