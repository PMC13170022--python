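"""Published summary counts of the two-species salivary-gland comparison.

Operand counts printed alongside the headline generalist/specialist
(H. armigera / H. assulta) size ratios of the larval labial salivary
gland transcriptome study: total and species-specific contig and gene
counts, selected GO/KEGG term sizes, essential and environment-response
gene counts, and the normalized qPCR means of the two validation genes
whose printed ratios are arithmetically consistent with their printed
means (ecdysone oxidase and yellow-d). Each entry is (count_a, count_b)
with A the generalist and B the specialist; ratios are recomputed from
these operands, never stored.
"""

from __future__ import annotations

#: (A, B) operand pairs for size-ratio recomputation
SIZE_RATIO_OPERANDS: dict[str, tuple[float, float]] = {
    # total assembled contigs / clustered unigenes per species
    "total_contigs": (85801, 45547),
    "total_unigenes": (69340, 36345),
    # species-specific contigs and genes (Venn partitions)
    "specific_contigs": (70493, 30239),
    "specific_genes": (20998, 11168),
    # essential vs environment-response species-specific gene counts
    "specific_essential_genes": (24, 16),
    "specific_environmental_genes": (621, 246),
    # environment-response genes: species-specific total vs shared
    "environmental_specific_vs_shared": (621 + 246, 303),
    # selected term sizes (A-specific vs B-specific contig counts)
    "go_aminoacyl_trna_synthetase_complex": (105, 2),
    "go_detoxification": (60, 2),
    "kegg_protein_export": (283, 4),
    # total assembled bases
    "assembled_bases": (51412837, 46013942),
}

#: normalized qPCR expression means (A, B) of the validation genes
QPCR_FOLD_OPERANDS: dict[str, tuple[float, float]] = {
    "ecdysone_oxidase": (3.29, 0.68),
    "yellow_d": (2.63, 1.09),
}
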