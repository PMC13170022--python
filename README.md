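# salivome

Cross-species comparison of larval labial salivary gland transcriptomes
between a generalist herbivore and a closely related specialist
(*Helicoverpa armigera* vs *H. assulta* style designs). The package
implements, as a tested and reusable pipeline, the analysis chain such
studies run over de novo assemblies: read QC, transposable-element (TE)
masking, a rule-based homology classifier, unigene clustering, RPKM
quantification, a secreted-protein decision cascade, hypergeometric
functional enrichment, chi-square size comparisons and
efficiency-corrected qPCR normalization — exercised end to end on a
synthetic dual-species dataset with known ground truth.

It is aimed at comparative transcriptomics of non-model insects, where
no per-species genome exists and the expressed gene repertoires of two
species must be compared from assembly contigs alone.

## The core classification

Given TE-masked contig sets of species A and B, a reciprocal
cross-species search, and searches of both sets against a reference
database (hits retained at e-value < 10⁻⁵ and bitscore > 60):

* contig pairs that are **reciprocal best hits** and hit the same
  reference subject with similar identity and e-value are
  **orthologues**;
* contigs with no retained cross-species hit whose reference subject is
  hit by no contig of the other species are **species-specifically
  expressed**;
* contigs without a cross-species hit that still agree on a reference
  subject with an other-species contig are orthologues transcribed from
  **different regions** of the same gene;
* remaining same-subject, non-best-matching contigs are split at 98%
  cross-species nucleotide identity: ≥ 98% **alleles**, < 98%
  **paralogues**.

Contigs above 94% mutual identity form single-linkage clusters
(**unigenes**), each treated as one expressed gene. Downstream, secreted
proteins are called by `signal peptide OR NN-score > 0.5`, excluding any
contig with transmembrane helices or a GPI anchor; term enrichment uses
the upper-tail hypergeometric test with Benjamini–Hochberg correction;
qPCR targets are normalized by
(1+E_t)^(−Ct_t) / ∛∏ᵣ(1+E_r)^(−Ct_r) with E = 10^(−1/slope) − 1 from
the standard curve.

## Worked example

The numbered scripts under `analysis/` run the study design over a
simulated 5,000-gene dual-species dataset (defaults in
`analysis/_common.py`), writing raw data under `scratch/data/` and
summary tables under `results/tables/`:

```sh
python analysis/01_simulate.py
python analysis/03_classify.py
```

prints (abridged):

```
simulated 9834 contigs over 5000 genes
classified 9834 contigs; truth agreement 100.0%
           quantity  observed  truth
  contig_a_specific    4624.0 4624.0
  contig_b_specific    2812.0 2812.0
contig_shared_pairs    1199.0 1199.0
    gene_a_specific    2490.0 2490.0
    gene_b_specific    1311.0 1311.0
        gene_shared    1199.0 1199.0
```

i.e. on clean hit tables the classifier reproduces every ground-truth
category and the shared / species-specific partition exactly, at both
contig and gene level. `05_secretome.py` recovers the secreted flag of
every contig (`truth recovery 100.0%`) and reports an A/B specific
secreted-gene ratio of 2.0 with its 1:1 chi-square; `07_qpcr.py`
recovers the six configured fold changes within 4.1% at a Ct noise of
0.1 cycles (and exactly at zero noise).

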