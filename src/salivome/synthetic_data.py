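"""Synthetic paired-species salivary-gland transcriptome datasets.

Generates everything the comparative pipeline consumes — per-species
contig FASTA, cross-species and reference hit tables, secretion/TE/term
annotations, negative-binomial read counts and qPCR plates — together
with a ground-truth catalog, so that every downstream stage has a
recoverable answer.

Construction keeps all pairwise identities analytic: each ancestral gene
has a uniform-random nucleotide template; orthologous primary contigs
carry the template unchanged, and allele/paralogue copies substitute
bases at disjoint uniform positions (no indels), so the identity between
any two contigs of a gene is exactly 100 * (1 - (s1 + s2) / L).
Reference hits of all contigs of a gene share one subject with one
identity and e-value, making the same-subject agreement rule exact by
construction. Hit e-values are a deterministic decreasing function of
the bitscore, which is itself a deterministic function of identity and
length; only their ordering matters downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homology import HIT_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic dual-species dataset.

    The defaults emulate the observed structure of the two-species
    salivary-gland comparison: gene-level shared : A-specific :
    B-specific proportions near 0.25 : 0.49 : 0.26 (an A/B
    species-specific gene ratio near 1.9), a specialist (B) with a
    three-fold higher per-contig TE insertion probability than the
    generalist (A), roughly 30% secreted genes, and qPCR targets whose
    true cross-species fold changes are the six verified values of the
    validation experiment.
    """

    n_genes: int = 5000
    p_shared: float = 0.25
    p_a_specific: float = 0.49
    p_b_specific: float = 0.26
    paralog_rate: float = 0.2
    allele_rate: float = 0.4
    identity_allele_range: tuple[float, float] = (98.2, 99.8)
    identity_paralog_range: tuple[float, float] = (94.6, 97.5)
    te_insertion_prob_a: float = 0.1
    te_insertion_prob_b: float = 0.3
    secreted_prob: float = 0.3
    essential_prob: float = 0.02
    environmental_prob: float = 0.05
    nb_mean: float = 100.0
    nb_dispersion: float = 0.5
    contig_len_range: tuple[int, int] = (300, 1500)
    qpcr_fold_truths: tuple[float, ...] = (4.84, 2.41, 259.61, 3.57, 317.66, 6.53)
    qpcr_ct_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_shared + self.p_a_specific + self.p_b_specific
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gene-class probabilities sum to {total}, not 1")
        for name in (
            "p_shared",
            "p_a_specific",
            "p_b_specific",
            "te_insertion_prob_a",
            "te_insertion_prob_b",
            "secreted_prob",
            "essential_prob",
            "environmental_prob",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name}={value} outside [0, 1]")
        lo, hi = self.identity_allele_range
        if not (98.0 <= lo <= hi <= 100.0):
            raise ValueError("allele identity range must lie in [98, 100]")
        lo, hi = self.identity_paralog_range
        if not (0 < lo <= hi < 98.0):
            raise ValueError("paralogue identity range must lie below 98")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("identity_allele_range", "identity_paralog_range",
                    "contig_len_range", "qpcr_fold_truths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v
                 for k, v in asdict(self).items()},
                fh,
                sort_keys=True,
            )


@dataclass
class TruthCatalog:
    """Ground truth for every synthetic contig.

    ``contigs`` columns: contig_id, species (A/B), gene_id, gene_class
    (shared | a_specific | b_specific), true_category (orthologue |
    species_specific | paralogue | allele), true_secreted, essential,
    environmental, true_expression_mean, te_inserted,
    reference_subject_id, ref_pident, length, n_subs.
    """

    contigs: pd.DataFrame
    config: GeneratorConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.contigs)

    def species_ids(self, species: str) -> list[str]:
        return list(
            self.contigs.loc[self.contigs["species"] == species, "contig_id"]
        )

    def to_tsv(self, path) -> None:
        self.contigs.to_csv(path, sep="\t", index=False)


_COLUMNS = [
    "contig_id",
    "species",
    "gene_id",
    "gene_class",
    "true_category",
    "true_secreted",
    "essential",
    "environmental",
    "true_expression_mean",
    "te_inserted",
    "reference_subject_id",
    "ref_pident",
    "length",
    "n_subs",
]


def _substitution_count(
    rng: np.random.Generator,
    length: int,
    identity_range: tuple[float, float],
    kind: str,
) -> int:
    """Draw a substitution count realizing an identity inside the range,
    clamped to the correct side of the 98% allele/paralogue boundary."""
    target = rng.uniform(*identity_range)
    subs = round(length * (100.0 - target) / 100.0)
    boundary = math.floor(length * 0.02)  # max subs with identity >= 98
    if kind == "allele":
        lo, hi = 1, boundary
    else:
        lo, hi = boundary + 1, math.floor(length * (100.0 - 90.0) / 100.0)
    if lo > hi:
        raise ValueError(
            f"contig length {length} too small to realize a distinct {kind} copy"
        )
    return int(min(max(subs, lo), hi))


def generate_truth(config: GeneratorConfig) -> TruthCatalog:
    """Draw gene classes, copy structure and labels; deterministic in seed."""
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_genes
    if n == 0:
        return TruthCatalog(pd.DataFrame(columns=_COLUMNS), config)

    classes = rng.choice(
        ["shared", "a_specific", "b_specific"],
        size=n,
        p=[config.p_shared, config.p_a_specific, config.p_b_specific],
    )
    lo, hi = config.contig_len_range
    lengths = rng.integers(lo, hi + 1, size=n)
    ref_pident = np.round(rng.uniform(85.0, 99.0, size=n), 1)
    secreted = rng.random(n) < config.secreted_prob
    essential = rng.random(n) < config.essential_prob
    environmental = rng.random(n) < config.environmental_prob
    n_allele = rng.poisson(config.allele_rate, size=(n, 2))
    n_paralog = rng.poisson(config.paralog_rate, size=(n, 2))

    rows: list[dict] = []
    counters = {"A": 0, "B": 0}

    def add_contig(gene: int, species: str, category: str, subs: int) -> None:
        counters[species] += 1
        contig_id = f"{species}{counters[species]:06d}"
        te_prob = (
            config.te_insertion_prob_a
            if species == "A"
            else config.te_insertion_prob_b
        )
        rows.append(
            {
                "contig_id": contig_id,
                "species": species,
                "gene_id": f"G{gene:06d}",
                "gene_class": classes[gene],
                "true_category": category,
                "true_secreted": bool(secreted[gene]),
                "essential": bool(essential[gene]),
                "environmental": bool(environmental[gene]),
                "true_expression_mean": config.nb_mean,
                "te_inserted": bool(rng.random() < te_prob),
                "reference_subject_id": f"REF{gene:06d}",
                "ref_pident": float(ref_pident[gene]),
                "length": int(lengths[gene]),
                "n_subs": subs,
            }
        )

    for g in range(n):
        length = int(lengths[g])
        gene_species = (
            ("A", "B")
            if classes[g] == "shared"
            else (("A",) if classes[g] == "a_specific" else ("B",))
        )
        for si, species in enumerate(gene_species):
            primary_cat = (
                "orthologue" if classes[g] == "shared" else "species_specific"
            )
            add_contig(g, species, primary_cat, 0)
            for kind, count in (
                ("allele", n_allele[g, si]),
                ("paralogue", n_paralog[g, si]),
            ):
                for _ in range(count):
                    subs = _substitution_count(
                        rng,
                        length,
                        config.identity_allele_range
                        if kind == "allele"
                        else config.identity_paralog_range,
                        kind,
                    )
                    # copies of species-specific genes are themselves
                    # species-specifically expressed; allele/paralogue
                    # categories only exist relative to the other species
                    category = kind if classes[g] == "shared" else "species_specific"
                    add_contig(g, species, category, subs)

    frame = pd.DataFrame.from_records(rows, columns=_COLUMNS)
    if frame["contig_id"].duplicated().any():
        raise AssertionError("duplicate contig ids generated")
    return TruthCatalog(frame, config)


def emit_sequences(
    catalog: TruthCatalog, config: GeneratorConfig
) -> dict[str, list[SeqRecord]]:
    """Per-species FASTA records realizing the catalog's identities.

    Substituted positions are disjoint across the copies of a gene and
    every substitution changes the base, so pairwise identities equal
    100 * (1 - (s1 + s2) / L) exactly.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    records: dict[str, list[SeqRecord]] = {"A": [], "B": []}
    frame = catalog.contigs.sort_values("contig_id", kind="mergesort")
    for gene_id, grp in frame.groupby("gene_id", sort=True):
        gene_index = int(gene_id[1:])
        length = int(grp["length"].iloc[0])
        rng = np.random.default_rng([config.seed, 17, gene_index])
        template = rng.integers(0, 4, size=length)
        positions = rng.permutation(length)
        offset = 0
        total_subs = int(grp["n_subs"].sum())
        if total_subs > length:
            raise ValueError(
                f"gene {gene_id}: substitution budget {total_subs} exceeds "
                f"length {length}"
            )
        for row in grp.itertuples():
            seq = template.copy()
            subs = int(row.n_subs)
            if subs:
                where = positions[offset : offset + subs]
                offset += subs
                shifts = rng.integers(1, 4, size=subs)
                seq[where] = (seq[where] + shifts) % 4
            bases = _BASES[seq].tobytes().decode()
            records[row.species].append(
                SeqRecord(Seq(bases), id=row.contig_id, description="")
            )
    for species in records:
        records[species].sort(key=lambda r: r.id)
    return records


def _score_hit(pident: float, length: int) -> tuple[float, float]:
    """Deterministic (bitscore, evalue) from identity and length."""
    bitscore = round(2.0 * length * pident / 100.0, 1)
    evalue = max(10.0 ** (-bitscore / 10.0), 1e-200)
    return bitscore, evalue


def _hit_row(qseqid, sseqid, pident, length, mismatch) -> dict:
    bitscore, evalue = _score_hit(pident, length)
    return {
        "qseqid": qseqid,
        "sseqid": sseqid,
        "pident": round(pident, 3),
        "length": length,
        "mismatch": mismatch,
        "gapopen": 0,
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": evalue,
        "bitscore": bitscore,
    }


def emit_hit_tables(
    catalog: TruthCatalog,
    config: GeneratorConfig,
    dropout: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-species hits (both directions) and reference hits.

    Every contig pair of a shared gene yields hits in both directions
    with pident equal to the construction identity, so true orthologue
    pairs are mutual best hits. Every contig hits its gene's reference
    subject with the gene's reference identity/e-value. With
    ``dropout`` > 0 each cross-species hit row is independently removed
    with that probability (robustness experiments).
    """
    cross_rows: list[dict] = []
    ref_rows: list[dict] = []
    for _, grp in catalog.contigs.groupby("gene_id", sort=True):
        length = int(grp["length"].iloc[0])
        subject = grp["reference_subject_id"].iloc[0]
        ref_pident = float(grp["ref_pident"].iloc[0])
        ref_mismatch = round(length * (100.0 - ref_pident) / 100.0)
        for row in grp.itertuples():
            ref_rows.append(
                _hit_row(row.contig_id, subject, ref_pident, length, ref_mismatch)
            )
        a_side = grp.loc[grp["species"] == "A"]
        b_side = grp.loc[grp["species"] == "B"]
        for ra in a_side.itertuples():
            for rb in b_side.itertuples():
                subs = int(ra.n_subs) + int(rb.n_subs)
                pident = 100.0 * (1.0 - subs / length)
                cross_rows.append(
                    _hit_row(ra.contig_id, rb.contig_id, pident, length, subs)
                )
                cross_rows.append(
                    _hit_row(rb.contig_id, ra.contig_id, pident, length, subs)
                )
    cross = pd.DataFrame.from_records(cross_rows, columns=HIT_COLUMNS)
    ref = pd.DataFrame.from_records(ref_rows, columns=HIT_COLUMNS)
    if dropout > 0 and not cross.empty:
        rng = np.random.default_rng([config.seed, 23])
        keep = rng.random(len(cross)) >= dropout
        cross = cross.loc[keep].reset_index(drop=True)
    return cross, ref


#: invented GO/KEGG-style term pool; two terms carry planted signal
TERM_POOL = [f"GO:{7000000 + i}" for i in range(18)] + [
    f"ko{90100 + i}" for i in range(8)
]
SECRETED_TERM = "GO:7000001"
ENVIRONMENT_TERM = "GO:7000002"


def emit_annotations(
    catalog: TruthCatalog, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Secretion annotations, term assignments and TE intervals.

    Secretion predictor outputs are constructed consistent with
    ``true_secreted`` (a true secreted contig always passes the cascade;
    a non-secreted one fails through a random rejection mode). Term
    assignments plant enrichment signal: secreted genes preferentially
    carry SECRETED_TERM and environmental genes ENVIRONMENT_TERM. TE
    intervals (TSV convention: 1-based inclusive) are emitted for every
    contig flagged ``te_inserted``.
    """
    rng = np.random.default_rng([config.seed, 31])
    sec_rows, te_rows, term_rows = [], [], []
    gene_terms: dict[str, list[str]] = {}
    for row in catalog.contigs.itertuples():
        if row.true_secreted:
            classical = rng.random() < 0.7
            sec_rows.append(
                {
                    "contig_id": row.contig_id,
                    "signal_peptide": int(classical),
                    "nn_score": round(
                        rng.uniform(0.55, 0.95) if not classical else rng.uniform(0, 0.45),
                        3,
                    ),
                    "tm_helix_count": 0,
                    "gpi_anchor": 0,
                }
            )
        else:
            mode = rng.choice(["no_signal", "tm", "gpi"], p=[0.6, 0.3, 0.1])
            sec_rows.append(
                {
                    "contig_id": row.contig_id,
                    "signal_peptide": int(mode != "no_signal" and rng.random() < 0.5),
                    "nn_score": round(
                        rng.uniform(0, 0.5)
                        if mode == "no_signal"
                        else rng.uniform(0, 0.9),
                        3,
                    ),
                    "tm_helix_count": int(rng.integers(1, 6)) if mode == "tm" else 0,
                    "gpi_anchor": int(mode == "gpi"),
                }
            )
        if row.te_inserted:
            te_len = int(rng.integers(50, max(51, min(300, row.length // 2) + 1)))
            start0 = int(rng.integers(0, row.length - te_len + 1))
            te_rows.append(
                {
                    "contig_id": row.contig_id,
                    "start": start0 + 1,
                    "end": start0 + te_len,
                }
            )
        if row.gene_id not in gene_terms:
            k = int(rng.integers(1, 4))
            terms = list(rng.choice(TERM_POOL, size=k, replace=False))
            if row.true_secreted and rng.random() < 0.7:
                terms.append(SECRETED_TERM)
            if row.environmental and rng.random() < 0.7:
                terms.append(ENVIRONMENT_TERM)
            gene_terms[row.gene_id] = sorted(set(terms))
        for term in gene_terms[row.gene_id]:
            term_rows.append({"id": row.contig_id, "term_id": term})
    return (
        pd.DataFrame.from_records(
            sec_rows,
            columns=[
                "contig_id",
                "signal_peptide",
                "nn_score",
                "tm_helix_count",
                "gpi_anchor",
            ],
        ),
        pd.DataFrame.from_records(term_rows, columns=["id", "term_id"]),
        pd.DataFrame.from_records(te_rows, columns=["contig_id", "start", "end"]),
    )


def emit_counts(
    catalog: TruthCatalog, config: GeneratorConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Negative-binomial read counts per contig and per-species totals.

    counts ~ NB(mean = true_expression_mean, size = nb_dispersion); the
    per-species total mapped reads is the sum of that species' contig
    counts (count conservation).
    """
    rng = np.random.default_rng([config.seed, 41])
    means = catalog.contigs["true_expression_mean"].to_numpy(dtype=float)
    r = config.nb_dispersion
    counts = np.zeros(len(means), dtype=int)
    positive = means > 0
    if positive.any():
        p = r / (r + means[positive])
        counts[positive] = rng.negative_binomial(r, p)
    table = pd.DataFrame(
        {
            "contig_id": catalog.contigs["contig_id"],
            "species": catalog.contigs["species"],
            "count": counts,
            "length": catalog.contigs["length"],
        }
    )
    totals = table.groupby("species")["count"].sum().astype(int).to_dict()
    return table, totals


#: reference-gene roles and efficiencies of the qPCR plate
QPCR_REFERENCES: tuple[tuple[str, float], ...] = (
    ("RPL13", 0.90),
    ("RPL32", 0.95),
    ("BTUB", 1.00),
)
_TARGET_EFFICIENCIES = (0.95, 0.90, 1.00, 0.92, 0.88, 0.97)


@dataclass
class QPCRDataset:
    measurements: pd.DataFrame  # sample_id, species, gene_id, replicate, ct
    curves: pd.DataFrame  # gene_id, slope
    reference_genes: tuple[str, ...]
    fold_truths: dict[str, float]


def emit_qpcr(config: GeneratorConfig, n_samples: int = 3, n_replicates: int = 3) -> QPCRDataset:
    """qPCR plate whose normalization recovers the configured fold changes.

    Reference genes have zero true fold change (equal base Ct in both
    species); each target's species-A Ct is shifted by
    log(fold) / log(1 + E) cycles below the species-B Ct, so the
    efficiency-corrected normalization recovers the configured fold in
    expectation. Gaussian Ct noise with sd ``qpcr_ct_sd`` is added per
    replicate.
    """
    if not config.qpcr_fold_truths:
        raise ValueError("qpcr_fold_truths must be nonempty")
    rng = np.random.default_rng([config.seed, 53])
    targets = [f"TG{i + 1}" for i in range(len(config.qpcr_fold_truths))]
    eff = {
        name: _TARGET_EFFICIENCIES[i % len(_TARGET_EFFICIENCIES)]
        for i, name in enumerate(targets)
    }
    base_ct = {name: 24.0 + i for i, name in enumerate(targets)}
    ref_base = {name: 20.0 + i for i, (name, _) in enumerate(QPCR_REFERENCES)}
    eff.update(dict(QPCR_REFERENCES))

    rows = []
    for species in ("A", "B"):
        for s in range(1, n_samples + 1):
            sample = f"{species}{s}"
            for gene in targets + [name for name, _ in QPCR_REFERENCES]:
                if gene in ref_base:
                    ct0 = ref_base[gene]
                else:
                    ct0 = base_ct[gene]
                    if species == "A":
                        fold = config.qpcr_fold_truths[targets.index(gene)]
                        ct0 = ct0 - math.log(fold) / math.log(1.0 + eff[gene])
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, config.qpcr_ct_sd) if config.qpcr_ct_sd else 0.0
                    rows.append(
                        {
                            "sample_id": sample,
                            "species": species,
                            "gene_id": gene,
                            "replicate": rep,
                            "ct": ct0 + noise,
                        }
                    )
    curves = pd.DataFrame(
        {
            "gene_id": list(eff),
            "slope": [-1.0 / math.log10(1.0 + e) for e in eff.values()],
        }
    )
    return QPCRDataset(
        measurements=pd.DataFrame.from_records(rows),
        curves=curves,
        reference_genes=tuple(name for name, _ in QPCR_REFERENCES),
        fold_truths=dict(zip(targets, config.qpcr_fold_truths)),
    )
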