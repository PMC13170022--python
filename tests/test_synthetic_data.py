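"""The generator must be deterministic, hit its configured distributions,
and emit data whose identities and counts are consistent with its own
ground-truth catalog."""

import numpy as np
import pandas as pd
import pytest

from salivome import qpcr, stats_report
from salivome.synthetic_data import (
    GeneratorConfig,
    emit_counts,
    emit_annotations,
    emit_hit_tables,
    emit_qpcr,
    emit_sequences,
    generate_truth,
)


class TestConfig:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig(p_shared=0.5, p_a_specific=0.5, p_b_specific=0.5)

    def test_identity_ranges_respect_allele_boundary(self):
        with pytest.raises(ValueError):
            GeneratorConfig(identity_allele_range=(97.0, 99.0))
        with pytest.raises(ValueError):
            GeneratorConfig(identity_paralog_range=(95.0, 98.5))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(n_genes=7, seed=3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert GeneratorConfig.from_yaml(path) == cfg


class TestGenerateTruth:
    def test_empty_when_no_genes(self):
        catalog = generate_truth(GeneratorConfig(n_genes=0))
        assert len(catalog) == 0

    def test_deterministic_given_seed(self, small_config, small_catalog):
        again = generate_truth(small_config)
        pd.testing.assert_frame_equal(small_catalog.contigs, again.contigs)

    def test_contig_ids_unique(self, small_catalog):
        assert small_catalog.contigs["contig_id"].is_unique

    def test_specific_gene_ratio_realized(self):
        # A/B specific-gene odds set to 2.33; realized ratio from truth
        # counts should land within 5% by binomial sampling at n=50000
        cfg = GeneratorConfig(
            n_genes=50000,
            p_shared=0.30,
            p_a_specific=0.70 * 2.33 / 3.33,
            p_b_specific=0.70 * 1.00 / 3.33,
            allele_rate=0.0,
            paralog_rate=0.0,
            seed=5,
        )
        genes = generate_truth(cfg).contigs.drop_duplicates("gene_id")
        ratio = (genes.gene_class == "a_specific").sum() / (
            genes.gene_class == "b_specific"
        ).sum()
        assert ratio == pytest.approx(2.33, rel=0.05)


class TestSequences:
    def test_deterministic(self, small_catalog, small_config):
        one = emit_sequences(small_catalog, small_config)
        two = emit_sequences(small_catalog, small_config)
        for sp in ("A", "B"):
            assert [str(r.seq) for r in one[sp]] == [str(r.seq) for r in two[sp]]

    def test_substitution_identity_arithmetic(self, small_catalog, small_config):
        """Hamming identity of each copy to its gene primary equals
        100 * (1 - n_subs / L): 0 subs -> 100%, 10/1000 -> 99%, etc."""
        seqs = emit_sequences(small_catalog, small_config)
        seq_of = {r.id: str(r.seq) for sp in seqs.values() for r in sp}
        frame = small_catalog.contigs
        checked = 0
        for _, grp in frame.groupby("gene_id"):
            primaries = grp.loc[grp["n_subs"] == 0, "contig_id"]
            copies = grp.loc[grp["n_subs"] > 0]
            if primaries.empty or copies.empty:
                continue
            template = seq_of[primaries.iloc[0]]
            for row in copies.itertuples():
                seq = seq_of[row.contig_id]
                mismatches = sum(a != b for a, b in zip(template, seq))
                assert mismatches == row.n_subs
                identity = 100.0 * (1 - mismatches / row.length)
                if row.true_category == "allele":
                    assert identity >= 98.0
                elif row.true_category == "paralogue":
                    assert identity < 98.0
                checked += 1
        assert checked > 10

    def test_empty_catalog_rejected(self, small_config):
        empty = generate_truth(GeneratorConfig(n_genes=0))
        with pytest.raises(ValueError):
            emit_sequences(empty, small_config)

    def test_short_contigs_cannot_realize_allele(self):
        cfg = GeneratorConfig(
            n_genes=50, contig_len_range=(20, 30), allele_rate=2.0, seed=1
        )
        with pytest.raises(ValueError, match="too small"):
            generate_truth(cfg)


class TestHitTables:
    def test_orthologue_pairs_are_mutual_best(self, small_catalog, small_config):
        cross, _ = emit_hit_tables(small_catalog, small_config)
        frame = small_catalog.contigs
        orth = frame.loc[frame["true_category"] == "orthologue"]
        pairs = orth.groupby("gene_id")["contig_id"].agg(list)
        best = cross.sort_values("bitscore", ascending=False).drop_duplicates(
            "qseqid"
        )
        best_map = dict(zip(best["qseqid"], best["sseqid"]))
        for members in pairs:
            a, b = sorted(members)
            assert best_map[a] == b and best_map[b] == a

    def test_species_specific_contigs_have_only_reference_hits(
        self, small_catalog, small_config
    ):
        cross, ref = emit_hit_tables(small_catalog, small_config)
        frame = small_catalog.contigs
        specific = set(
            frame.loc[frame["true_category"] == "species_specific", "contig_id"]
        )
        assert specific.isdisjoint(set(cross["qseqid"]))
        per_contig = ref.groupby("qseqid").size()
        assert (per_contig.loc[list(specific)] == 1).all()

    def test_hit_identity_matches_truth(self, small_catalog, small_config):
        """Emitted pident equals 100*(1 - (s1+s2)/L) from the catalog."""
        cross, _ = emit_hit_tables(small_catalog, small_config)
        info = small_catalog.contigs.set_index("contig_id")
        for row in cross.sample(200, random_state=0).itertuples():
            q, s = info.loc[row.qseqid], info.loc[row.sseqid]
            expected = 100.0 * (1 - (q.n_subs + s.n_subs) / q.length)
            assert row.pident == pytest.approx(expected, abs=0.05)

    def test_dropout_removes_rows_deterministically(
        self, small_catalog, small_config
    ):
        full, _ = emit_hit_tables(small_catalog, small_config)
        one, _ = emit_hit_tables(small_catalog, small_config, dropout=0.2)
        two, _ = emit_hit_tables(small_catalog, small_config, dropout=0.2)
        assert len(one) < len(full)
        pd.testing.assert_frame_equal(one, two)


class TestAnnotations:
    def test_no_te_when_probability_zero(self):
        cfg = GeneratorConfig(n_genes=200, te_insertion_prob_a=0.0, seed=2)
        catalog = generate_truth(cfg)
        _, _, te = emit_annotations(catalog, cfg)
        a_ids = set(catalog.species_ids("A"))
        assert a_ids.isdisjoint(set(te["contig_id"]))

    def test_te_bias_detectable_by_chi_square(self):
        cfg = GeneratorConfig(
            n_genes=2000, te_insertion_prob_a=0.1, te_insertion_prob_b=0.3, seed=3
        )
        catalog = generate_truth(cfg)
        _, _, te = emit_annotations(catalog, cfg)
        te_ids = set(te["contig_id"])
        table = [
            [
                sum(c in te_ids for c in catalog.species_ids(sp)),
                sum(c not in te_ids for c in catalog.species_ids(sp)),
            ]
            for sp in ("A", "B")
        ]
        _, _, p = stats_report.chisq_2x2(table)
        assert p < 0.05


class TestCounts:
    def test_count_conservation(self, small_catalog, small_config):
        counts, totals = emit_counts(small_catalog, small_config)
        sums = counts.groupby("species")["count"].sum()
        assert totals == sums.to_dict()

    def test_zero_mean_gives_zero_count(self, small_config):
        cfg = GeneratorConfig(n_genes=50, nb_mean=0.0, seed=4)
        catalog = generate_truth(cfg)
        counts, _ = emit_counts(catalog, cfg)
        assert (counts["count"] == 0).all()

    def test_sample_mean_near_configured_mean(self):
        cfg = GeneratorConfig(n_genes=700, nb_mean=100.0, seed=6)
        catalog = generate_truth(cfg)
        counts, _ = emit_counts(catalog, cfg)
        assert len(counts) >= 1000
        assert counts["count"].mean() == pytest.approx(100.0, rel=0.10)

    def test_deterministic(self, small_catalog, small_config):
        one, _ = emit_counts(small_catalog, small_config)
        two, _ = emit_counts(small_catalog, small_config)
        pd.testing.assert_frame_equal(one, two)


class TestQPCR:
    def test_zero_noise_recovers_folds_exactly(self):
        cfg = GeneratorConfig(n_genes=0, qpcr_ct_sd=0.0, seed=8)
        plate = emit_qpcr(cfg)
        levels = qpcr.quantify(
            plate.measurements, plate.curves, plate.reference_genes
        )
        folds = qpcr.species_fold_changes(levels)
        recovered = dict(zip(folds["gene_id"], folds["fold"]))
        assert recovered == plate.fold_truths

    def test_noisy_recovery_within_15_percent(self):
        cfg = GeneratorConfig(n_genes=0, qpcr_ct_sd=0.1, seed=9)
        plate = emit_qpcr(cfg)
        levels = qpcr.quantify(
            plate.measurements, plate.curves, plate.reference_genes
        )
        folds = qpcr.species_fold_changes(levels)
        for row in folds.itertuples():
            assert row.fold == pytest.approx(
                plate.fold_truths[row.gene_id], rel=0.15
            )

    def test_requires_fold_truths(self):
        cfg = GeneratorConfig(n_genes=0, qpcr_fold_truths=())
        with pytest.raises(ValueError):
            emit_qpcr(cfg)
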