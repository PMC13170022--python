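"""The homology rule set: identity scoring, hit filtering, reciprocal
best hits, subject agreement, the four-way classification, unigene
clustering and allele counting."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salivome.homology import (
    HIT_COLUMNS,
    ClassifierThresholds,
    allele_count,
    best_hit,
    classify,
    cluster_unigenes,
    fast_identity,
    filter_hits,
    pairwise_identity,
    reciprocal_best_pairs,
    subject_agreement,
    venn_counts,
)
from salivome.synthetic_data import GeneratorConfig, emit_sequences, generate_truth

from alignment_oracle import brute_force_identity

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 100.0), ("ACGT", "AGGT", 75.0), ("AAAA", "AAAT", 75.0)],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    @given(a=DNA, b=DNA)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_agrees_with_alignment_enumeration(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(brute_force_identity(a, b))

    def test_generator_copies_at_construction_identity(self):
        """Aligned identity of an allele/paralogue copy against its gene
        primary reproduces the substitution-count truth within 0.05."""
        cfg = GeneratorConfig(
            n_genes=40, contig_len_range=(80, 140), allele_rate=0.8, seed=21
        )
        catalog = generate_truth(cfg)
        seqs = emit_sequences(catalog, cfg)
        seq_of = {r.id: str(r.seq) for sp in seqs.values() for r in sp}
        checked = 0
        for _, grp in catalog.contigs.groupby("gene_id"):
            primary = grp.loc[grp["n_subs"] == 0]
            copies = grp.loc[grp["n_subs"] > 0]
            if primary.empty or copies.empty:
                continue
            template = seq_of[primary["contig_id"].iloc[0]]
            for row in copies.head(2).itertuples():
                truth = 100.0 * (1 - row.n_subs / row.length)
                assert pairwise_identity(
                    seq_of[row.contig_id], template
                ) == pytest.approx(truth, abs=0.05)
                checked += 1
        assert checked >= 5

    @given(a=st.text(alphabet="ACGT", min_size=20, max_size=60), n=st.integers(0, 3))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_fast_identity_matches_scored_alignment_on_substitutions(self, a, n):
        # sparse substitutions at spaced positions: the high-identity
        # regime where the ungapped alignment is the scored optimum
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        b = list(a)
        for i in range(n):
            b[i * 7] = flip[b[i * 7]]
        b = "".join(b)
        assert fast_identity(a, b) == pytest.approx(pairwise_identity(a, b))


def _hit(q, s, pident=99.0, evalue=1e-50, bitscore=500.0, length=1000):
    return {
        "qseqid": q,
        "sseqid": s,
        "pident": pident,
        "length": length,
        "mismatch": round(length * (100 - pident) / 100),
        "gapopen": 0,
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": evalue,
        "bitscore": bitscore,
    }


def _hits(rows):
    return pd.DataFrame.from_records(rows, columns=HIT_COLUMNS)


class TestHitFilter:
    @pytest.mark.parametrize(
        "evalue,bitscore,kept",
        [(1e-6, 100.0, True), (1e-4, 100.0, False), (1e-6, 60.0, False)],
    )
    def test_strict_thresholds(self, thresholds, evalue, bitscore, kept):
        out = filter_hits(
            _hits([_hit("q", "s", evalue=evalue, bitscore=bitscore)]), thresholds
        )
        assert (len(out) == 1) is kept

    def test_negative_evalue_rejected(self, thresholds):
        with pytest.raises(ValueError):
            filter_hits(_hits([_hit("q", "s", evalue=-1.0)]), thresholds)


class TestBestHit:
    def test_highest_bitscore_wins(self):
        out = best_hit(
            _hits([_hit("q", "s1", bitscore=100), _hit("q", "s2", bitscore=200)])
        )
        assert list(out["sseqid"]) == ["s2"]

    def test_full_tie_breaks_lexicographically(self):
        out = best_hit(_hits([_hit("q", "B2"), _hit("q", "B10")]))
        assert list(out["sseqid"]) == ["B10"]  # "B10" < "B2" as strings

    def test_one_row_per_query(self):
        out = best_hit(
            _hits([_hit("q1", "s"), _hit("q1", "t"), _hit("q2", "s")])
        )
        assert sorted(out["qseqid"]) == ["q1", "q2"]


class TestReciprocalBest:
    def test_mutual_best_forms_pair(self):
        pairs = reciprocal_best_pairs(
            _hits([_hit("A1", "B1")]), _hits([_hit("B1", "A1")])
        )
        assert pairs == {("A1", "B1")}

    def test_non_mutual_is_excluded(self):
        pairs = reciprocal_best_pairs(
            _hits([_hit("A1", "B1")]), _hits([_hit("B1", "A2")])
        )
        assert pairs == set()

    def test_empty_inputs(self):
        assert reciprocal_best_pairs(_hits([]), _hits([])) == set()


class TestSubjectAgreement:
    def test_similar_identity_and_evalue(self, thresholds):
        a = next(_hits([_hit("a", "R", pident=90.0, evalue=1e-50)]).itertuples())
        b = next(_hits([_hit("b", "R", pident=90.5, evalue=1e-49)]).itertuples())
        assert subject_agreement(a, b, thresholds)

    def test_different_subjects_never_agree(self, thresholds):
        a = next(_hits([_hit("a", "R1")]).itertuples())
        b = next(_hits([_hit("b", "R2")]).itertuples())
        assert not subject_agreement(a, b, thresholds)

    def test_identity_gap_beyond_tolerance(self, thresholds):
        a = next(_hits([_hit("a", "R", pident=90.0)]).itertuples())
        b = next(_hits([_hit("b", "R", pident=99.0)]).itertuples())
        assert not subject_agreement(a, b, thresholds)

    def test_zero_evalue_floored(self, thresholds):
        a = next(_hits([_hit("a", "R", evalue=0.0)]).itertuples())
        b = next(_hits([_hit("b", "R", evalue=1e-200)]).itertuples())
        assert subject_agreement(a, b, thresholds)


class TestClassify:
    @pytest.fixture()
    def scenario(self, thresholds):
        """One gene (R1) with an RBH orthologue pair, an allele at 98.0,
        a paralogue at 97.9 and a different-region contig; plus two
        species-specific contigs on unique subjects."""
        contigs_a = ["A1", "A2", "A5", "A6", "A7"]
        contigs_b = ["B1", "B2"]
        cross = _hits(
            [
                _hit("A1", "B1", pident=100.0, bitscore=2000),
                _hit("B1", "A1", pident=100.0, bitscore=2000),
                _hit("A5", "B1", pident=98.0, bitscore=1960),
                _hit("A6", "B1", pident=97.9, bitscore=1958),
            ]
        )
        ref = _hits(
            [
                _hit("A1", "R1", pident=92.0),
                _hit("B1", "R1", pident=92.0),
                _hit("A5", "R1", pident=92.0),
                _hit("A6", "R1", pident=91.5),
                _hit("A7", "R1", pident=92.0),
                _hit("A2", "RX", pident=88.0),
                _hit("B2", "RY", pident=87.0),
            ]
        )
        rbh = reciprocal_best_pairs(
            best_hit(cross[cross.qseqid.str.startswith("A")]),
            best_hit(cross[cross.qseqid.str.startswith("B")]),
        )
        calls = classify(contigs_a, contigs_b, rbh, cross, ref, thresholds)
        return calls.set_index("contig_id")

    def test_rbh_with_agreement_is_orthologue(self, scenario):
        assert scenario.loc["A1", "category"] == "orthologue"
        assert scenario.loc["B1", "category"] == "orthologue"
        assert scenario.loc["A1", "partner_ids"] == "B1"

    def test_unique_subject_is_species_specific(self, scenario):
        assert scenario.loc["A2", "category"] == "species_specific"
        assert scenario.loc["B2", "category"] == "species_specific"
        assert scenario.loc["A2", "partner_ids"] == ""

    def test_allele_boundary_inclusive_at_98(self, scenario):
        assert scenario.loc["A5", "category"] == "allele"

    def test_paralogue_below_98(self, scenario):
        assert scenario.loc["A6", "category"] == "paralogue"

    def test_no_cross_hit_same_subject_is_different_region_orthologue(
        self, scenario
    ):
        assert scenario.loc["A7", "category"] == "orthologue"
        assert bool(scenario.loc["A7", "different_region"])

    def test_every_contig_called_once(self, scenario):
        assert sorted(scenario.index) == ["A1", "A2", "A5", "A6", "A7", "B1", "B2"]

    def test_unknown_contig_in_hits_rejected(self, thresholds):
        with pytest.raises(ValueError, match="absent"):
            classify(["A1"], ["B1"], set(), _hits([_hit("A9", "B1")]),
                     _hits([]), thresholds)


def _members(ids_lengths):
    return pd.DataFrame(
        [
            {"contig_id": c, "species": c[0], "length": l}
            for c, l in ids_lengths
        ]
    )


class TestClustering:
    def test_isolated_contig_is_singleton(self, thresholds):
        clusters = cluster_unigenes(_members([("A1", 100)]), [], thresholds)
        assert len(clusters) == 1 and clusters[0].members == {"A": ["A1"]}

    def test_single_linkage_chains(self, thresholds):
        clusters = cluster_unigenes(
            _members([("A1", 100), ("A2", 90), ("A3", 80)]),
            [("A1", "A2", 95.0), ("A2", "A3", 95.0), ("A1", "A3", 90.0)],
            thresholds,
        )
        assert len(clusters) == 1
        assert clusters[0].members["A"] == ["A1", "A2", "A3"]
        assert clusters[0].representative == "A1"  # longest member

    def test_94_boundary_is_strict(self, thresholds):
        clusters = cluster_unigenes(
            _members([("A1", 100), ("A2", 100)]), [("A1", "A2", 94.0)], thresholds
        )
        assert len(clusters) == 2

    def test_representative_tie_breaks_lexicographically(self, thresholds):
        clusters = cluster_unigenes(
            _members([("A2", 100), ("A1", 100)]), [("A1", "A2", 99.0)], thresholds
        )
        assert clusters[0].representative == "A1"


class TestAlleleCount:
    def test_singleton_counts_one(self):
        assert allele_count({"A": ["A1"]}, "A1", {}) == {"A": 1}

    def test_all_high_identity_members_count(self):
        idents = {
            frozenset(("A1", "A2")): 99.0,
            frozenset(("A1", "A3")): 99.5,
        }
        counts = allele_count({"A": ["A1", "A2", "A3"]}, "A1", idents)
        assert counts == {"A": 3}

    def test_low_identity_member_excluded(self):
        idents = {
            frozenset(("A1", "A2")): 99.0,
            frozenset(("A1", "A3")): 95.0,
        }
        counts = allele_count({"A": ["A1", "A2", "A3"]}, "A1", idents)
        assert counts == {"A": 2}

    def test_raising_threshold_never_increases_count(self):
        idents = {
            frozenset(("A1", "A2")): 98.5,
            frozenset(("A1", "A3")): 99.9,
        }
        members = {"A": ["A1", "A2", "A3"]}
        counts = [
            allele_count(members, "A1", idents, allele_min_identity=t)["A"]
            for t in (98.0, 98.6, 99.95, 100.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestVennCounts:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["contig_id", "species", "category", "gene_id"]
        )

    def test_all_orthologues_leaves_no_specific(self):
        calls = self._calls(
            [("A1", "A", "orthologue", "G1"), ("B1", "B", "orthologue", "G1")]
        )
        out = venn_counts(calls)
        assert out["contig_a_specific"] == 0 and out["contig_b_specific"] == 0
        assert out["gene_shared"] == 1

    def test_partition_identity(self, small_run):
        out = small_run.venn
        frame = small_run.calls
        assert (
            out["contig_shared_a"] + out["contig_a_specific"]
            == (frame.species == "A").sum()
        )
        total_genes = (
            out["gene_shared"] + out["gene_a_specific"] + out["gene_b_specific"]
        )
        tv = small_run.truth_venn
        assert total_genes == (
            tv["gene_shared"] + tv["gene_a_specific"] + tv["gene_b_specific"]
        )

    def test_species_swap_symmetry(self):
        calls = self._calls(
            [
                ("A1", "A", "orthologue", "G1"),
                ("B1", "B", "orthologue", "G1"),
                ("A2", "A", "species_specific", "G2"),
                ("A3", "A", "species_specific", "G3"),
                ("B2", "B", "species_specific", "G4"),
            ]
        )
        swapped = calls.copy()
        swapped["species"] = swapped["species"].map({"A": "B", "B": "A"})
        out, out_sw = venn_counts(calls), venn_counts(swapped)
        assert out["contig_a_specific"] == out_sw["contig_b_specific"]
        assert out["contig_b_specific"] == out_sw["contig_a_specific"]
        assert out["contig_shared_pairs"] == out_sw["contig_shared_pairs"]
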