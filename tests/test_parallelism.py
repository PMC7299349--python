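"""Qualifying-mutation filtering, Dice similarity, permutation and Fisher tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citniche.parallelism import (
    GeneHitMatrix,
    GeneLink,
    MutationRecord,
    dice,
    gene_treatment_fisher,
    hit_matrix,
    parallelism_report,
    permutation_test_sw_sb,
    qualifying_mutations,
    rank_genes,
    similarity_summary,
)
from citniche.simulate import gen_mutation_table


def matrix_from_sets(sets_by_clone, treatments):
    genes = sorted({g for s in sets_by_clone.values() for g in s})
    counts = pd.DataFrame(
        [[1 if g in sets_by_clone[c] else 0 for g in genes] for c in sets_by_clone],
        index=list(sets_by_clone),
        columns=genes,
    )
    return GeneHitMatrix(counts=counts, treatments=pd.Series(treatments))


class TestQualifyingFilter:
    def test_toy_table_keeps_exactly_five(self, toy_mutation_records):
        kept = qualifying_mutations(toy_mutation_records)
        assert len(kept) == 5
        assert all(isinstance(g, str) for _, g in kept)

    def test_synonymous_snp_excluded(self):
        rec = MutationRecord(
            "c", "DM0", 10, "snp_synonymous",
            genes_affected=(GeneLink("gltA", "coding"),),
        )
        assert qualifying_mutations([rec]) == []

    def test_promoter_insertion_within_window_qualifies(self):
        # An IS150 35 bp upstream of the yhiO start qualifies and is
        # assigned to yhiO.
        rec = MutationRecord(
            "c", "DM0", 10, "is_insertion", element="IS150",
            genes_affected=(GeneLink("yhiO", "promoter", distance_bp=35),),
        )
        assert qualifying_mutations([rec]) == [(rec, "yhiO")]

    def test_promoter_outside_window_excluded(self):
        rec = MutationRecord(
            "c", "DM0", 10, "is_insertion", element="IS150",
            genes_affected=(GeneLink("yhiO", "promoter", distance_bp=400),),
        )
        assert qualifying_mutations([rec], promoter_window_bp=150) == []

    def test_multi_gene_deletion_excluded(self):
        rec = MutationRecord(
            "c", "DM0", 10, "deletion",
            genes_affected=(GeneLink("a", "coding"), GeneLink("b", "coding")),
        )
        assert qualifying_mutations([rec]) == []


class TestDice:
    def test_identical_sets(self):
        assert dice({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert dice({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert dice({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(2 / 3)

    def test_both_empty_defined_as_zero(self):
        assert dice(set(), set()) == 0.0

    @given(
        x=st.sets(st.sampled_from("abcdefgh")),
        y=st.sets(st.sampled_from("abcdefgh")),
    )
    @settings(deadline=None)
    def test_symmetric(self, x, y):
        assert dice(x, y) == dice(y, x)


class TestSimilaritySummary:
    def test_identical_clones_give_all_ones(self):
        m = matrix_from_sets(
            {f"c{i}": {"a", "b"} for i in range(4)},
            {f"c{i}": ("DM0" if i < 2 else "DM25") for i in range(4)},
        )
        assert similarity_summary(m) == (1.0, 1.0, 1.0)

    def test_pair_count_identity(self):
        # S_m * N_pairs == S_w * N_within + S_b * N_between, exactly.
        recs, tm = gen_mutation_table(
            n_clones_per_treatment=6, background_rate=0.3,
            gene_universe_size=15, seed=2,
        )
        clones = [tuple(x.split(":")) for x in tm["clones"]]
        m = hit_matrix(qualifying_mutations(recs), clones=clones)
        s_m, s_w, s_b = similarity_summary(m)
        n = len(m.clones)
        labels = m.treatments.to_numpy()
        n_pairs = n * (n - 1) // 2
        n_within = sum(
            k * (k - 1) // 2 for k in pd.Series(labels).value_counts()
        )
        n_between = n_pairs - n_within
        assert s_m * n_pairs == pytest.approx(s_w * n_within + s_b * n_between)

    def test_exchangeable_generator_has_no_treatment_effect(self):
        # With identical hit probabilities in both treatments, the mean
        # within- and between-treatment similarities coincide on average.
        diffs = []
        for s in range(100):
            recs, tm = gen_mutation_table(background_rate=0.15,
                                          gene_universe_size=30, seed=s)
            clones = [tuple(x.split(":")) for x in tm["clones"]]
            m = hit_matrix(qualifying_mutations(recs), clones=clones)
            _, s_w, s_b = similarity_summary(m)
            diffs.append(s_w - s_b)
        mc_se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * mc_se + 1e-4


class TestPermutationTest:
    def test_identical_sets_give_p_one(self):
        m = matrix_from_sets(
            {f"c{i}": {"a"} for i in range(6)},
            {f"c{i}": ("DM0" if i < 3 else "DM25") for i in range(6)},
        )
        assert permutation_test_sw_sb(m, n_perm=200, seed=0) == 1.0

    def test_p_floor_is_one_over_nperm_plus_one(self):
        m = matrix_from_sets(
            {"a1": {"x"}, "a2": {"x"}, "b1": {"y"}, "b2": {"y"}},
            {"a1": "DM0", "a2": "DM0", "b1": "DM25", "b2": "DM25"},
        )
        p = permutation_test_sw_sb(m, n_perm=500, seed=3)
        assert p >= 1 / 501

    def test_strong_treatment_specific_targets_detected(self):
        targets_a = {f"gene{i + 1:04d}": 0.8 for i in range(5)}
        targets_b = {f"gene{i + 11:04d}": 0.8 for i in range(5)}
        recs, tm = gen_mutation_table(
            target_genes={"DM0": targets_a, "DM25": targets_b},
            background_rate=0.05, seed=7,
        )
        clones = [tuple(x.split(":")) for x in tm["clones"]]
        m = hit_matrix(qualifying_mutations(recs), clones=clones)
        assert permutation_test_sw_sb(m, n_perm=999, seed=7) < 0.01

    def test_single_treatment_rejected(self):
        m = matrix_from_sets(
            {"c1": {"a"}, "c2": {"b"}}, {"c1": "DM0", "c2": "DM0"}
        )
        with pytest.raises(ValueError):
            permutation_test_sw_sb(m, n_perm=10, seed=0)


class TestGeneFisher:
    def test_hit_counts_produce_published_scale_p(self):
        # 11/12 clones hit in one treatment vs 3/12 in the other.
        sets = {}
        treatments = {}
        for i in range(12):
            sets[f"a{i}"] = {"gltA"} if i < 11 else {"other"}
            treatments[f"a{i}"] = "DM0"
        for i in range(12):
            sets[f"b{i}"] = {"gltA"} if i < 3 else {"other"}
            treatments[f"b{i}"] = "DM25"
        m = matrix_from_sets(sets, treatments)
        assert round(gene_treatment_fisher(m, "gltA"), 4) == 0.0028

    def test_unhit_gene_gives_p_one(self):
        m = matrix_from_sets(
            {"c1": {"a"}, "c2": {"a"}, "c3": set(), "c4": set()},
            {"c1": "DM0", "c2": "DM0", "c3": "DM25", "c4": "DM25"},
        )
        assert gene_treatment_fisher(m, "nonexistent") == 1.0


class TestRankGenes:
    def test_single_gene_hit_twice(self):
        m = matrix_from_sets(
            {"c1": {"a"}, "c2": {"a"}, "c3": set(), "c4": set()},
            {"c1": "DM0", "c2": "DM0", "c3": "DM25", "c4": "DM25"},
        )
        ranking = rank_genes(m)
        assert list(ranking["gene"]) == ["a"]
        assert ranking["abs_difference"].iloc[0] == 2

    def test_ordering_and_min_genome_filter(self):
        counts = pd.DataFrame(
            {
                "g_big": [1, 1, 1, 1, 1, 0, 0, 0],
                "g_mid": [1, 1, 1, 0, 0, 0, 0, 0],
                "g_even": [1, 1, 0, 0, 1, 1, 0, 0],
                "g_single": [1, 0, 0, 0, 0, 0, 0, 0],
            },
            index=[f"c{i}" for i in range(8)],
        )
        treatments = pd.Series(
            {f"c{i}": ("DM0" if i < 4 else "DM25") for i in range(8)}
        )
        ranking = rank_genes(GeneHitMatrix(counts=counts, treatments=treatments))
        assert list(ranking["gene"])[0] == "g_big"  # |4-1| = 3 leads
        assert "g_single" not in set(ranking["gene"])  # < 2 genomes
        assert ranking.iloc[-1]["gene"] == "g_even"  # 0 difference last

    def test_empty_matrix(self):
        m = GeneHitMatrix(
            counts=pd.DataFrame(index=["c1", "c2"]),
            treatments=pd.Series({"c1": "DM0", "c2": "DM25"}),
        )
        assert rank_genes(m).empty


def test_full_report_wires_components_together():
    recs, tm = gen_mutation_table(
        target_genes={"DM0": {"gene0001": 0.9}, "DM25": {"gene0002": 0.9}},
        background_rate=0.05, seed=11,
    )
    clones = [tuple(x.split(":")) for x in tm["clones"]]
    m = hit_matrix(qualifying_mutations(recs), clones=clones)
    rep = parallelism_report(m, n_perm=499, seed=1)
    assert 0 <= rep.S_b <= rep.S_m <= rep.S_w <= 1
    assert rep.permutation_p < 0.05
    assert set(rep.gene_fisher_p) == set(rep.ranking["gene"])
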