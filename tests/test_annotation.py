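import numpy as np
import pandas as pd
import pytest

from comirnet import (
    AnnotationBundle,
    ConfigurationError,
    DataError,
    ExpressionMatrix,
    LookupFailure,
    affected_genes,
    characterize_pairs,
    distance_test,
    expression_related_genes,
    fdr_adjust,
    filter_targets,
    genomic_distance,
    overlap_test,
    pair_coherence,
    pair_flags,
    random_pair_null,
)

from oracles import bh_stepup, hypergeom_upper_tail_enumerated


class TestGenomicDistance:
    LOCS = {
        "a": ("chr1", 100, 200, "+"),
        "b": ("chr1", 150, 250, "-"),
        "c": ("chr1", 301, 400, "+"),
        "d": ("chr2", 100, 200, "+"),
    }

    def test_overlapping_intervals_have_distance_zero(self):
        assert genomic_distance("a", "b", self.LOCS) == 0

    def test_gap_under_one_based_inclusive_convention(self):
        assert genomic_distance("a", "c", self.LOCS) == 100  # 301 - 200 - 1

    def test_different_chromosomes_give_none(self):
        assert genomic_distance("a", "d", self.LOCS) is None

    def test_order_of_arguments_is_irrelevant(self):
        assert genomic_distance("c", "a", self.LOCS) == genomic_distance("a", "c", self.LOCS)

    def test_unknown_mirna_raises(self):
        with pytest.raises(LookupFailure, match="zz"):
            genomic_distance("a", "zz", self.LOCS)


class TestDistanceTest:
    def test_total_separation_five_vs_five_is_one_over_252(self):
        close = [1, 2, 3, 4, 5]
        far = [10, 11, 12, 13, 14]
        assert distance_test(close, far) == pytest.approx(1 / 252)

    def test_identical_samples_near_half(self):
        x = list(range(20))
        assert 0.4 < distance_test(x, x) < 0.6

    def test_empty_side_rejected(self):
        with pytest.raises(DataError):
            distance_test([], [1.0])


class TestPairFlags:
    def _bundle(self):
        return AnnotationBundle(
            clusters={"a": "c1", "b": "c1", "c": "c2"},
            families={"a": "ACGUAC", "b": "GGGUAC"},
            tf_edges={("E2F1", "a"), ("E2F1", "b"), ("MYC", "b")},
        )

    def test_shared_cluster_family_tf(self):
        b = self._bundle()
        assert pair_flags(("a", "b"), b) == (True, False, True)
        assert pair_flags(("a", "c"), b) == (False, False, False)

    def test_missing_annotation_counts_as_no(self):
        assert pair_flags(("x", "y"), self._bundle()) == (False, False, False)


class TestRandomPairNull:
    UNIVERSE = [f"m{i}" for i in range(10)]

    def test_always_true_predicate_saturates(self):
        null = random_pair_null(self.UNIVERSE, 4, 20, lambda p: True, seed=0)
        assert np.all(null.samples == 4)

    def test_always_false_predicate_is_zero(self):
        null = random_pair_null(self.UNIVERSE, 4, 20, lambda p: False, seed=0)
        assert np.all(null.samples == 0)

    def test_same_family_expectation_on_four_mirnas(self):
        # universe of 4 with one same-family pair: 1 favorable of C(4,2)=6
        fam = {"a": "f1", "b": "f1", "c": "f2", "d": "f3"}
        null = random_pair_null(
            ["a", "b", "c", "d"], 1, 10_000,
            lambda p: fam[p[0]] == fam[p[1]], seed=1,
        )
        assert abs(null.samples.mean() - 1 / 6) < 4 * np.sqrt((1 / 6) * (5 / 6) / 10_000)

    def test_pairs_are_distinct_and_never_self(self):
        from comirnet.annotation import sample_pairs

        rng = np.random.default_rng(0)
        pairs = sample_pairs(self.UNIVERSE, 45, rng)  # all C(10,2) pairs
        assert len(set(map(tuple, map(sorted, pairs)))) == 45
        assert all(a != b for a, b in pairs)

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ConfigurationError):
            random_pair_null(["a", "b"], 2, 5, lambda p: True, seed=0)

    def test_observed_pairs_give_observed_statistic(self):
        null = random_pair_null(
            self.UNIVERSE, 2, 10, lambda p: "m0" in p, seed=0,
            observed_pairs=[("m0", "m1"), ("m2", "m3")],
        )
        assert null.observed == 1.0


class TestFilterTargets:
    def test_cutoff_keeps_strong_context_scores(self):
        out = filter_targets(
            {"m": {"g1", "g2"}}, {"m": {"g1": -0.5, "g2": -0.1}}, context_cutoff=-0.3
        )
        assert out["m"] == {"g1"}

    def test_none_cutoff_is_identity(self):
        sets = {"m": {"g1", "g2"}}
        assert filter_targets(sets, None, context_cutoff=None) == sets

    def test_all_filtered_kept_as_empty_set(self):
        out = filter_targets({"m": {"g1"}}, {"m": {"g1": -0.1}}, context_cutoff=-0.3)
        assert out["m"] == set()

    def test_cutoff_without_scores_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_targets({"m": {"g1"}}, None, context_cutoff=-0.3)


class TestOverlapTest:
    def test_complete_overlap_of_five_in_ten(self):
        genes = {f"g{i}" for i in range(5)}
        res = overlap_test(genes, genes, 10)
        assert res.p == pytest.approx(1 / 252)
        assert (res.k, res.K, res.n, res.N) == (5, 5, 5, 10)

    def test_zero_overlap_has_p_one(self):
        assert overlap_test({"g1"}, {"g2"}, 10).p == 1.0

    def test_hand_enumerated_two_in_four(self):
        res = overlap_test({"g1", "g2"}, {"g1", "g3"}, 4)
        assert res.p == pytest.approx(5 / 6)

    def test_matches_exhaustive_enumeration_for_small_universes(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            a = set(universe[:K])
            b = set(rng.choice(universe, size=n, replace=False))
            res = overlap_test(a, b, N)
            assert res.p == pytest.approx(
                hypergeom_upper_tail_enumerated(N, K, n, res.k), abs=1e-12
            )

    def test_sets_exceeding_universe_rejected(self):
        with pytest.raises(DataError):
            overlap_test({f"g{i}" for i in range(5)}, {"g0"}, 3)


class TestFdrAdjust:
    def test_hand_computed_three_pvalues(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        assert np.allclose(fdr_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_matches_brute_force_stepup_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(fdr_adjust(p), bh_stepup(p), atol=1e-12)

    def test_monotone_in_sorted_order_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q <= 1.0)


class TestExpressionRelatedGenes:
    def _mrna(self, rows, genes, samples):
        return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples))

    def test_identical_negated_and_orthogonal_profiles(self):
        samples = ["s1", "s2", "s3", "s4"]
        mir = pd.Series([1.0, 2.0, 3.0, 4.0], index=samples)
        rows = [
            [1.0, 2.0, 3.0, 4.0],    # identical -> PCC 1
            [-1.0, -2.0, -3.0, -4.0],  # negation -> PCC -1
            [1.0, -1.0, -1.0, 1.0],  # orthogonal to the linear trend -> PCC 0
        ]
        out = expression_related_genes(mir, self._mrna(rows, ["gi", "gn", "go"], samples))
        assert out == {"gi", "gn"}

    def test_sample_mismatch_rejected(self):
        mir = pd.Series([1.0, 2.0], index=["s1", "s2"])
        with pytest.raises(DataError):
            expression_related_genes(mir, self._mrna([[1.0, 2.0]], ["g"], ["s1", "sX"]))


class TestAffectedGenes:
    def test_upregulated_beyond_cutoff_included(self):
        assert affected_genes({"line1": {"g1": 1.5}}) == {"g1"}

    def test_downregulation_included_under_direction_agnostic_rule(self):
        assert affected_genes({"line1": {"g1": 0.8}}) == {"g1"}  # 1/0.8 = 1.25
        assert affected_genes({"line1": {"g1": 0.8}}, direction_agnostic=False) == set()

    def test_small_changes_excluded_and_union_across_lines(self):
        table = {"l1": {"g1": 1.1, "g2": 1.5}, "l2": {"g3": 2.0}}
        assert affected_genes(table) == {"g2", "g3"}

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(DataError):
            affected_genes({"l1": {"g1": 0.0}})


class TestPairCoherence:
    GO = {"term_rare": {"g1", "g2", "g3"}, "term_all": {f"g{i}" for i in range(100)}}

    def test_rare_term_fully_covered_is_enriched(self):
        hits = pair_coherence({"g1", "g2", "g3"}, self.GO, 100, p_cutoff=0.001)
        assert [t for t, _ in hits] == ["term_rare"]

    def test_empty_common_genes_give_no_terms(self):
        assert pair_coherence(set(), self.GO, 100) == []

    def test_term_covering_whole_universe_never_enriched(self):
        hits = pair_coherence({"g5", "g6"}, {"term_all": self.GO["term_all"]}, 100, 0.999)
        assert hits == []


class TestCharacterizePairs:
    def test_planted_pairs_share_annotation_and_targets(self, small_data, small_bundle):
        h, _, _, truth = small_data
        pairs = sorted(truth.conserved_pairs)
        table = characterize_pairs(pairs, small_bundle, mirna_expr=h)
        assert len(table) == len(pairs)
        # every planted pair was built with elevated target overlap
        assert (table["target_overlap_q"] < 0.05).all()
        assert table["same_family"].sum() >= 1
        assert table["shared_tf"].sum() >= 1
        assert table["same_cluster"].sum() >= 1
        # affected-gene overlaps computed where knockout tables exist
        assert table["affected_overlap_p"].notna().all()
        assert (table["affected_overlap_p"] < 0.05).all()

    def test_family_restricted_rerun_path(self, small_data, small_bundle):
        # excluding same-family pairs and re-running the panel needs no new
        # code: it is a plain filter on the characterization table
        h, _, _, truth = small_data
        pairs = sorted(truth.conserved_pairs)
        table = characterize_pairs(pairs, small_bundle, mirna_expr=h)
        non_family = table[~table["same_family"]]
        assert len(non_family) < len(table)
        assert (non_family["target_overlap_q"] < 0.05).all()
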