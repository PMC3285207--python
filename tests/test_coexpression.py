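import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comirnet import (
    ConfigurationError,
    DataError,
    ExpressionMatrix,
    LookupFailure,
    OrthologyMap,
    SyntheticConfig,
    build_network,
    generate_expression_pair,
    order_statistic_pvalue,
    pair_rank_ratio,
    pearson_matrix,
    project_to_species,
    rank_ratios,
    score_all_pairs,
)

from oracles import null_law_of_pair_pvalue, order_statistic_cdf_monte_carlo


def _em(rows, index):
    return ExpressionMatrix(pd.DataFrame(rows, index=index))


class TestPearsonMatrix:
    def test_duplicate_row_has_correlation_one(self):
        m = _em([[1.0, 2.0, 5.0], [1.0, 2.0, 5.0]], ["a", "b"])
        assert pearson_matrix(m).at["a", "b"] == pytest.approx(1.0)

    def test_negated_row_has_correlation_minus_one(self):
        m = _em([[1.0, 2.0, 5.0], [-1.0, -2.0, -5.0]], ["a", "b"])
        assert pearson_matrix(m).at["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        m = _em([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]], ["a", "b"])
        assert pearson_matrix(m).at["a", "b"] == pytest.approx(0.5)

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(DataError, match="3 samples"):
            pearson_matrix(_em([[1.0, 2.0]], ["a"]))

    def test_zero_variance_row_propagates_missing(self):
        m = _em([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], ["flat", "b"])
        corr = pearson_matrix(m)
        assert np.isnan(corr.at["flat", "b"])
        assert corr.at["b", "b"] == 1.0


class TestRankRatios:
    def test_definition_on_three_features(self):
        corr = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.4], [0.1, 0.4, 1.0]],
            index=list("BAC"), columns=list("BAC"),
        )
        # anchor B: A has corr 0.9 (rank 1), C has 0.1 (rank 2); N = 3
        t = rank_ratios(corr)
        assert pair_ratio(t, "A", "B") == pytest.approx(1 / 3)
        assert pair_ratio(t, "C", "B") == pytest.approx(2 / 3)

    def test_ties_get_average_rank(self):
        corr = pd.DataFrame(np.eye(4), index=list("ABCD"), columns=list("ABCD"))
        corr.loc["B", "A"] = corr.loc["A", "B"] = 0.8
        corr.loc["C", "A"] = corr.loc["A", "C"] = 0.8
        corr.loc["D", "A"] = corr.loc["A", "D"] = 0.1
        t = rank_ratios(corr)
        # B and C tie at the top of A's list: average rank 1.5, N = 4
        assert pair_ratio(t, "B", "A") == pytest.approx(1.5 / 4)
        assert pair_ratio(t, "C", "A") == pytest.approx(0.375)

    def test_best_untied_partner_has_ratio_one_over_n(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((8, 30))
        corr = pd.DataFrame(np.corrcoef(x), index=list("ABCDEFGH"), columns=list("ABCDEFGH"))
        t = rank_ratios(corr)
        col = corr["A"].drop("A")
        best = col.idxmax()
        assert pair_ratio(t, best, "A") == pytest.approx(1 / 8)

    def test_each_anchor_column_is_a_permutation_of_the_grid(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((10, 20))
        ids = [f"f{i}" for i in range(10)]
        corr = pd.DataFrame(np.corrcoef(x), index=ids, columns=ids)
        t = rank_ratios(corr)
        for j in range(10):
            col = np.delete(t.ratios[:, j], j)
            assert np.allclose(np.sort(col), np.arange(1, 10) / 10)

    def test_missing_correlations_rank_last(self):
        corr = pd.DataFrame(
            [[1.0, 0.5, np.nan], [0.5, 1.0, 0.2], [np.nan, 0.2, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        t = rank_ratios(corr)
        i, j = t.index_of("C"), t.index_of("A")
        assert t.ratios[i, j] == pytest.approx(2 / 3)  # NaN ranks after 0.5


def pair_ratio(t, a, b):
    return t.ratios[t.index_of(a), t.index_of(b)]


class TestPairRankRatio:
    def _table(self):
        corr = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.8], [0.1, 0.8, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        return rank_ratios(corr)

    def test_minimum_of_both_directions(self):
        t = self._table()
        expected = min(pair_ratio(t, "A", "C"), pair_ratio(t, "C", "A"))
        assert pair_rank_ratio(t, "A", "C") == pytest.approx(expected)
        assert pair_rank_ratio(t, "A", "C") <= pair_ratio(t, "A", "C")
        assert pair_rank_ratio(t, "A", "C") <= pair_ratio(t, "C", "A")

    def test_unknown_id_raises(self):
        with pytest.raises(LookupFailure):
            pair_rank_ratio(self._table(), "A", "Z")


class TestOrderStatisticPvalue:
    def test_certain_event(self):
        assert order_statistic_pvalue([1.0, 1.0]) == 1.0

    def test_measure_zero_constraint(self):
        for x in (0.0, 0.3, 1.0):
            assert order_statistic_pvalue([0.0, x]) == 0.0

    def test_hand_computed_example(self):
        assert order_statistic_pvalue([0.1, 0.5]) == pytest.approx(0.09, abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            order_statistic_pvalue([0.5, 1.2])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=5),
        st.randoms(use_true_random=False),
    )
    def test_symmetric_and_monotone(self, r, pyrandom):
        p = order_statistic_pvalue(r)
        shuffled = list(r)
        pyrandom.shuffle(shuffled)
        assert order_statistic_pvalue(shuffled) == pytest.approx(p, abs=1e-12)
        bumped = list(r)
        i = pyrandom.randrange(len(r))
        bumped[i] = min(1.0, bumped[i] + 0.1)
        assert order_statistic_pvalue(bumped) >= p - 1e-12

    def test_closed_form_agreement_for_two_species(self):
        rng = np.random.default_rng(0)
        for r1, r2 in rng.uniform(size=(200, 2)):
            a, b = min(r1, r2), max(r1, r2)
            assert order_statistic_pvalue([r1, r2]) == pytest.approx(
                2 * a * b - a * a, abs=1e-12
            )

    def test_three_species_matches_monte_carlo(self):
        rng = np.random.default_rng(1)
        for r in rng.uniform(0.1, 0.9, size=(5, 3)):
            p = order_statistic_pvalue(r)
            est, se = order_statistic_cdf_monte_carlo(r, 200_000, rng)
            assert abs(p - est) < 3 * se


class TestScoreAllPairs:
    def _tables(self, n_features=10, n_orth=5, seed=0):
        cfg = SyntheticConfig(
            n_mirnas_per_species=n_features, n_orthologs=n_orth,
            n_samples_human=20, n_samples_mouse=20,
            n_planted_conserved=0, n_planted_single_species=0, n_genes=50, seed=seed,
        )
        h, m, o, _ = generate_expression_pair(cfg)
        t1 = rank_ratios(pearson_matrix(h), "human")
        t2 = rank_ratios(pearson_matrix(m), "mouse")
        return t1, t2, o

    def test_pair_count_is_k_choose_2(self):
        t1, t2, o = self._tables()
        scores = score_all_pairs(t1, t2, o)
        assert len(scores) == math.comb(len(o), 2)

    def test_bonferroni_uses_scored_pair_count_and_caps_at_one(self):
        t1, t2, o = self._tables()
        scores = score_all_pairs(t1, t2, o)
        m = len(scores)
        expected = np.minimum(1.0, scores["p_raw"] * m)
        assert np.allclose(scores["p_corrected"], expected)
        assert (scores["p_corrected"] <= 1.0).all()

    def test_missing_member_raises(self):
        t1, t2, _ = self._tables()
        bad = OrthologyMap(pairs=[("nope", "mmu-miR-0000")])
        with pytest.raises(LookupFailure, match="nope"):
            score_all_pairs(t1, t2, bad)


class TestBuildNetwork:
    def _scores(self, p_raw):
        n = len(p_raw)
        return pd.DataFrame(
            {
                "node_a": [f"a{i}" for i in range(n)],
                "node_b": [f"b{i}" for i in range(n)],
                "member1_a": [f"a{i}" for i in range(n)],
                "member1_b": [f"b{i}" for i in range(n)],
                "member2_a": [f"ma{i}" for i in range(n)],
                "member2_b": [f"mb{i}" for i in range(n)],
                "r_human": [0.1] * n,
                "r_mouse": [0.1] * n,
                "p_raw": p_raw,
                "p_corrected": np.minimum(1.0, np.asarray(p_raw) * n),
            }
        )

    def test_no_significant_score_gives_empty_network(self):
        net = build_network(self._scores([0.5, 0.9]), alpha=0.05)
        assert net.number_of_nodes() == 0 and net.number_of_edges() == 0

    def test_single_significant_pair(self):
        net = build_network(self._scores([1e-6, 0.9]), alpha=0.05)
        assert net.number_of_nodes() == 2 and net.number_of_edges() == 1

    def test_alpha_domain(self):
        with pytest.raises(ConfigurationError):
            build_network(self._scores([0.5]), alpha=1.5)
        assert build_network(self._scores([0.0]), alpha=0.0).number_of_edges() == 0

    def test_projection_preserves_edges_and_round_trips(self):
        net = build_network(self._scores([1e-6, 1e-7]), alpha=0.05)
        proj = project_to_species(net, "species2")
        assert proj.number_of_edges() == net.number_of_edges()
        for node in proj.nodes:
            assert proj.nodes[node]["ortholog_node"] in net.nodes
        empty = build_network(self._scores([0.9]), alpha=0.05)
        assert project_to_species(empty, "species1").number_of_nodes() == 0


class TestNullDistributionOfPairPvalue:
    def test_raw_pvalues_follow_the_joint_cdf_null_law(self):
        # the order-statistic p is a joint-CDF transform, not a probability
        # integral transform: under the global null it follows the law of
        # W = 2UV - min(U,V)^2, which is markedly non-uniform mid-range
        cfg = SyntheticConfig(
            n_mirnas_per_species=100, n_orthologs=60, n_samples_human=100,
            n_samples_mouse=100, n_planted_conserved=0, n_planted_single_species=0,
            n_genes=100, seed=17,
        )
        h, m, o, _ = generate_expression_pair(cfg)
        t1 = rank_ratios(pearson_matrix(h), "human")
        t2 = rank_ratios(pearson_matrix(m), "mouse")
        p = np.sort(score_all_pairs(t1, t2, o)["p_raw"].to_numpy())
        ecdf = np.arange(1, len(p) + 1) / len(p)
        assert np.abs(ecdf - null_law_of_pair_pvalue(p)).max() < 0.1
        assert np.abs(ecdf - p).max() > 0.15  # far from uniform
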