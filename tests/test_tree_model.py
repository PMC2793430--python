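import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coevotree.msa_io import Alignment, encode_rows
from coevotree.pair_stats import DirichletParams, ScoreMatrix, log_R, log_marginal_prob
from coevotree.msa_io import column_counts
from coevotree.tree_model import (
    BetaMatrix, build_beta, edge_posteriors, log_evidence, max_spanning_tree,
    rescale_beta, spanning_tree_sum,
)

from _oracles import brute_edge_posteriors, brute_tree_sum


def random_beta(L, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    lb = scale * rng.normal(size=(L, L))
    lb = (lb + lb.T) / 2
    np.fill_diagonal(lb, -np.inf)
    return BetaMatrix(lb)


class TestBuildBeta:
    def test_alpha_one_uniform_prior_reduces_to_scores(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(4, 4))
        v = (v + v.T) / 2
        b = build_beta(ScoreMatrix(v, "logR"), alpha=1.0)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(b.log_beta[off], v[off])

    def test_alpha_zero_prior_only(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(4, 4))
        v = (v + v.T) / 2
        w = np.exp(rng.normal(size=(4, 4)))
        w = (w + w.T) / 2
        b = build_beta(ScoreMatrix(v, "logR"), prior_weights=w, alpha=0.0)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(b.log_beta[off], np.log(w)[off], atol=1e-12)

    def test_affine_combination_and_range_check(self):
        v = np.array([[np.nan, 2.0], [2.0, np.nan]])
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        b = build_beta(ScoreMatrix(v, "logR"), prior_weights=w, alpha=0.5)
        assert b.log_beta[0, 1] == pytest.approx(1.0 + np.log(0.5))
        with pytest.raises(ValueError):
            build_beta(ScoreMatrix(v, "logR"), alpha=1.5)


class TestRescale:
    def test_endpoints_and_monotonicity(self):
        b = random_beta(8, 2, scale=40.0)
        r = rescale_beta(b, lambda_min=1e-12)
        off = ~np.eye(8, dtype=bool)
        vals = np.exp(r.log_beta[off])
        assert vals.max() == pytest.approx(1.0)
        assert vals.min() == pytest.approx(1e-12, rel=1e-6)
        order_in = np.argsort(b.log_beta[off])
        order_out = np.argsort(r.log_beta[off])
        np.testing.assert_array_equal(order_in, order_out)

    def test_degenerate_all_equal_gives_ones(self):
        lb = np.zeros((4, 4)) + 3.0
        np.fill_diagonal(lb, -np.inf)
        r = rescale_beta(BetaMatrix(lb))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(np.exp(r.log_beta[off]), 1.0)

    def test_invalid_lambda_min(self):
        with pytest.raises(ValueError):
            rescale_beta(random_beta(3, 0), lambda_min=1.5)


class TestSpanningTreeSum:
    @pytest.mark.parametrize("L,expect", [(3, 3.0), (4, 16.0)])
    def test_cayley_unit_weights(self, L, expect):
        lb = np.zeros((L, L))
        np.fill_diagonal(lb, -np.inf)
        assert np.exp(spanning_tree_sum(BetaMatrix(lb))) == pytest.approx(expect)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_prufer_enumeration_l5(self, seed):
        b = random_beta(5, seed)
        w = b.beta
        assert spanning_tree_sum(b) == pytest.approx(
            np.log(brute_tree_sum(w)), rel=1e-12)

    def test_independent_of_dropped_index(self):
        b = random_beta(6, 42)
        ref = spanning_tree_sum(b, drop=0)
        for k in range(1, 6):
            assert spanning_tree_sum(b, drop=k) == pytest.approx(ref, rel=1e-10)

    def test_disconnected_graph_minus_inf(self):
        lb = np.full((4, 4), -np.inf)
        lb[0, 1] = lb[1, 0] = 0.0
        lb[2, 3] = lb[3, 2] = 0.0
        with pytest.warns(UserWarning):
            assert spanning_tree_sum(BetaMatrix(lb)) == -np.inf


class TestLogEvidence:
    def aln(self, rows):
        return Alignment([f"s{i}" for i in range(len(rows))], encode_rows(rows))

    def test_l1_is_column_marginal(self):
        a = self.aln(["A", "C", "A"])
        b = BetaMatrix(np.array([[-np.inf]]))
        params = DirichletParams()
        # no edges: evidence is the single column's marginal
        assert log_evidence(a, b, params) == pytest.approx(
            log_marginal_prob(column_counts(a, 0), params))

    def test_l2_single_tree(self):
        a = self.aln(["AC", "CA", "AA"])
        params = DirichletParams()
        lr = log_R(a, 0, 1, params)
        lb = np.full((2, 2), -np.inf)
        lb[0, 1] = lb[1, 0] = lr
        expect = (log_marginal_prob(column_counts(a, 0), params)
                  + log_marginal_prob(column_counts(a, 1), params) + lr)
        assert log_evidence(a, BetaMatrix(lb), params) == pytest.approx(expect)

    def test_unit_r_cancels_normalisation(self):
        a = self.aln(["ACD", "CAD", "AAC"])
        params = DirichletParams()
        lb = np.zeros((3, 3))
        np.fill_diagonal(lb, -np.inf)
        cols = sum(log_marginal_prob(column_counts(a, i), params) for i in range(3))
        # tree sum = L^(L-2) exactly cancels the uniform prior normalisation
        assert log_evidence(a, BetaMatrix(lb), params) == pytest.approx(cols)


class TestEdgePosteriors:
    def test_equal_weights_symmetric_two_over_l(self):
        for L in (3, 5, 12):
            lb = np.zeros((L, L))
            np.fill_diagonal(lb, -np.inf)
            pm = edge_posteriors(BetaMatrix(lb))
            off = ~np.eye(L, dtype=bool)
            np.testing.assert_allclose(pm.post[off], 2.0 / L, atol=1e-12)
            assert pm.total() == pytest.approx(L - 1, abs=1e-9)

    @pytest.mark.parametrize("method", ["resistance", "contraction"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_l5(self, method, seed):
        b = random_beta(5, 100 + seed)
        pm = edge_posteriors(b, method=method)
        want = brute_edge_posteriors(b.beta)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(pm.post[off], want[off], atol=1e-10)

    def test_methods_agree(self):
        b = random_beta(12, 7, scale=3.0)
        p1 = edge_posteriors(b, method="resistance").post
        p2 = edge_posteriors(b, method="contraction").post
        off = ~np.eye(12, dtype=bool)
        np.testing.assert_allclose(p1[off], p2[off], atol=1e-9)

    def test_scale_invariance(self):
        b = random_beta(10, 3)
        base = edge_posteriors(b).post
        for c in (1e-6, 1e6):
            scaled = BetaMatrix(b.log_beta + np.log(c))
            np.testing.assert_allclose(
                edge_posteriors(scaled).post, base, atol=1e-9, equal_nan=True)


@settings(deadline=None, max_examples=28, derandomize=True)
@given(st.integers(3, 30), st.integers(0, 2**31 - 1))
def test_posterior_normalisation_property(L, seed):
    """Sum of edge posteriors over i<j equals L-1: trees have L-1 edges."""
    pm = edge_posteriors(random_beta(L, seed, scale=2.0))
    assert pm.total() == pytest.approx(L - 1, abs=1e-9)


class TestMaxSpanningTree:
    def test_picks_two_heaviest_of_three(self):
        lb = np.full((3, 3), -np.inf)
        lb[0, 1] = lb[1, 0] = np.log(3)
        lb[1, 2] = lb[2, 1] = np.log(2)
        lb[0, 2] = lb[2, 0] = np.log(1)
        assert max_spanning_tree(BetaMatrix(lb)) == [(0, 1), (1, 2)]

    def test_chain_dominant_weights_recover_chain(self):
        L = 6
        rng = np.random.default_rng(5)
        lb = rng.normal(-5, 0.1, size=(L, L))
        lb = (lb + lb.T) / 2
        for i in range(L - 1):
            lb[i, i + 1] = lb[i + 1, i] = 10.0
        np.fill_diagonal(lb, -np.inf)
        tree = max_spanning_tree(BetaMatrix(lb))
        assert sorted(tree) == [(i, i + 1) for i in range(L - 1)]

    def test_all_equal_weights_lexicographic_tiebreak(self):
        lb = np.zeros((4, 4))
        np.fill_diagonal(lb, -np.inf)
        assert max_spanning_tree(BetaMatrix(lb)) == [(0, 1), (0, 2), (0, 3)]

    def test_matches_exhaustive_small(self):
        from _oracles import all_labeled_trees
        b = random_beta(5, 77)
        best = max(all_labeled_trees(5),
                   key=lambda t: sum(b.log_beta[i, j] for i, j in t))
        got = max_spanning_tree(b)
        assert sum(b.log_beta[i, j] for i, j in got) == pytest.approx(
            sum(b.log_beta[i, j] for i, j in best))
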