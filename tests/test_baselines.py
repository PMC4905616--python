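"""Hotelling T^2 and the MST-based runs / Kolmogorov-Smirnov tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mmdpath.baselines import (
    MSTree, NotApplicableError,
    build_mst, expected_runs, hdp_ranks, hotelling_t2, ks_test,
    runs_count, runs_variance, ww_test,
)


def prufer_trees(n):
    """Every labeled tree on n nodes, decoded from its Pruefer sequence."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        edges = []
        for v in seq:
            leaf = min(u for u in range(n) if degree[u] == 1)
            edges.append((min(leaf, v), max(leaf, v)))
            degree[leaf] -= 1
            degree[v] -= 1
        u, w = [v for v in range(n) if degree[v] == 1]
        edges.append((u, w))
        yield edges


class TestHotelling:
    def test_one_dim_worked_example(self):
        # X = {1,2,3}, Y = {4,5,6}: pooled variance 1, T^2 = (9/6)*9 = 13.5
        res = hotelling_t2(np.array([[1.0], [2.0], [3.0]]),
                           np.array([[4.0], [5.0], [6.0]]))
        assert res.statistic == pytest.approx(13.5)
        assert res.method == "hotelling"

    def test_identical_groups_zero_statistic(self, rng):
        X = rng.standard_normal((5, 2))
        res = hotelling_t2(X, X.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_one_dim_equals_squared_t_statistic(self, rng):
        for _ in range(5):
            x = rng.standard_normal(6)
            y = rng.standard_normal(9) + 0.5
            res = hotelling_t2(x[:, None], y[:, None])
            t_stat, t_p = stats.ttest_ind(x, y, equal_var=True)
            assert res.statistic == pytest.approx(t_stat**2, rel=1e-10)
            assert res.p_value == pytest.approx(t_p, rel=1e-10)

    def test_not_applicable_when_features_exceed_df(self, rng):
        # p = 16 features with 4 + 4 samples: pooled covariance is singular
        X = rng.standard_normal((4, 16))
        Y = rng.standard_normal((4, 16))
        with pytest.raises(NotApplicableError, match="not applicable"):
            hotelling_t2(X, Y)

    def test_singular_covariance_not_applicable(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # rank-1 features
        Y = np.array([[1.0, 2.0], [2.0, 4.0], [4.0, 8.0]])
        with pytest.raises(NotApplicableError):
            hotelling_t2(X, Y)


class TestBuildMST:
    def test_one_dim_path(self):
        tree = build_mst(np.array([[0.0], [1.0], [5.0]]))
        assert sorted((i, j) for i, j, _ in tree.edges) == [(0, 1), (1, 2)]
        assert tree.total_weight == pytest.approx(5.0)

    def test_tree_shape_invariants(self, rng):
        X = rng.standard_normal((9, 2))
        tree = build_mst(X)
        assert len(tree.edges) == 8
        assert sorted(tree.degrees.tolist()) == sorted(
            d for _, d in tree.graph().degree())

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_weight_matches_exhaustive_minimum(self, rng, n):
        X = rng.standard_normal((n, 2))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        best = min(sum(D[i, j] for i, j in edges) for edges in prufer_trees(n))
        assert build_mst(X).total_weight == pytest.approx(best, rel=1e-12)

    def test_duplicate_points_allowed(self):
        tree = build_mst(np.array([[0.0], [0.0], [1.0]]))
        assert min(w for _, _, w in tree.edges) == 0.0

    def test_deterministic_under_ties(self):
        # four corners of a square: many equal-weight MSTs; ties resolve
        # lexicographically so repeated builds agree exactly
        X = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        e1 = build_mst(X).edges
        e2 = build_mst(X).edges
        assert e1 == e2


class TestRunsCount:
    def test_one_between_edge_gives_two_subtrees(self):
        tree = build_mst(np.array([[0.0], [1.0], [10.0], [11.0]]))
        assert runs_count(tree, [True, True, False, False]) == 2

    def test_alternating_path_labels(self):
        tree = build_mst(np.arange(6, dtype=float)[:, None])
        labels = np.array([True, False] * 3)
        assert runs_count(tree, labels) == 6

    def test_single_label_gives_one(self):
        # no between-group edge is deleted, so the tree stays in one piece
        tree = build_mst(np.arange(4, dtype=float)[:, None])
        assert runs_count(tree, np.ones(4, dtype=bool)) == 1


class TestRunsMoments:
    def test_path_of_four_mean_is_three(self):
        # all 6 balanced labelings of a path a-b-c-d: mean R = 3 = 2mn/N + 1
        tree = MSTree(list("abcd"), [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        rs = []
        for idx in itertools.combinations(range(4), 2):
            mask = np.zeros(4, bool)
            mask[list(idx)] = True
            rs.append(runs_count(tree, mask))
        assert np.mean(rs) == pytest.approx(expected_runs(2, 2)) == 3.0

    @pytest.mark.parametrize("n,m", [(5, 2), (6, 3), (7, 3), (8, 4)])
    def test_moment_formulas_match_exhaustive_enumeration(self, rng, n, m):
        X = rng.standard_normal((n, 3))
        tree = build_mst(X)
        rs = []
        for idx in itertools.combinations(range(n), m):
            mask = np.zeros(n, bool)
            mask[list(idx)] = True
            rs.append(runs_count(tree, mask))
        rs = np.array(rs, float)
        assert rs.mean() == pytest.approx(expected_runs(m, n - m), rel=1e-12)
        assert rs.var() == pytest.approx(runs_variance(tree, m, n - m), rel=1e-10)

    def test_variance_undefined_for_tiny_n(self):
        tree = MSTree(list("abc"), [(0, 1, 1.0), (1, 2, 1.0)])
        with pytest.raises(ValueError, match="N <= 3"):
            runs_variance(tree, 2, 1)


class TestWWTest:
    def test_separated_groups_reject_in_lower_tail(self, rng):
        X = np.vstack([rng.standard_normal((10, 2)),
                       rng.standard_normal((10, 2)) + 8.0])
        labels = np.array([True] * 10 + [False] * 10)
        res = ww_test(X, labels, t=199, seed=5)
        assert res.extra["R"] == 2
        assert res.p_value < 0.05

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((12, 2))
        labels = np.array([True] * 6 + [False] * 6)
        p1 = ww_test(X, labels, t=99, seed=3).p_value
        p2 = ww_test(X, labels, t=99, seed=3).p_value
        assert p1 == p2

    def test_asymptotic_mode_agrees_with_permutation_at_n40(self, rng):
        X = np.vstack([rng.standard_normal((20, 3)),
                       rng.standard_normal((20, 3)) + 1.0])
        labels = np.array([True] * 20 + [False] * 20)
        p_perm = ww_test(X, labels, t=999, seed=0).p_value
        p_asym = ww_test(X, labels, mode="asymptotic").p_value
        assert abs(p_perm - p_asym) < 0.05

    def test_asymptotic_needs_n_above_three(self):
        X = np.arange(3, dtype=float)[:, None]
        with pytest.raises(ValueError, match="N > 3"):
            ww_test(X, np.array([True, True, False]), mode="asymptotic")


class TestHDPRanks:
    def test_path_graph_ranks_follow_path(self):
        tree = build_mst(np.array([3.0, 2.0, 0.0, 1.0])[:, None])
        ranks = hdp_ranks(tree)
        order = np.argsort(ranks)
        # root is a path endpoint; ranking walks the path monotonically
        values = [3.0, 2.0, 0.0, 1.0]
        walked = [values[i] for i in order]
        assert walked == sorted(walked) or walked == sorted(walked, reverse=True)

    def test_star_roots_at_a_leaf(self):
        # star: center node 0, leaves 1..3; leaves have larger eccentricity
        tree = MSTree(list("abcd"), [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])
        ranks = hdp_ranks(tree)
        assert ranks[1] == 1  # smallest-index max-eccentricity leaf is the root
        assert ranks[0] == 2  # the center is visited second

    def test_ranks_are_a_bijection(self, rng):
        for n in (5, 8, 12):
            tree = build_mst(rng.standard_normal((n, 3)))
            ranks = hdp_ranks(tree)
            assert sorted(ranks.tolist()) == list(range(1, n + 1))


class TestKSTest:
    def test_full_separation_gives_d_one(self, rng):
        X = np.vstack([rng.standard_normal((6, 1)),
                       rng.standard_normal((6, 1)) + 50.0])
        labels = np.array([True] * 6 + [False] * 6)
        res = ks_test(X, labels, t=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_alternating_ranks_hand_value(self):
        # points 0,1,2,3 on a line form a path; labels alternate along it:
        # prefix gaps 0.5, 0, 0.5, 0 -> D = 0.5
        X = np.arange(4, dtype=float)[:, None]
        labels = np.array([True, False, True, False])
        res = ks_test(X, labels, t=9, seed=0)
        assert res.statistic == pytest.approx(0.5)

    def test_label_swap_symmetry(self, rng):
        X = rng.standard_normal((10, 2))
        labels = np.array([True] * 4 + [False] * 6)
        d1 = ks_test(X, labels, t=9, seed=0).statistic
        d2 = ks_test(X, ~labels, t=9, seed=0).statistic
        assert d1 == pytest.approx(d2)
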