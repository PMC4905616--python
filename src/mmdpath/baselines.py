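"""Baseline multivariate two-sample tests: Hotelling T^2 and the two
minimum-spanning-tree (MST) generalizations of classical univariate tests —
the multivariate Wald-Wolfowitz runs test (mWW) and the multivariate
Kolmogorov-Smirnov test (mKS).

All three operate on the raw (Euclidean) feature space of the pooled samples,
not on a kernel embedding; for integrated multi-omics runs the aligned blocks'
columns are concatenated.

Hotelling's T^2 assumes multivariate normality with a common covariance and
requires the pooled covariance to be invertible; with p features and groups of
sizes m, n this fails whenever p > m + n - 2, in which case the test is
reported "not applicable" (:class:`NotApplicableError`) — the kernel MMD test
has no such restriction.

The graph tests start from the MST of the pooled points under Euclidean edge
weights.  The runs test deletes every edge joining samples from different
groups and counts the remaining disjoint subtrees R (on a tree, R equals the
between-group edge count plus one); few subtrees indicate separation, so the
test rejects in the lower tail.  The multivariate KS test ranks the pooled
points by a height-directed preorder (HDP) traversal of the MST rooted at a
node of maximal eccentricity, then computes the usual maximal gap between the
two groups' empirical distribution functions along that ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .io import OmicsBlock
from .mmd import TestResult, _as_mask

__all__ = [
    "NotApplicableError",
    "MSTree",
    "hotelling_t2",
    "build_mst",
    "runs_count",
    "expected_runs",
    "runs_variance",
    "ww_test",
    "hdp_ranks",
    "ks_test",
]


class NotApplicableError(ValueError):
    """The test's assumptions fail structurally (e.g. p > m + n - 2 for
    Hotelling); corresponds to a dash rather than a p-value in a results
    table."""


def _points(data: OmicsBlock | np.ndarray) -> np.ndarray:
    return data.values if isinstance(data, OmicsBlock) else np.asarray(data, float)


# ---------------------------------------------------------------------------
# Hotelling T^2


def hotelling_t2(
    block_x: OmicsBlock | np.ndarray, block_y: OmicsBlock | np.ndarray
) -> TestResult:
    """Two-sample Hotelling T^2 test with pooled covariance.

    ``T^2 = (mn/(m+n)) (xbar - ybar)' S^{-1} (xbar - ybar)`` and
    ``(m+n-p-1)/((m+n-2) p) * T^2 ~ F(p, m+n-p-1)`` under the null.

    Raises :class:`NotApplicableError` when ``p > m + n - 2`` or the pooled
    covariance is numerically singular.
    """
    X = np.atleast_2d(_points(block_x))
    Y = np.atleast_2d(_points(block_y))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("groups must share the feature space")
    m, n, p = X.shape[0], Y.shape[0], X.shape[1]
    if m < 2 or n < 2:
        raise ValueError("each group needs >= 2 samples")
    if p > m + n - 2:
        raise NotApplicableError(
            f"Hotelling test not applicable: p={p} features exceed m+n-2={m + n - 2} "
            "degrees of freedom (pooled covariance is singular)"
        )
    d = X.mean(axis=0) - Y.mean(axis=0)
    S = ((m - 1) * np.cov(X, rowvar=False, ddof=1)
         + (n - 1) * np.cov(Y, rowvar=False, ddof=1)) / (m + n - 2)
    S = np.atleast_2d(S)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        raise NotApplicableError(
            "Hotelling test not applicable: pooled covariance is singular"
        ) from None
    if not np.all(np.isfinite(sol)) or np.linalg.cond(S) > 1e12:
        raise NotApplicableError(
            "Hotelling test not applicable: pooled covariance is numerically singular"
        )
    t2 = float(m * n / (m + n) * d @ sol)
    df2 = m + n - p - 1
    f_stat = t2 * df2 / ((m + n - 2) * p)
    p_value = float(stats.f.sf(f_stat, p, df2))
    return TestResult(
        method="hotelling",
        statistic=t2,
        p_value=p_value,
        t=0,
        n_null_ge_observed=0,
        seed=None,
        group_sizes=(m, n),
        extra={"F": f_stat, "df": (p, df2)},
    )


# ---------------------------------------------------------------------------
# Minimum spanning tree machinery


@dataclass
class MSTree:
    """Euclidean minimum spanning tree of the pooled samples.

    ``edges`` hold ``(i, j, weight)`` with ``i < j`` node indices into
    ``nodes``; a tree on n nodes has exactly n - 1 edges.
    """

    nodes: list[str]
    edges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if len(self.edges) != n - 1:
            raise ValueError(f"a spanning tree on {n} nodes needs {n - 1} edges")
        g = self.graph()
        if not nx.is_connected(g):
            raise ValueError("edges do not form a connected tree")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_weighted_edges_from(self.edges)
        return g

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def edge_array(self) -> np.ndarray:
        return np.array([(i, j) for i, j, _ in self.edges], dtype=int)

    def to_edge_list(self) -> str:
        """Plain-text edge list (one ``id_i<TAB>id_j<TAB>weight`` per line)."""
        return "\n".join(
            f"{self.nodes[i]}\t{self.nodes[j]}\t{w:.10g}" for i, j, w in self.edges
        )


def build_mst(points: OmicsBlock | np.ndarray) -> MSTree:
    """Euclidean MST of the pooled samples with deterministic tie-breaking.

    Candidate edges enter Kruskal's algorithm in lexicographic (i, j) order,
    so equal-weight ties always resolve the same way across runs and
    platforms.  Duplicate points are allowed (zero-weight edges).
    """
    X = np.atleast_2d(_points(points))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 points")
    ids = (list(points.sample_ids) if isinstance(points, OmicsBlock)
           else [str(i) for i in range(n)])
    D = np.sqrt(np.maximum(
        ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1), 0.0))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(D[i, j]))
    # networkx Kruskal sorts edges stably by weight, so insertion order
    # (lexicographic) breaks ties deterministically
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted(
        (min(i, j), max(i, j), float(d["weight"])) for i, j, d in mst.edges(data=True)
    )
    return MSTree(ids, edges)


def runs_count(tree: MSTree, labels: Sequence | np.ndarray) -> int:
    """Number of disjoint subtrees R after deleting between-group edges.

    Equals the between-group edge count plus one.
    """
    mask = _as_mask(labels, tree.n)
    between = sum(1 for i, j, _ in tree.edges if mask[i] != mask[j])
    return between + 1


def expected_runs(m: int, n: int) -> float:
    """Null mean of R under label permutation: ``E[R] = 2mn/N + 1``."""
    N = m + n
    return 2.0 * m * n / N + 1.0


def runs_variance(tree: MSTree, m: int, n: int) -> float:
    """Null variance of R under label permutation on a fixed tree.

    ``Var[R] = (2mn/(N(N-1))) [ (2mn - N)/N
               + ((C - N + 2)/((N-2)(N-3))) (N(N-1) - 4mn + 2) ]``
    with ``C = sum_v deg(v)(deg(v)-1)/2`` the number of edge pairs sharing a
    node.  Undefined for N <= 3.
    """
    N = m + n
    if N <= 3:
        raise ValueError("runs-test variance undefined for N <= 3")
    deg = tree.degrees
    C = float((deg * (deg - 1)).sum()) / 2.0
    mn2 = 2.0 * m * n
    return (mn2 / (N * (N - 1.0))) * (
        (mn2 - N) / N
        + ((C - N + 2.0) / ((N - 2.0) * (N - 3.0))) * (N * (N - 1.0) - 2.0 * mn2 + 2.0)
    )


def ww_test(
    points: OmicsBlock | np.ndarray,
    labels: Sequence | np.ndarray,
    mode: Literal["permutation", "asymptotic"] = "permutation",
    t: int = 2499,
    seed: int | None = None,
    tree: MSTree | None = None,
) -> TestResult:
    """Multivariate Wald-Wolfowitz runs test on the Euclidean MST.

    Permutation mode (default): labels are permuted on the *fixed* tree and
    ``p = (1 + #{R* <= R_obs})/(t + 1)`` (few subtrees = separation, lower
    tail).  Asymptotic mode: the standardized count
    ``W = (R - E[R])/sqrt(Var[R])`` is referred to the standard normal, again
    lower-tailed.  The standardized W is reported in either mode (for N >= 4).
    """
    X = np.atleast_2d(_points(points))
    mask = _as_mask(labels, X.shape[0])
    m, n = int(mask.sum()), int((~mask).sum())
    if min(m, n) < 1:
        raise ValueError("both groups must be non-empty")
    if tree is None:
        tree = build_mst(points)
    r_obs = runs_count(tree, mask)
    N = m + n
    w = None
    if N > 3:
        var = runs_variance(tree, m, n)
        w = (r_obs - expected_runs(m, n)) / np.sqrt(var) if var > 0 else np.nan
    if mode == "asymptotic":
        if N <= 3:
            raise ValueError("asymptotic runs test needs N > 3 (variance undefined)")
        return TestResult(
            method="mWW", statistic=float(w), p_value=float(stats.norm.cdf(w)),
            t=0, n_null_ge_observed=0, seed=None, group_sizes=(m, n),
            extra={"R": r_obs, "W": float(w), "mode": "asymptotic"},
        )
    if mode != "permutation":
        raise ValueError(f"unknown mode {mode!r}")
    if t < 1:
        raise ValueError("t must be >= 1")
    rng = np.random.default_rng(seed)
    edges = tree.edge_array()
    count_le = 0
    for _ in range(t):
        perm_mask = np.zeros(N, dtype=bool)
        perm_mask[rng.permutation(N)[:m]] = True
        r_star = int((perm_mask[edges[:, 0]] != perm_mask[edges[:, 1]]).sum()) + 1
        if r_star <= r_obs:
            count_le += 1
    return TestResult(
        method="mWW",
        statistic=float(r_obs),
        p_value=(1 + count_le) / (t + 1),
        t=t,
        n_null_ge_observed=count_le,  # lower-tail count for R
        seed=seed,
        group_sizes=(m, n),
        extra={"R": r_obs, "W": None if w is None else float(w), "mode": "permutation"},
    )


def hdp_ranks(tree: MSTree) -> np.ndarray:
    """Rank the pooled points 1..n by height-directed preorder traversal.

    The root is a node of maximal eccentricity (unweighted hop distance on the
    tree; ties -> smallest node index).  Each node's children are visited in
    order of increasing subtree height, ties again by node index.  Returns an
    array ``ranks`` with ``ranks[v]`` the visit position (1-based) of node v —
    a bijection onto 1..n.
    """
    g = tree.graph()
    ecc = nx.eccentricity(g)
    root = min(sorted(ecc), key=lambda v: (-ecc[v], v))
    # iterative post-order to get subtree heights
    height = {v: 0 for v in g.nodes}
    parent = {root: None}
    order = [root]
    for v in order:
        for u in g.neighbors(v):
            if u != parent[v]:
                parent[u] = v
                order.append(u)
    for v in reversed(order):
        if parent[v] is not None:
            height[parent[v]] = max(height[parent[v]], height[v] + 1)
    ranks = np.empty(tree.n, dtype=int)
    stack = [root]
    pos = 0
    while stack:
        v = stack.pop()
        pos += 1
        ranks[v] = pos
        children = [u for u in g.neighbors(v) if parent[u] == v]
        children.sort(key=lambda u: (height[u], u), reverse=True)  # stack pops smallest
        stack.extend(children)
    return ranks


def _ks_statistic(order: np.ndarray, mask: np.ndarray, m: int, n: int) -> float:
    """Max prefix gap |F1 - F2| along a ranking (order = node indices, ranked)."""
    g1 = np.cumsum(mask[order]) / m
    g2 = np.cumsum(~mask[order]) / n
    return float(np.max(np.abs(g1 - g2)))


def ks_test(
    points: OmicsBlock | np.ndarray,
    labels: Sequence | np.ndarray,
    t: int = 2499,
    seed: int | None = None,
    tree: MSTree | None = None,
) -> TestResult:
    """Multivariate Kolmogorov-Smirnov test via MST-based HDP ranking.

    With the pooled points sorted by :func:`hdp_ranks`, the statistic is the
    classical two-sample KS gap ``D = max_i |F1_hat(i) - F2_hat(i)|`` over
    ranking prefixes, and ``p = (1 + #{D* >= D_obs})/(t + 1)`` by label
    permutation on the fixed ranking.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    X = np.atleast_2d(_points(points))
    mask = _as_mask(labels, X.shape[0])
    m, n = int(mask.sum()), int((~mask).sum())
    if tree is None:
        tree = build_mst(points)
    ranks = hdp_ranks(tree)
    order = np.argsort(ranks)
    d_obs = _ks_statistic(order, mask, m, n)
    rng = np.random.default_rng(seed)
    N = m + n
    count_ge = 0
    for _ in range(t):
        perm_mask = np.zeros(N, dtype=bool)
        perm_mask[rng.permutation(N)[:m]] = True
        if _ks_statistic(order, perm_mask, m, n) >= d_obs:
            count_ge += 1
    return TestResult(
        method="mKS",
        statistic=d_obs,
        p_value=(1 + count_ge) / (t + 1),
        t=t,
        n_null_ge_observed=count_ge,
        seed=seed,
        group_sizes=(m, n),
        extra={"D": d_obs, "ranks": ranks.tolist()},
    )
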