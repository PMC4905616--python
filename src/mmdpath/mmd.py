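"""Unbiased MMD^2 two-sample statistic and its permutation test.

The maximum mean discrepancy (MMD) between distributions P and Q is the RKHS
distance between their mean elements; with a universal kernel (e.g. Gaussian)
it is zero iff P = Q.  Given samples X (size m) and Y (size n) the unbiased
estimator of MMD^2 is the U-statistic

    MMD^2 = 1/(m(m-1)) sum_{i!=j} k(x_i, x_j)
          + 1/(n(n-1)) sum_{i!=j} k(y_i, y_j)
          - 2/(mn)     sum_{i,j}  k(x_i, y_j)

which may be negative on finite samples (that is the price of unbiasedness).
Significance is assessed by a permutation test: group labels are reassigned
uniformly at random (group sizes preserved) on the *fixed* pooled kernel
matrix, and

    p = (1 + #{null >= observed}) / (t + 1)

so the smallest attainable p-value at t permutations is 1/(t+1) (4e-04 at the
default t = 2499) and p is never zero.  Ties count toward the >= set
(conservative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .kernels import KernelMatrix

__all__ = ["TestResult", "mmd2_unbiased", "permutation_null", "mmd_test"]

DEFAULT_PERMUTATIONS = 2499


@dataclass
class TestResult:
    """Outcome of a permutation (or parametric) two-sample test."""

    method: str
    statistic: float
    p_value: float
    t: int
    n_null_ge_observed: int
    seed: int | None
    group_sizes: tuple[int, int]
    null_stats: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t > 0:
            expected = (1 + self.n_null_ge_observed) / (self.t + 1)
            if abs(self.p_value - expected) > 1e-12:
                raise ValueError("p_value inconsistent with permutation counts")
            if not (1.0 / (self.t + 1) - 1e-12 <= self.p_value <= 1.0 + 1e-12):
                raise ValueError("permutation p-value out of range")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "t": int(self.t),
            "n_null_ge_observed": int(self.n_null_ge_observed),
            "seed": self.seed,
            "group_sizes": list(self.group_sizes),
        }
        d.update({
            k: (float(v) if isinstance(v, (int, float, np.integer, np.floating))
                else v)
            for k, v in self.extra.items()
        })
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_tsv_row(self) -> str:
        d = self.to_dict()
        return "\t".join(str(d[k]) for k in
                         ("method", "statistic", "p_value", "t", "seed", "group_sizes"))


def _as_mask(labels: Sequence | np.ndarray, n: int) -> np.ndarray:
    mask = np.asarray(labels)
    if mask.dtype != bool:
        lv = list(dict.fromkeys(mask.tolist()))
        if len(lv) != 2:
            raise ValueError(f"labels must have exactly 2 levels, got {lv}")
        mask = mask == lv[0]
    if mask.shape != (n,):
        raise ValueError(f"labels length {mask.shape} does not match {n} samples")
    return mask


def mmd2_unbiased(
    K: KernelMatrix | np.ndarray,
    labels: Sequence | np.ndarray,
    cross: Literal["full", "exclude-paired"] = "full",
) -> float:
    """Unbiased MMD^2 from a precomputed kernel matrix and two-level labels.

    ``labels`` is either a boolean mask (True = group X) or any two-level
    vector (first level observed = group X; the statistic is symmetric in the
    groups, so the choice is immaterial).  Both groups need >= 2 samples.

    ``cross="full"`` uses the full cross sum over all (i, j) pairs — the
    standard U-statistic.  ``cross="exclude-paired"`` omits the i == j diagonal
    of the cross term (a variant only defined for m == n), available for
    sensitivity checks.
    """
    V = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    mask = _as_mask(labels, V.shape[0])
    m = int(mask.sum())
    n = int((~mask).sum())
    if m < 2 or n < 2:
        raise ValueError(f"each group needs >= 2 samples, got m={m}, n={n}")
    Kxx = V[np.ix_(mask, mask)]
    Kyy = V[np.ix_(~mask, ~mask)]
    Kxy = V[np.ix_(mask, ~mask)]
    term_x = (Kxx.sum() - np.trace(Kxx)) / (m * (m - 1))
    term_y = (Kyy.sum() - np.trace(Kyy)) / (n * (n - 1))
    if cross == "full":
        term_xy = Kxy.sum() / (m * n)
    elif cross == "exclude-paired":
        if m != n:
            raise ValueError("cross='exclude-paired' requires m == n")
        term_xy = (Kxy.sum() - np.trace(Kxy)) / (m * n)
    else:
        raise ValueError(f"unknown cross convention {cross!r}")
    return float(term_x + term_y - 2.0 * term_xy)


def permutation_null(
    K: KernelMatrix | np.ndarray,
    labels: Sequence | np.ndarray,
    t: int,
    seed: int | np.random.Generator | None = None,
    cross: Literal["full", "exclude-paired"] = "full",
) -> np.ndarray:
    """Null distribution of MMD^2 under random relabeling.

    Each of the ``t`` draws partitions the pooled index set uniformly at
    random into groups of the observed sizes (m, n); kernel entries are never
    recomputed.  Reproducible given ``seed``.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    V = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    N = V.shape[0]
    mask = _as_mask(labels, N)
    m = int(mask.sum())
    n = N - m
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masks = np.zeros((t, N), dtype=float)
    for b in range(t):
        masks[b, rng.permutation(N)[:m]] = 1.0
    if cross != "full":
        return np.array([mmd2_unbiased(V, masks[b].astype(bool), cross=cross)
                         for b in range(t)])
    # batched quadratic forms: for each 0/1 mask z,
    #   z'Kz, z'K1 and the diagonal parts give all three sums of the estimator
    KM = masks @ V                                   # (t, N)
    qxx = np.einsum("ti,ti->t", KM, masks)           # z'Kz (diag included)
    zK1 = KM.sum(axis=1)                             # z'K1
    diag = V.diagonal()
    diag_x = masks @ diag
    total, trace = V.sum(), diag.sum()
    sxx = qxx - diag_x                               # sum_{i!=j} K_xx
    syy = (total - 2 * zK1 + qxx) - (trace - diag_x)  # sum_{i!=j} K_yy
    cross_sum = zK1 - qxx                            # full cross sum
    return sxx / (m * (m - 1)) + syy / (n * (n - 1)) - 2 * cross_sum / (m * n)


def mmd_test(
    K: KernelMatrix | np.ndarray,
    labels: Sequence | np.ndarray,
    t: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    cross: Literal["full", "exclude-paired"] = "full",
    keep_null: bool = False,
) -> TestResult:
    """Kernel MMD permutation test for equality of two distributions.

    Returns a :class:`TestResult` with the observed unbiased MMD^2 and
    ``p = (1 + #{null >= observed})/(t + 1)``.
    """
    V = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    mask = _as_mask(labels, V.shape[0])
    observed = mmd2_unbiased(V, mask, cross=cross)
    null = permutation_null(V, mask, t=t, seed=seed, cross=cross)
    r = int((null >= observed).sum())
    return TestResult(
        method="mmd",
        statistic=observed,
        p_value=(1 + r) / (t + 1),
        t=t,
        n_null_ge_observed=r,
        seed=seed if isinstance(seed, int) else None,
        group_sizes=(int(mask.sum()), int((~mask).sum())),
        null_stats=null if keep_null else None,
    )
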