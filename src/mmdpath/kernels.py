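"""Kernel matrices: Gaussian (RBF) kernels, the quantile bandwidth heuristic,
double-centering, and kernel addition for multi-omics integration.

The Gaussian kernel is parameterized as ``k(x, x') = exp(-gamma * ||x - x'||^2)``
with rate ``gamma > 0``.  The bandwidth heuristic estimates an admissible range
for gamma from the 0.1 and 0.9 quantiles of the nonzero pairwise squared
distances — any rate between ``1/q_0.9`` and ``1/q_0.1`` is considered a good
choice — and this implementation fixes the default deterministically at the
reciprocal of the *median* nonzero squared distance.  All pairwise distances
enter the quantiles (sample sizes in this problem class are small), so the
estimate involves no randomness.

Integration of several omics blocks is by weighted addition of their kernel
matrices: a sum of positive semi-definite (PSD) matrices is PSD, so the result
is again a valid kernel, now over the concatenated feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import OmicsBlock

__all__ = [
    "KernelConfig",
    "KernelMatrix",
    "squared_distances",
    "estimate_gamma",
    "rbf_kernel",
    "linear_kernel",
    "center_kernel",
    "combine_kernels",
    "read_kernel",
    "write_kernel",
]

#: relative eigenvalue tolerance for the PSD invariant
PSD_RTOL = 1e-8


@dataclass(frozen=True)
class KernelConfig:
    """Kernel family and hyper-parameters.

    ``gamma`` is the RBF rate; ``gamma_bounds`` is the admissible interval
    produced by the quantile heuristic (always reported alongside the chosen
    value so the sensitivity of downstream results can be probed).
    """

    kernel_family: str = "rbf"
    gamma: float | None = None
    gamma_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kernel_family not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel family {self.kernel_family!r}")
        if self.kernel_family == "rbf":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("rbf kernel requires gamma > 0")
            if self.gamma_bounds is not None:
                lo, hi = self.gamma_bounds
                if not (0 < lo <= hi):
                    raise ValueError("gamma_bounds must be positive and ordered")
                if not (lo - 1e-12 <= self.gamma <= hi + 1e-12):
                    raise ValueError(
                        f"gamma {self.gamma} outside bounds {self.gamma_bounds}"
                    )


@dataclass
class KernelMatrix:
    """Symmetric PSD sample x sample similarity matrix with provenance.

    ``provenance`` records, per contributing block, the block name, its
    :class:`KernelConfig` and the combination weight.
    """

    values: np.ndarray
    sample_ids: list[str]
    provenance: list[tuple[str, KernelConfig, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match {n} sample ids"
            )
        # enforce exact symmetry by construction
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def is_psd(self, rtol: float = PSD_RTOL) -> bool:
        """Eigenvalue check: smallest eigenvalue >= -rtol * largest."""
        ev = np.linalg.eigvalsh(self.values)
        top = max(ev[-1], np.finfo(float).tiny)
        return bool(ev[0] >= -rtol * top)


def squared_distances(block: OmicsBlock | np.ndarray) -> np.ndarray:
    """All pairwise squared Euclidean distances, as a symmetric matrix.

    ``d[i, j] = sum_f (x[i, f] - x[j, f])^2`` with an exactly zero diagonal.
    """
    X = block.values if isinstance(block, OmicsBlock) else np.asarray(block, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    D = squareform(pdist(X, metric="sqeuclidean"))
    return np.maximum(D, 0.0)


def estimate_gamma(
    block: OmicsBlock | np.ndarray,
    quantile_pair: tuple[float, float] = (0.1, 0.9),
) -> KernelConfig:
    """RBF rate by the quantile heuristic on pooled pairwise squared distances.

    ``gamma_bounds = (1/q_hi, 1/q_lo)`` where ``q_lo``/``q_hi`` are the lower
    and upper quantiles (default 0.1 and 0.9, linear interpolation) of the
    *nonzero* squared distances, and the default rate is the reciprocal of
    their median.  Estimated once on the pooled two-condition data — the
    permutation null must hold the kernel fixed.

    Raises on constant data (no positive pairwise distance).
    """
    D = squared_distances(block)
    iu = np.triu_indices_from(D, k=1)
    d = D[iu]
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all pairwise distances are zero (constant data); "
                         "cannot estimate a bandwidth")
    q_lo, q_hi = quantile_pair
    if not (0 <= q_lo <= q_hi <= 1):
        raise ValueError(f"invalid quantile pair {quantile_pair}")
    lo_d, med, hi_d = np.quantile(d, [q_lo, 0.5, q_hi], method="linear")
    return KernelConfig(
        kernel_family="rbf",
        gamma=float(1.0 / med),
        gamma_bounds=(float(1.0 / hi_d), float(1.0 / lo_d)),
    )


def rbf_kernel(block: OmicsBlock, config: KernelConfig | None = None) -> KernelMatrix:
    """Gaussian kernel ``K[i, j] = exp(-gamma * ||x_i - x_j||^2)``.

    With ``config=None`` the rate is estimated by :func:`estimate_gamma`.
    The diagonal is exactly 1.
    """
    if config is None:
        config = estimate_gamma(block)
    if config.kernel_family != "rbf":
        raise ValueError("rbf_kernel requires an rbf KernelConfig")
    K = np.exp(-config.gamma * squared_distances(block))
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, list(block.sample_ids), [(block.name, config, 1.0)])


def linear_kernel(block: OmicsBlock) -> KernelMatrix:
    """Linear kernel ``K = X X^T`` (inner products in the raw feature space)."""
    K = block.values @ block.values.T
    return KernelMatrix(K, list(block.sample_ids),
                        [(block.name, KernelConfig("linear"), 1.0)])


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """Double-center a kernel: ``K~ = H K H`` with ``H = I - 11^T/n``.

    Equivalent to centering the implicit feature-space embedding at its mean;
    every row and column of the output sums to zero.  Idempotent.
    """
    V = K.values
    n = V.shape[0]
    row = V.mean(axis=1, keepdims=True)
    col = V.mean(axis=0, keepdims=True)
    C = V - row - col + V.mean()
    return KernelMatrix(C, list(K.sample_ids), list(K.provenance))


def combine_kernels(
    kernels: Sequence[KernelMatrix],
    weights: Sequence[float] | None = None,
) -> KernelMatrix:
    """Weighted sum of kernel matrices over the same ordered samples.

    The default weights are all 1 (plain addition).  A nonnegative combination
    of PSD matrices is PSD, so the result is a valid kernel on the combined
    representation.  Sample ids must match exactly, in order — use
    :func:`mmdpath.io.align_samples` first.
    """
    if not kernels:
        raise ValueError("no kernels to combine")
    if weights is None:
        weights = [1.0] * len(kernels)
    weights = [float(w) for w in weights]
    if len(weights) != len(kernels):
        raise ValueError("one weight per kernel required")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    if not any(w > 0 for w in weights):
        raise ValueError("at least one weight must be positive")
    ids = kernels[0].sample_ids
    for k in kernels[1:]:
        if k.sample_ids != ids:
            raise ValueError("kernels have mismatched sample ids/order; align first")
    total = sum(w * k.values for k, w in zip(kernels, weights))
    prov = [
        (name, cfg, w * pw)
        for k, w in zip(kernels, weights)
        for name, cfg, pw in k.provenance
    ]
    return KernelMatrix(total, list(ids), prov)


def write_kernel(K: KernelMatrix, path: str | Path) -> None:
    """Export a kernel matrix as TSV with sample ids (for debugging and
    cross-language checks)."""
    df = pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_kernel(path: str | Path) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("kernel TSV row and column ids differ")
    return KernelMatrix(df.to_numpy(float), list(df.index.astype(str)))
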