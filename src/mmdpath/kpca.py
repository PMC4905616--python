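"""Kernel PCA sample maps and per-feature gradient ("arrow") fields.

Kernel PCA eigendecomposes the double-centered kernel matrix; sample
coordinates on component k are ``sqrt(lambda_k) * v_k``.  For a linear kernel
on column-centered data this reproduces classical PCA scores, which serves as
the oracle in the test suite.

To interpret a pathway map, each feature can be displayed as a field of
arrows: the feature's values are smoothed over the 2-D embedding with a
Nadaraya-Watson (Gaussian-weighted local average) estimator and the arrow at
each sample is the analytic gradient of that smooth surface — the local
direction of maximum growth of the feature.  This smoother-gradient
construction is this package's own, fully specified surrogate for the
visualization technique the original pathway figures rely on; it reproduces
the intended semantics (arrows point where the feature increases) and is
testable in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import OmicsBlock, SampleMetadata
from .kernels import KernelMatrix, center_kernel

__all__ = ["KPCAEmbedding", "ArrowField", "kpca_embed", "variable_arrows",
           "silverman_bandwidths", "export_plot_data"]


@dataclass
class KPCAEmbedding:
    """Samples projected on the leading kernel principal components.

    ``coordinates[:, k] = sqrt(eigenvalue_k) * v_k`` for unit eigenvectors
    ``v_k`` of the centered kernel, eigenvalues descending.
    ``dual_coefficients[:, k] = v_k / sqrt(eigenvalue_k)`` normalizes each
    feature-space principal axis to unit norm, so that projecting a (centered)
    kernel row onto component k is ``K_row @ dual_coefficients[:, k]``.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    dual_coefficients: np.ndarray
    sample_ids: list[str]
    kernel_provenance: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class ArrowField:
    """Per-sample gradient arrows of one feature over a 2-D embedding."""

    feature_id: str
    base_points: np.ndarray     # (n, 2) embedding coordinates
    vectors: np.ndarray         # (n, 2) scaled for plotting
    raw_gradients: np.ndarray   # (n, 2) unscaled analytic gradients

    def mean_vector(self) -> np.ndarray:
        """Single aggregate direction for the feature (average raw gradient)."""
        return self.raw_gradients.mean(axis=0)


def kpca_embed(K: KernelMatrix, n_components: int = 2,
               centered: bool = False) -> KPCAEmbedding:
    """Embed samples by eigendecomposition of the (double-centered) kernel.

    ``centered=True`` declares that ``K`` is already double-centered.  Signs
    are fixed so each component's largest-magnitude coordinate is positive
    (deterministic across eigen-solvers).  Requesting more components than
    there are positive eigenvalues is an error.
    """
    Kc = K if centered else center_kernel(K)
    evals, evecs = np.linalg.eigh(Kc.values)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals[0], 0.0) * 1e-10
    n_pos = int((evals > tol).sum())
    if n_components > n_pos:
        raise ValueError(
            f"requested {n_components} components but the centered kernel has "
            f"only {n_pos} positive eigenvalues"
        )
    lam = evals[:n_components]
    V = evecs[:, :n_components]
    # sign convention: largest-|coordinate| entry positive, per component
    for k in range(n_components):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    coords = V * np.sqrt(lam)
    dual = V / np.sqrt(lam)
    return KPCAEmbedding(
        coordinates=coords,
        eigenvalues=lam,
        dual_coefficients=dual,
        sample_ids=list(K.sample_ids),
        kernel_provenance=list(K.provenance),
    )


def silverman_bandwidths(coords: np.ndarray) -> np.ndarray:
    """Silverman's rule-of-thumb bandwidth per embedding axis (d = 2)."""
    n, d = coords.shape
    sigma = coords.std(axis=0, ddof=1)
    factor = (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))
    return factor * sigma


def variable_arrows(
    embedding: KPCAEmbedding,
    block: OmicsBlock,
    feature_id: str,
    bandwidth: float | Sequence[float] | None = None,
    max_length: float | None = None,
) -> ArrowField:
    """Gradient arrows of one feature over the leading-2-component plane.

    The feature is smoothed by a Nadaraya-Watson estimator with a Gaussian
    kernel over the 2-D embedding coordinates,

        m(z) = sum_i w_i(z) f_i,   w_i(z) ∝ exp(-sum_j (z_j - c_ij)^2 / (2 h_j^2)),

    and the arrow at each sample is the analytic gradient

        ∇m(z) = sum_i w_i(z) (f_i - m(z)) (c_i - z) / h^2   (elementwise in j).

    ``bandwidth`` is a scalar or per-axis pair; ``None`` uses Silverman's
    rule per axis.  For plotting, arrows are rescaled to a common maximum
    length (default: 10 % of the embedding's coordinate range); the raw
    gradients are retained.
    """
    if embedding.n_components < 2:
        raise ValueError("arrow fields need an embedding with >= 2 components")
    if embedding.sample_ids != block.sample_ids:
        raise ValueError("embedding and block sample ids differ; align first")
    if feature_id not in block.feature_ids:
        raise KeyError(f"feature {feature_id!r} not in block {block.name!r}")
    coords = embedding.coordinates[:, :2]
    f = block.values[:, block.feature_ids.index(feature_id)]
    if bandwidth is None:
        h = silverman_bandwidths(coords)
    else:
        h = np.broadcast_to(np.asarray(bandwidth, float), (2,)).copy()
    if np.any(h <= 0):
        raise ValueError("bandwidth must be strictly positive")
    if np.ptp(f) == 0:  # constant feature: the smooth surface is flat
        zeros = np.zeros_like(coords)
        return ArrowField(feature_id=feature_id, base_points=coords.copy(),
                          vectors=zeros, raw_gradients=zeros.copy())
    f = f - f.mean()  # gradient is offset-invariant; improves conditioning

    diff = coords[None, :, :] - coords[:, None, :]        # (z, i, 2): c_i - z
    logw = -0.5 * ((diff / h) ** 2).sum(axis=-1)          # (z, i)
    W = np.exp(logw - logw.max(axis=1, keepdims=True))
    W /= W.sum(axis=1, keepdims=True)
    m = W @ f                                             # smoothed value at each z
    resid = f[None, :] - m[:, None]                       # (z, i)
    grad = ((W * resid)[:, :, None] * diff / h**2).sum(axis=1)  # (z, 2)

    norms = np.linalg.norm(grad, axis=1)
    top = norms.max()
    if max_length is None:
        span = coords.max(axis=0) - coords.min(axis=0)
        max_length = 0.1 * float(np.linalg.norm(span))
    vectors = grad * (max_length / top) if top > 0 else np.zeros_like(grad)
    return ArrowField(feature_id=feature_id, base_points=coords.copy(),
                      vectors=vectors, raw_gradients=grad)


def export_plot_data(
    embedding: KPCAEmbedding,
    out_dir: str | Path,
    arrow_fields: Sequence[ArrowField] = (),
    metadata: SampleMetadata | None = None,
    render: bool = False,
) -> dict[str, Path]:
    """Write TSVs with the sample map (plus factor levels) and arrow fields.

    Returns a dict of written paths.  ``render=True`` additionally saves a
    static PNG of the map with arrows (matplotlib, no GUI).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    coords = pd.DataFrame(
        embedding.coordinates,
        index=embedding.sample_ids,
        columns=[f"PC{k + 1}" for k in range(embedding.n_components)],
    )
    coords.index.name = "sample_id"
    if metadata is not None:
        meta = metadata.reorder(embedding.sample_ids)
        for fac, levels in meta.factors.items():
            coords[fac] = levels
    p = out_dir / "kpca_coordinates.tsv"
    coords.to_csv(p, sep="\t")
    written["coordinates"] = p

    if arrow_fields:
        rows = []
        for af in arrow_fields:
            for sid, base, vec, raw in zip(
                embedding.sample_ids, af.base_points, af.vectors, af.raw_gradients
            ):
                rows.append((af.feature_id, sid, *base, *vec, *raw))
        arrows = pd.DataFrame(
            rows, columns=["feature", "sample_id", "x", "y",
                           "dx", "dy", "grad_x", "grad_y"],
        )
        p = out_dir / "kpca_arrows.tsv"
        arrows.to_csv(p, sep="\t", index=False)
        written["arrows"] = p
        means = pd.DataFrame(
            [(af.feature_id, *af.mean_vector()) for af in arrow_fields],
            columns=["feature", "mean_grad_x", "mean_grad_y"],
        )
        p = out_dir / "kpca_arrow_means.tsv"
        means.to_csv(p, sep="\t", index=False)
        written["arrow_means"] = p

    if render:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        xy = embedding.coordinates[:, :2]
        if metadata is not None and meta.factors:
            fac = next(iter(meta.factors))
            for lv in dict.fromkeys(meta.factors[fac]):
                sel = np.array([v == lv for v in meta.factors[fac]])
                ax.scatter(xy[sel, 0], xy[sel, 1], label=f"{fac}={lv}", s=25)
            ax.legend(frameon=False, fontsize=8)
        else:
            ax.scatter(xy[:, 0], xy[:, 1], s=25)
        for af in arrow_fields:
            ax.quiver(af.base_points[:, 0], af.base_points[:, 1],
                      af.vectors[:, 0], af.vectors[:, 1],
                      angles="xy", scale_units="xy", scale=1,
                      width=0.002, alpha=0.5)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        p = out_dir / "kpca_map.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written["figure"] = p
    return written
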