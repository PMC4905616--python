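"""Kernel PCA embedding and per-feature gradient arrow fields."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA

from mmdpath.io import OmicsBlock, SampleMetadata
from mmdpath.kernels import center_kernel, linear_kernel, rbf_kernel
from mmdpath.kpca import (
    export_plot_data, kpca_embed, silverman_bandwidths, variable_arrows,
)


def make_block(X, name="b"):
    return OmicsBlock(name, [f"s{i}" for i in range(X.shape[0])],
                      [f"f{j}" for j in range(X.shape[1])], X)


def sign_align(A, B):
    """Flip columns of A to match the signs of B (component-wise)."""
    out = A.copy()
    for k in range(A.shape[1]):
        if np.dot(out[:, k], B[:, k]) < 0:
            out[:, k] = -out[:, k]
    return out


class TestKPCAEmbed:
    def test_linear_kernel_reproduces_classical_pca(self, rng):
        X = rng.standard_normal((15, 4))
        Xc = X - X.mean(axis=0)
        emb = kpca_embed(linear_kernel(make_block(Xc)), n_components=3)
        scores = PCA(n_components=3).fit_transform(Xc)
        np.testing.assert_allclose(sign_align(scores, emb.coordinates),
                                   emb.coordinates, atol=1e-8)

    def test_duplicated_samples_share_coordinates(self, rng):
        X = rng.standard_normal((6, 3))
        X[4] = X[1]
        emb = kpca_embed(rbf_kernel(make_block(X)), n_components=2)
        np.testing.assert_allclose(emb.coordinates[4], emb.coordinates[1],
                                   atol=1e-10)

    def test_eigenvalues_descending_and_bounded_by_trace(self, rng):
        X = rng.standard_normal((10, 5))
        K = rbf_kernel(make_block(X))
        emb = kpca_embed(K, n_components=4)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)
        assert emb.eigenvalues.sum() <= np.trace(center_kernel(K).values) + 1e-10

    def test_coordinates_are_centered(self, rng):
        X = rng.standard_normal((12, 3))
        emb = kpca_embed(rbf_kernel(make_block(X)), n_components=2)
        np.testing.assert_allclose(emb.coordinates.mean(axis=0), 0.0, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        X = rng.standard_normal((8, 3))
        emb = kpca_embed(rbf_kernel(make_block(X)), n_components=2)
        for k in range(2):
            j = np.argmax(np.abs(emb.coordinates[:, k]))
            assert emb.coordinates[j, k] > 0

    def test_too_many_components_rejected(self):
        # rank-1 data: only one positive eigenvalue after centering
        X = np.outer(np.arange(5, dtype=float), [1.0, 2.0])
        with pytest.raises(ValueError, match="positive eigenvalues"):
            kpca_embed(linear_kernel(make_block(X)), n_components=3)

    def test_dual_coefficients_project_back(self, rng):
        X = rng.standard_normal((9, 4))
        K = center_kernel(rbf_kernel(make_block(X)))
        emb = kpca_embed(K, n_components=2, centered=True)
        np.testing.assert_allclose(K.values @ emb.dual_coefficients,
                                   emb.coordinates, atol=1e-8)


def symmetric_grid_embedding():
    """Embedding whose coordinates form a symmetric grid (closed-form checks)."""
    g = np.linspace(-1, 1, 5)
    xx, yy = np.meshgrid(g, g)
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    from mmdpath.kpca import KPCAEmbedding
    n = coords.shape[0]
    return KPCAEmbedding(
        coordinates=coords,
        eigenvalues=np.array([2.0, 1.0]),
        dual_coefficients=np.zeros((n, 2)),
        sample_ids=[f"s{i}" for i in range(n)],
    )


class TestVariableArrows:
    def test_constant_feature_gives_zero_vectors(self):
        emb = symmetric_grid_embedding()
        block = make_block(np.full((25, 1), 3.7))
        af = variable_arrows(emb, block, "f0", bandwidth=0.5)
        np.testing.assert_array_equal(af.raw_gradients, 0.0)
        np.testing.assert_array_equal(af.vectors, 0.0)

    def test_gradient_points_along_increasing_coordinate(self):
        emb = symmetric_grid_embedding()
        f = emb.coordinates[:, 0:1].copy()  # feature == first embedding axis
        af = variable_arrows(emb, make_block(f), "f0", bandwidth=0.6)
        assert np.all(af.raw_gradients[:, 0] > 0)
        np.testing.assert_allclose(af.raw_gradients[:, 1], 0.0, atol=1e-6)

    def test_sign_flip_linearity(self):
        emb = symmetric_grid_embedding()
        f = emb.coordinates[:, 0] + 0.5 * emb.coordinates[:, 1]
        a_pos = variable_arrows(emb, make_block(f[:, None]), "f0", bandwidth=0.5)
        a_neg = variable_arrows(emb, make_block(-f[:, None]), "f0", bandwidth=0.5)
        np.testing.assert_allclose(a_pos.raw_gradients, -a_neg.raw_gradients,
                                   atol=1e-12)

    def test_rotation_equivariance_with_isotropic_bandwidth(self, rng):
        from mmdpath.kpca import KPCAEmbedding
        coords = rng.standard_normal((20, 2))
        f = rng.standard_normal((20, 1))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        def emb_for(c):
            return KPCAEmbedding(c, np.array([2.0, 1.0]), np.zeros((20, 2)),
                                 [f"s{i}" for i in range(20)])
        a = variable_arrows(emb_for(coords), make_block(f), "f0", bandwidth=0.8)
        b = variable_arrows(emb_for(coords @ R.T), make_block(f), "f0",
                            bandwidth=0.8)
        np.testing.assert_allclose(b.raw_gradients, a.raw_gradients @ R.T,
                                   atol=1e-10)

    def test_zero_bandwidth_rejected(self):
        emb = symmetric_grid_embedding()
        with pytest.raises(ValueError, match="bandwidth"):
            variable_arrows(emb, make_block(np.zeros((25, 1))), "f0",
                            bandwidth=0.0)

    def test_silverman_bandwidths_positive(self, rng):
        h = silverman_bandwidths(rng.standard_normal((30, 2)))
        assert h.shape == (2,)
        assert np.all(h > 0)


class TestExportPlotData:
    def test_coordinates_round_trip_with_factor(self, rng, tmp_path):
        X = rng.standard_normal((8, 3))
        block = make_block(X)
        emb = kpca_embed(rbf_kernel(block), n_components=2)
        meta = SampleMetadata(block.sample_ids,
                              {"genotype": ["wt"] * 4 + ["ko"] * 4})
        arrows = [variable_arrows(emb, block, "f0")]
        written = export_plot_data(emb, tmp_path, arrows, meta)
        coords = pd.read_csv(written["coordinates"], sep="\t", index_col=0)
        assert list(coords.index) == block.sample_ids
        assert list(coords["genotype"]) == meta.factors["genotype"]
        np.testing.assert_allclose(coords[["PC1", "PC2"]].to_numpy(),
                                   emb.coordinates, atol=1e-6)
        means = pd.read_csv(written["arrow_means"], sep="\t")
        assert len(means) == 1

    def test_empty_arrow_list_exports_coordinates_only(self, rng, tmp_path):
        X = rng.standard_normal((6, 2))
        emb = kpca_embed(rbf_kernel(make_block(X)), n_components=2)
        written = export_plot_data(emb, tmp_path)
        assert "coordinates" in written and "arrows" not in written
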