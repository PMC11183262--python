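"""QC, normalization, PCA, clustering, markers, cell-cycle regression."""

import numpy as np
import pandas as pd
import pytest

from conftest import layer_adata, make_adata
from mammodev.preprocess import (
    AllCellsFilteredError,
    QCThresholds,
    cluster_cells,
    find_markers,
    normalize,
    pca_embedding,
    qc_filter,
    regress_cell_cycle,
)


def _toy_qc_matrix():
    """4 cells with UMIs (6000, 4000, 7000, 8000) and mito fractions
    (0.01, 0.01, 0.10, 0.02), built from one mt- gene plus one filler."""
    umis = np.array([6000, 4000, 7000, 8000])
    mito_frac = np.array([0.01, 0.01, 0.10, 0.02])
    mito = (umis * mito_frac).round().astype(int)
    counts = np.column_stack([mito, umis - mito])
    return make_adata(counts, genes=["mt-Nd1", "Actb"])


class TestQCFilter:
    def test_hand_thresholds_keep_cells_1_and_4(self):
        out = qc_filter(_toy_qc_matrix(), QCThresholds(min_cells_per_gene=0))
        assert list(out.obs_names) == ["c0", "c3"]

    def test_zero_thresholds_are_identity(self):
        a = _toy_qc_matrix()
        out = qc_filter(a, QCThresholds(min_umi=0, max_mito=1.0, min_cells_per_gene=0))
        assert out.shape == a.shape
        assert (out.X != a.X).nnz == 0

    def test_idempotent(self):
        t = QCThresholds(min_cells_per_gene=0)
        once = qc_filter(_toy_qc_matrix(), t)
        twice = qc_filter(once, t)
        assert list(twice.obs_names) == list(once.obs_names)
        assert (twice.X != once.X).nnz == 0

    def test_monotone_in_thresholds(self, small_lineage):
        adata, _ = small_lineage
        base = qc_filter(adata, QCThresholds())
        tighter = [
            QCThresholds(min_umi=8000),
            QCThresholds(max_mito=0.03),
            QCThresholds(min_cells_per_gene=10),
        ]
        for t in tighter:
            out = qc_filter(adata, t)
            assert out.n_obs <= base.n_obs
            assert out.n_vars <= base.n_vars

    def test_gene_filter_applied_after_cell_filter(self):
        # gene detected only in a cell that fails QC must be removed
        counts = np.array([[6000, 0], [1000, 50]])
        a = make_adata(counts, genes=["Actb", "RareGene"])
        out = qc_filter(a, QCThresholds(min_umi=5000, min_cells_per_gene=1))
        assert list(out.var_names) == ["Actb"]

    def test_all_filtered_raises_with_counts(self):
        a = _toy_qc_matrix()
        with pytest.raises(AllCellsFilteredError) as exc:
            qc_filter(a, QCThresholds(min_umi=10_000))
        assert exc.value.n_low_umi == 4

    def test_input_unmodified(self):
        a = _toy_qc_matrix()
        before = a.X.copy()
        qc_filter(a, QCThresholds(min_cells_per_gene=0))
        assert (a.X != before).nnz == 0 and "total_umi" not in a.obs


def _pearson_oracle(counts: np.ndarray, theta: float) -> np.ndarray:
    """Scalar Pearson-residual formula, independent of the implementation."""
    n, _ = counts.shape
    tot = counts.sum()
    cell = counts.sum(1, keepdims=True)
    gene = counts.sum(0, keepdims=True)
    mu = cell * gene / tot
    r = (counts - mu) / np.sqrt(mu + mu**2 / theta)
    return np.clip(r, -np.sqrt(n), np.sqrt(n))


class TestNormalize:
    def test_constant_proportion_gene_has_zero_residual(self):
        # gene takes exactly 10% of every cell's depth -> residual ~ 0
        depths = np.array([100, 200, 300, 400])
        counts = np.column_stack([depths // 10, depths - depths // 10])
        a = make_adata(counts)
        out = normalize(a, theta=1e12)  # Poisson limit
        assert np.abs(out.layers["pearson"][:, 0]).max() < 1e-6

    def test_matches_scalar_oracle(self):
        counts = np.array([[10, 90], [0, 100], [5, 120]])
        out = normalize(make_adata(counts), theta=100.0)
        np.testing.assert_allclose(
            out.layers["pearson"], _pearson_oracle(counts, 100.0), atol=1e-12
        )

    def test_residuals_clipped_at_sqrt_n(self, normalized_lineage):
        adata, _ = normalized_lineage
        assert np.abs(adata.layers["pearson"]).max() <= np.sqrt(adata.n_obs) + 1e-9

    def test_zero_depth_cell_rejected(self):
        a = make_adata(np.array([[0, 0], [5, 5]]))
        with pytest.raises(ValueError, match="zero-depth"):
            normalize(a)


class TestPCA:
    def test_rank_one_matrix_explained_by_pc1(self):
        rng = np.random.default_rng(0)
        u, v = rng.normal(size=(50, 1)), rng.normal(size=(1, 30))
        a = make_adata(np.zeros((50, 30), dtype=int))
        a.layers["pearson"] = u @ v
        a.var["pearson_residual_var"] = (u @ v).var(axis=0)
        out = pca_embedding(a, n_hvg=30, n_pcs=3)
        assert out.uns["pca"]["variance_ratio"][0] > 0.999

    def test_matches_eigendecomposition_oracle(self):
        X = np.array([[1.0, 2.0, 0.5], [0.2, 0.1, 1.5], [2.0, 0.3, 0.9]])
        a = make_adata(np.zeros((3, 3), dtype=int))
        a.layers["pearson"] = X
        a.var["pearson_residual_var"] = X.var(axis=0)
        out = pca_embedding(a, n_hvg=3, n_pcs=2)
        C = X - X.mean(0)
        w, V = np.linalg.eigh(C.T @ C)
        order = np.argsort(w)[::-1]
        V = V[:, order[:2]]
        for k in range(2):  # same sign convention as the implementation
            j = np.argmax(np.abs(V[:, k]))
            if V[j, k] < 0:
                V[:, k] *= -1
        np.testing.assert_allclose(out.obsm["X_pca"], C @ V, atol=1e-8)

    def test_sign_convention_consistent_under_global_flip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        scores = []
        for mat in (X, -X):
            a = make_adata(np.zeros((20, 6), dtype=int))
            a.layers["pearson"] = mat
            a.var["pearson_residual_var"] = mat.var(axis=0)
            scores.append(pca_embedding(a, n_hvg=6, n_pcs=2).obsm["X_pca"])
        # flipping the data flips the scores, with the convention re-applied
        np.testing.assert_allclose(np.abs(scores[0]), np.abs(scores[1]), atol=1e-8)

    def test_too_many_pcs_rejected(self):
        a = make_adata(np.zeros((5, 4), dtype=int))
        a.layers["pearson"] = np.random.default_rng(0).normal(size=(5, 4))
        a.var["pearson_residual_var"] = np.ones(4)
        with pytest.raises(ValueError, match="n_pcs"):
            pca_embedding(a, n_hvg=4, n_pcs=10)


class TestClusterCells:
    def test_two_separated_blobs_split_exactly(self):
        rng = np.random.default_rng(0)
        b1 = rng.normal(scale=0.1, size=(100, 15))
        b2 = rng.normal(scale=0.1, size=(100, 15))
        b2[:, 0] += 10
        labels = cluster_cells(np.vstack([b1, b2]), k_neighbors=20,
                               resolution=0.8, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:100])) == 1 and len(set(labels[100:])) == 1

    def test_one_blob_low_resolution_single_cluster(self):
        rng = np.random.default_rng(1)
        labels = cluster_cells(rng.normal(size=(150, 15)), resolution=0.1, seed=0)
        assert len(set(labels)) == 1

    def test_labels_are_consecutive_and_size_ordered(self):
        rng = np.random.default_rng(2)
        b1 = rng.normal(scale=0.1, size=(120, 10))
        b2 = rng.normal(scale=0.1, size=(60, 10))
        b2[:, 1] += 20
        labels = cluster_cells(np.vstack([b1, b2]), seed=0)
        sizes = np.bincount(labels)
        assert sorted(set(labels)) == list(range(len(sizes)))
        assert (np.diff(sizes) <= 0).all()

    def test_k_reduced_with_warning_for_few_cells(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="reducing"):
            labels = cluster_cells(rng.normal(size=(10, 3)), k_neighbors=20)
        assert len(labels) == 10

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 10))
        l1 = cluster_cells(X, seed=5)
        l2 = cluster_cells(X, seed=5)
        np.testing.assert_array_equal(l1, l2)


class TestFindMarkers:
    def _exclusive_gene_adata(self, n_side=25):
        rng = np.random.default_rng(0)
        base = rng.lognormal(size=(2 * n_side, 20))
        base[:n_side, 0] = 0.0  # gene g0 exclusive to cluster B
        return layer_adata(base), np.repeat([0, 1], n_side)

    def test_exclusive_gene_is_top_marker(self):
        adata, labels = self._exclusive_gene_adata()
        table = find_markers(adata, labels)
        top = table[table["cluster"] == 1].iloc[0]
        assert top["gene"] == "g0"
        assert top["adjusted_p"] < 0.05
        assert top["fraction_in_cluster"] == 1.0 and top["fraction_out"] == 0.0

    def test_identical_expression_gives_empty_table(self):
        vals = np.full((12, 15), 2.0)
        adata = layer_adata(vals)
        table = find_markers(adata, np.repeat([0, 1], 6))
        assert table.empty

    def test_low_detection_fraction_never_reported(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(size=(40, 10))
        vals[:20, 3] = 0.0
        vals[20, 3] = 50.0  # detected in 1/20 = 5% of cluster 1 cells
        vals[21:, 3] = 0.0
        adata = layer_adata(vals)
        table = find_markers(adata, np.repeat([0, 1], 20), min_fraction=0.10)
        assert "g3" not in set(table["gene"])

    def test_fractions_and_lfc_recomputable(self, normalized_lineage):
        adata, truth = normalized_lineage
        labels = (truth.cell_meta.loc[adata.obs_names, "branch"] == "basal").astype(int)
        table = find_markers(adata, labels.to_numpy())
        row = table.iloc[0]
        Y = adata.layers["lognorm"]
        mask = labels.to_numpy() == row["cluster"]
        j = adata.var_names.get_loc(row["gene"])
        assert row["fraction_in_cluster"] == pytest.approx((Y[mask, j] > 0).mean())
        lfc = np.log(np.expm1(Y[mask, j]).mean() + 1) - np.log(
            np.expm1(Y[~mask, j]).mean() + 1
        )
        assert row["log_fold_change"] == pytest.approx(lfc, rel=1e-12)

    def test_singleton_cluster_skipped(self):
        rng = np.random.default_rng(2)
        adata = layer_adata(rng.lognormal(size=(11, 12)))
        labels = np.array([0] * 10 + [1])
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = find_markers(adata, labels)
        assert set(table["cluster"]) <= {0}


class TestRegressCellCycle:
    def _cycle_adata(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        n_genes = 60
        vals = rng.lognormal(sigma=0.3, size=(n, n_genes))
        s_genes = [f"g{j}" for j in range(5)]
        g2m_genes = [f"g{j}" for j in range(5, 10)]
        # drive the S genes with a strong shared factor
        s_factor = rng.normal(size=n)
        vals[:, :5] += 2.0 * s_factor[:, None]
        # target gene depends linearly on the S program
        vals[:, 20] = 2.0 * s_factor + rng.normal(scale=0.1, size=n)
        return layer_adata(vals), s_genes, g2m_genes

    def test_corrected_layer_uncorrelated_with_s_score(self):
        adata, s_genes, g2m_genes = self._cycle_adata()
        out = regress_cell_cycle(adata, s_genes, g2m_genes)
        s = out.obs["S_score"].to_numpy()
        corrected = out.layers["corrected"][:, 20]
        assert abs(np.corrcoef(s, corrected)[0, 1]) < 0.05

    def test_matches_normal_equations_oracle(self):
        adata, s_genes, g2m_genes = self._cycle_adata(n=80, seed=1)
        out = regress_cell_cycle(adata, s_genes, g2m_genes)
        Y = out.layers["lognorm"]
        D = np.column_stack(
            [np.ones(80), out.obs["S_score"], out.obs["G2M_score"]]
        )
        beta = np.linalg.solve(D.T @ D, D.T @ Y)
        np.testing.assert_allclose(
            out.layers["corrected"], Y - D[:, 1:] @ beta[1:], atol=1e-10
        )

    def test_empty_gene_list_rejected(self):
        adata, s_genes, _ = self._cycle_adata(n=20, seed=2)
        with pytest.raises(ValueError, match="non-empty"):
            regress_cell_cycle(adata, s_genes, [])
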