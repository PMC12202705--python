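"""Pearson residuals, z-scores, membership scores, centroid distances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from melanokit import scoring
from melanokit.errors import ParameterError
from melanokit.scoring import (
    CountMatrix,
    NoiseModel,
    cluster_centroid_distances,
    estimate_cv,
    membership_score,
    pearson_residuals,
    standardize_residuals,
)


def toy_matrix():
    x = np.array([[4, 1, 0], [2, 3, 5], [0, 2, 6]], dtype=float)
    return CountMatrix(genes=["ga", "gb", "gc"], cells=["c1", "c2", "c3"], x=x)


class TestPearsonResiduals:
    def test_matches_brute_force_formula_on_toy_matrix(self):
        # independent oracle: explicit per-entry loops over the NB residual
        cm = toy_matrix()
        model = NoiseModel(cv=0.55)
        rm = pearson_residuals(cm, model)
        x = cm.dense()
        grand = x.sum()
        theta = 1.0 / 0.55**2
        clip = math.sqrt(3)
        for g in range(3):
            for c in range(3):
                mu = x[g].sum() * x[:, c].sum() / grand
                expected = (x[g, c] - mu) / math.sqrt(mu + mu**2 / theta)
                expected = max(-clip, min(clip, expected))
                assert rm.residuals[g, c] == pytest.approx(expected, rel=1e-12)

    def test_exactly_expected_counts_give_zero_residuals(self):
        # rank-one matrix: x_gc = row_g * col_c / grand holds exactly
        x = np.outer([1, 2, 4.0], [8, 4, 2, 2.0])
        cm = CountMatrix(genes=list("abc"), cells=list("wxyz"), x=x)
        rm = pearson_residuals(cm, NoiseModel(cv=0.55))
        assert np.allclose(rm.residuals, 0.0, atol=1e-12)

    def test_matches_scanpy_analytic_residuals(self, null_counts):
        sc = pytest.importorskip("scanpy")
        import anndata

        spec, cm, _ = null_counts
        model = NoiseModel(cv=0.55)
        rm = pearson_residuals(cm, model)
        adata = anndata.AnnData(X=sparse.csr_matrix(cm.dense().T))
        out = sc.experimental.pp.normalize_pearson_residuals(
            adata, theta=model.theta, inplace=False
        )
        np.testing.assert_allclose(rm.residuals, np.asarray(out["X"]).T, rtol=1e-6, atol=1e-6)

    def test_zero_total_genes_removed_with_warning(self, caplog):
        x = np.array([[0, 0, 0], [1, 2, 3], [3, 2, 1.0]])
        cm = CountMatrix(genes=list("abc"), cells=list("xyz"), x=x)
        with caplog.at_level("WARNING"):
            rm = pearson_residuals(cm, NoiseModel(cv=0.5))
        assert rm.genes == ["b", "c"]
        assert "zero total" in caplog.text

    def test_all_zero_matrix_rejected(self):
        cm = CountMatrix(genes=list("ab"), cells=list("xy"), x=np.zeros((2, 2)))
        with pytest.raises(ParameterError, match="all-zero"):
            pearson_residuals(cm, NoiseModel(cv=0.5))

    def test_invalid_cv_rejected(self):
        with pytest.raises(ParameterError):
            NoiseModel(cv=0.0)

    def test_sparse_and_dense_inputs_agree(self, null_counts):
        _, cm, _ = null_counts
        dense = CountMatrix(genes=cm.genes, cells=cm.cells, x=cm.dense())
        a = pearson_residuals(cm, NoiseModel(cv=0.55)).residuals
        b = pearson_residuals(dense, NoiseModel(cv=0.55)).residuals
        np.testing.assert_array_equal(a, b)

    def test_clipping_bound_enforced(self, planted_counts):
        _, cm, _, _ = planted_counts
        rm = pearson_residuals(cm, NoiseModel(cv=0.55))
        assert np.abs(rm.residuals).max() <= math.sqrt(len(cm.cells)) + 1e-12

    def test_depth_shift_keeps_scores_finite(self):
        x = np.random.default_rng(0).poisson(3.0, size=(20, 10)).astype(float)
        x[:, 0] += 50  # one cell much deeper than the rest
        cm = CountMatrix(genes=[f"g{i}" for i in range(20)], cells=[f"c{i}" for i in range(10)], x=x)
        z = standardize_residuals(pearson_residuals(cm, NoiseModel(cv=0.55)))
        scores = membership_score(z, [f"g{i}" for i in range(5)]).scores
        assert np.isfinite(scores).all()


class TestStandardize:
    def test_hand_computed_z_scores_with_sample_sd(self):
        rm = scoring.ResidualMatrix(
            genes=["a", "b"], cells=["x", "y", "z"],
            residuals=np.array([[-1.0, 0.0, 1.0], [2.0, 4.0, 6.0]]),
            expected=np.ones((2, 3)),
        )
        z = standardize_residuals(rm)
        np.testing.assert_allclose(z.loc["a"], [-1.0, 0.0, 1.0])  # sd(ddof=1)=1
        np.testing.assert_allclose(z.loc["b"], [-1.0, 0.0, 1.0])

    def test_per_gene_means_vanish_and_sds_are_one(self, null_counts):
        _, cm, _ = null_counts
        z = standardize_residuals(pearson_residuals(cm, NoiseModel(cv=0.55)))
        assert np.abs(z.mean(axis=1)).max() < 1e-10
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, rtol=1e-10)

    def test_constant_residual_gene_dropped_with_warning(self, caplog):
        rm = scoring.ResidualMatrix(
            genes=["flat", "ok"], cells=["x", "y", "z"],
            residuals=np.array([[0.5, 0.5, 0.5], [1.0, 2.0, 3.0]]),
            expected=np.ones((2, 3)),
        )
        with caplog.at_level("WARNING"):
            z = standardize_residuals(rm)
        assert list(z.index) == ["ok"] and "zero-variance" in caplog.text


class TestMembershipScore:
    def test_single_gene_signature_equals_that_genes_z_row(self, null_counts):
        _, cm, _ = null_counts
        z = standardize_residuals(pearson_residuals(cm, NoiseModel(cv=0.55)))
        ms = membership_score(z, [z.index[0]])
        np.testing.assert_allclose(ms.scores, z.iloc[0])

    def test_case_insensitive_matching_and_missing_report(self, null_counts):
        _, cm, _ = null_counts
        z = standardize_residuals(pearson_residuals(cm, NoiseModel(cv=0.55)))
        ms = membership_score(z, [z.index[0].upper(), "NOT_A_GENE"])
        assert ms.n_genes_used == 1 and ms.genes_missing == ("NOT_A_GENE",)

    def test_symbol_map_translates_identifiers(self, null_counts):
        _, cm, _ = null_counts
        z = standardize_residuals(pearson_residuals(cm, NoiseModel(cv=0.55)))
        ms = membership_score(z, ["HUMAN1"], symbol_map={"HUMAN1": z.index[3]})
        np.testing.assert_allclose(ms.scores, z.iloc[3])

    def test_disjoint_signature_rejected_listing_missing(self, null_counts):
        _, cm, _ = null_counts
        z = standardize_residuals(pearson_residuals(cm, NoiseModel(cv=0.55)))
        with pytest.raises(ParameterError, match="NOPE"):
            membership_score(z, ["NOPE"])

    def test_scores_invariant_to_gene_and_cell_permutation(self, planted_counts):
        spec, cm, _, sig = planted_counts
        model = NoiseModel(cv=0.55)
        base = scoring.score_signatures(cm, {"s": list(sig.genes)}, model)["s"]
        rng = np.random.default_rng(0)
        gperm = rng.permutation(len(cm.genes))
        cperm = rng.permutation(len(cm.cells))
        permuted = CountMatrix(
            genes=[cm.genes[i] for i in gperm],
            cells=[cm.cells[j] for j in cperm],
            x=cm.dense()[np.ix_(gperm, cperm)],
        )
        shuffled_sig = [sig.genes[i] for i in rng.permutation(len(sig.genes))]
        out = scoring.score_signatures(permuted, {"s": shuffled_sig}, model)["s"]
        np.testing.assert_allclose(out.loc[base.index], base, rtol=1e-9)

    def test_planted_cells_score_above_background(self, planted_counts):
        from conftest import auc

        spec, cm, truth, sig = planted_counts
        scores = scoring.score_signatures(cm, {"s": list(sig.genes)}, NoiseModel(cv=0.55))["s"]
        positive = np.array([t == "planted" for t in truth.cell_types])
        assert auc(scores.to_numpy(), positive) > 0.9


class TestCentroidDistances:
    def test_three_four_five_triangle(self):
        coords = np.array([[0, 0], [0, 0], [3, 4], [3, 4.0]])
        d = cluster_centroid_distances(coords, ["a", "a", "b", "b"])
        assert d.loc["a", "b"] == pytest.approx(5.0)
        assert d.loc["a", "a"] == 0.0

    def test_identical_centroids_give_zero_distance(self):
        coords = np.array([[1, 2], [3, 4], [1, 2], [3, 4.0]])
        d = cluster_centroid_distances(coords, ["a", "a", "b", "b"])
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_known_centroid_geometry_with_noise(self):
        # generator truth: clusters drawn around centroids (0,0), (6,0), (0,8)
        rng = np.random.default_rng(12)
        centroids = {"a": (0.0, 0.0), "b": (6.0, 0.0), "c": (0.0, 8.0)}
        pts, labels = [], []
        for name, mu in centroids.items():
            pts.append(rng.normal(mu, 0.05, size=(400, 2)))
            labels += [name] * 400
        d = cluster_centroid_distances(np.vstack(pts), labels)
        assert d.loc["a", "b"] == pytest.approx(6.0, abs=0.05)
        assert d.loc["a", "c"] == pytest.approx(8.0, abs=0.05)
        assert d.loc["b", "c"] == pytest.approx(10.0, abs=0.05)

    def test_symmetry_zero_diagonal_triangle_inequality(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(60, 10))
        labels = rng.choice(list("abcd"), size=60)
        d = cluster_centroid_distances(coords, labels, n_dims=10).to_numpy()
        np.testing.assert_allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_leading_dimension_subsetting(self):
        coords = np.array([[0, 100], [0, 100], [3, -100], [3, -100.0]])
        d = cluster_centroid_distances(coords, ["a", "a", "b", "b"], n_dims=1)
        assert d.loc["a", "b"] == pytest.approx(3.0)

    def test_fewer_than_two_clusters_rejected(self):
        with pytest.raises(ParameterError, match="2 non-empty"):
            cluster_centroid_distances(np.zeros((3, 2)), ["a", "a", "a"])


class TestCVEstimator:
    def test_recovers_generating_cv(self, null_counts):
        _, cm, _ = null_counts
        assert estimate_cv(cm) == pytest.approx(0.55, rel=0.2)
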