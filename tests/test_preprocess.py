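"""Filtering, normalization, HVG selection, regression, scaling, PCA, recipe."""

import numpy as np
import pytest
import scipy.sparse as sp

import annmat as am


class TestFilterAxis:
    def test_cells_by_min_counts(self):
        a = am.AnnMatrix(np.array([[5.0, 0], [0, 0], [1, 1]]))
        out, report = am.filter_axis(a, "obs", min_counts=1)
        assert out.n_obs == 2 and report["removed"] == ["obs1"]

    def test_genes_by_min_entities(self):
        # gene1 detected in 1 of 3 cells, gene0 in two
        X = np.array([[1.0, 1.0], [2.0, 0], [0, 0]])
        out, report = am.filter_axis(am.AnnMatrix(X), "var", min_entities=2)
        assert out.n_var == 1 and report["removed"] == ["var1"]

    def test_requires_a_threshold(self, small_ann):
        with pytest.raises(ValueError, match="at least one"):
            am.filter_axis(small_ann, "obs")

    def test_removing_everything_errors(self):
        a = am.AnnMatrix(np.ones((2, 2)))
        with pytest.raises(ValueError, match="threshold"):
            am.filter_axis(a, "obs", min_counts=100)


class TestNormalizeTotal:
    def test_explicit_target(self):
        a = am.normalize_total(am.AnnMatrix(np.array([[1.0, 3.0]])), target_sum=10)
        np.testing.assert_allclose(a.X, [[2.5, 7.5]])

    def test_default_target_is_median_row_sum(self):
        a = am.AnnMatrix(np.array([[2.0, 0], [0, 4.0], [3.0, 3.0]]))
        am.normalize_total(a)
        np.testing.assert_allclose(np.asarray(a.X).sum(axis=1), [4, 4, 4])

    def test_zero_row_unchanged_with_warning(self):
        a = am.AnnMatrix(np.array([[1.0, 1.0], [0.0, 0.0]]))
        with pytest.warns(UserWarning, match="zero-count"):
            am.normalize_total(a, target_sum=4)
        np.testing.assert_allclose(np.asarray(a.X)[1], [0, 0])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            am.normalize_total(am.AnnMatrix(np.array([[-1.0, 2.0]])))

    def test_row_sums_property_sparse(self, small_ann):
        am.normalize_total(small_ann, target_sum=100)
        sums = np.asarray(small_ann.X.sum(axis=1)).ravel()
        nz = sums > 0
        np.testing.assert_allclose(sums[nz], 100, rtol=1e-8)


class TestLog1p:
    def test_values_and_sparsity(self):
        X = sp.csr_matrix(np.array([[0.0, np.e - 1], [0, 3]]))
        a = am.log1p(am.AnnMatrix(X))
        assert a.X.nnz == 2
        np.testing.assert_allclose(a.X.toarray(), [[0, 1], [0, np.log(4)]])
        assert a.uns["log1p"] is True

    def test_idempotence_guard(self):
        a = am.log1p(am.AnnMatrix(np.ones((2, 2))))
        before = np.asarray(a.X).copy()
        with pytest.warns(UserWarning, match="already"):
            am.log1p(a)
        np.testing.assert_array_equal(np.asarray(a.X), before)


def brute_force_hvg_z(X, n_bins, flavor):
    """Independent spreadsheet-style recomputation of binned dispersion z."""
    n, g = X.shape
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1), 0.0)
    order = np.argsort(mean, kind="stable")
    z = np.zeros(g)
    bins = np.array_split(order, n_bins)
    for members in bins:
        d = disp[members]
        if flavor == "meanstd":
            center, scale = d.mean(), (d.std(ddof=1) if d.size > 1 else 0.0)
        else:
            center = np.median(d)
            scale = 1.4826 * np.median(np.abs(d - center))
        z[members] = (d - center) / scale if scale > 0 and d.size > 1 else 0.0
    return z


class TestHighlyVariableGenes:
    @pytest.mark.parametrize("flavor", ["meanstd", "medianmad"])
    def test_matches_bruteforce_recomputation(self, rng, flavor):
        X = rng.gamma(2.0, 2.0, size=(40, 6))
        res = am.highly_variable_genes(am.AnnMatrix(X), n_top=3, n_bins=2, flavor=flavor)
        expected = brute_force_hvg_z(X, 2, flavor)
        np.testing.assert_allclose(res.dispersions_norm, expected, atol=1e-12)
        assert res.highly_variable.sum() == 3
        # selection equivalent up to exact ties in z
        sel_z = np.sort(expected[res.highly_variable])
        top_z = np.sort(expected)[-3:]
        np.testing.assert_allclose(sel_z, top_z, atol=1e-9)

    def test_constant_gene_never_selected(self, rng):
        X = rng.gamma(2.0, 2.0, size=(30, 5))
        X[:, 2] = 3.0  # constant, dispersion 0
        res = am.highly_variable_genes(am.AnnMatrix(X), n_top=4, n_bins=2)
        assert res.dispersions[2] == 0
        assert not res.highly_variable[2]

    def test_n_top_equals_n_var_flags_all(self, rng):
        X = rng.gamma(2.0, 2.0, size=(10, 5))
        res = am.highly_variable_genes(am.AnnMatrix(X), n_top=5)
        assert res.highly_variable.all()

    def test_n_top_too_large(self, small_ann):
        with pytest.raises(ValueError, match="n_top"):
            am.highly_variable_genes(small_ann, n_top=99)

    def test_permutation_equivariance(self, rng):
        X = rng.gamma(2.0, 2.0, size=(30, 12))
        perm = rng.permutation(12)
        r1 = am.highly_variable_genes(am.AnnMatrix(X), n_top=4, n_bins=3)
        r2 = am.highly_variable_genes(am.AnnMatrix(X[:, perm]), n_top=4, n_bins=3)
        np.testing.assert_array_equal(r1.highly_variable[perm], r2.highly_variable)


class TestRegressOut:
    def test_constant_covariate_centers(self, rng):
        X = rng.random((10, 3))
        a = am.AnnMatrix(X.copy(), obs={"c": np.ones(10)})
        with pytest.warns(UserWarning, match="collinear"):
            am.regress_out(a, ["c"])
        np.testing.assert_allclose(np.asarray(a.X), X - X.mean(axis=0), atol=1e-10)

    def test_exactly_linear_gene_vanishes(self, rng):
        cov = rng.random(15)
        X = np.outer(cov, [2.0, -1.0]) + 3.0
        a = am.AnnMatrix(X, obs={"c": cov})
        am.regress_out(a, ["c"])
        assert np.abs(np.asarray(a.X)).max() < 1e-10

    def test_residuals_orthogonal_to_covariates(self, rng):
        X = rng.random((30, 5))
        cov = {"u": rng.random(30), "v": rng.random(30)}
        a = am.AnnMatrix(X, obs=cov)
        am.regress_out(a, ["u", "v"])
        R = np.asarray(a.X)
        assert np.abs(R.mean(axis=0)).max() < 1e-8
        for c in cov.values():
            assert np.abs(c @ R).max() < 1e-8

    def test_missing_column(self, small_ann):
        with pytest.raises(KeyError, match="nope"):
            am.regress_out(small_ann, ["nope"])


class TestScaleClip:
    def test_unit_variance_and_constant_column(self):
        a = am.AnnMatrix(np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]]))
        am.scale_clip(a)
        np.testing.assert_allclose(np.asarray(a.X)[:, 0], [-1, 0, 1])
        np.testing.assert_allclose(np.asarray(a.X)[:, 1], 0)

    def test_clipping_symmetric(self, rng):
        # a single outlier among 200 cells standardizes to ~sqrt(199) > 10
        X = rng.random((200, 2))
        X[0, 0] = 1e6
        a = am.scale_clip(am.AnnMatrix(X), max_value=10)
        out = np.asarray(a.X)
        assert out.max() <= 10 and out.min() >= -10 and out[0, 0] == 10

    def test_mean_zero_std_one_property(self, rng):
        a = am.scale_clip(am.AnnMatrix(rng.random((50, 8))))
        out = np.asarray(a.X)
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1, rtol=1e-10)


class TestPca:
    def test_collinear_points(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t])
        res = am.pca(am.AnnMatrix(X), n_comps=2)
        np.testing.assert_allclose(res.explained_variance_ratio, [1, 0], atol=1e-12)

    def test_full_rank_reconstruction(self, rng):
        X = rng.random((15, 6))
        res = am.pca(am.AnnMatrix(X), n_comps=6)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(res.scores @ res.components.T, Xc, atol=1e-8)

    def test_deterministic_and_orthogonal_scores(self, rng):
        X = sp.csr_matrix(rng.random((40, 8)))
        a = am.AnnMatrix(X)
        r1 = am.pca(a, n_comps=4, seed=7)
        r2 = am.pca(a, n_comps=4, seed=7)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        C = np.cov(r1.scores, rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(C)).max()
        # loadings orthonormal, ratios sorted
        np.testing.assert_allclose(r1.components.T @ r1.components, np.eye(4), atol=1e-10)
        assert (np.diff(r1.explained_variance_ratio) <= 1e-12).all()

    def test_n_comps_bounds(self, small_ann):
        with pytest.raises(ValueError, match="n_comps"):
            am.pca(small_ann, n_comps=11)


class TestRecipe:
    def test_shape_log_and_manual_chain(self):
        a = am.generate_mixture(n_cells=200, n_genes=500, n_clusters=3,
                                separation=8.0, seed=0)
        out = am.recipe_benchmark(a.copy(), n_top_genes=100)
        assert out.shape[1] == 100 and out.shape[0] <= 200
        assert len(out.uns["recipe_log"]) == 7

        b, _ = am.filter_axis(a.copy(), "obs", min_counts=1)
        b = am.normalize_total(b)
        hvg = am.highly_variable_genes(b, n_top=100, flavor="medianmad")
        b = b[:, hvg.highly_variable]
        b._materialize()
        b = am.normalize_total(b)
        b = am.log1p(b)
        b = am.scale_clip(b, max_value=10)
        np.testing.assert_allclose(np.asarray(out.X), np.asarray(b.X), atol=1e-12)
        assert list(out.var_names) == list(b.var_names)
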