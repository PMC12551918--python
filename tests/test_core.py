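"""Standardization, canonical transform, ridge fitting and the MSE formulas."""

import numpy as np
import pytest
import statsmodels.api as sm

import ridgepen as rp
from ridgepen.core import CanonicalFit

from conftest import make_correlated_dataset


class TestStandardize:
    def test_unit_norm_centered_column_is_unchanged(self):
        n = 16
        col = np.arange(n, dtype=float)
        col -= col.mean()
        col /= np.linalg.norm(col)
        ds = rp.Dataset(predictors=col.reshape(-1, 1), response=np.arange(n, dtype=float))
        design = rp.standardize(ds)
        np.testing.assert_allclose(design.Xstar[:, 0], col, atol=1e-14)
        np.testing.assert_allclose(design.column_scales, [1.0], atol=1e-12)

    def test_cross_product_reproduces_known_correlation(self, rng):
        # construct two columns with sample correlation exactly 0.9
        n = 25
        u = rng.standard_normal(n)
        u -= u.mean()
        u /= np.linalg.norm(u)
        v = rng.standard_normal(n)
        v -= v.mean()
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        x2 = 0.9 * u + np.sqrt(1 - 0.81) * v
        ds = rp.Dataset(
            predictors=np.column_stack([u, x2]), response=rng.standard_normal(n)
        )
        S = rp.standardize(ds).Xstar
        np.testing.assert_allclose((S.T @ S)[0, 1], 0.9, atol=1e-12)

    def test_cross_product_equals_correlation_oracle(self, rng):
        X = rng.standard_normal((20, 4)) * [1.0, 5.0, 0.2, 30.0] + [0, 3, -2, 100]
        ds = rp.Dataset(predictors=X, response=rng.standard_normal(20))
        S = rp.standardize(ds).Xstar
        np.testing.assert_allclose(S.T @ S, np.corrcoef(X, rowvar=False), atol=1e-10)
        assert np.abs(S.sum(axis=0)).max() < 1e-10
        np.testing.assert_allclose(np.linalg.norm(S, axis=0), 1.0, atol=1e-12)

    def test_constant_column_error_names_column(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 7.0
        ds = rp.Dataset(
            predictors=X, response=rng.standard_normal(10), column_names=["a", "b", "c"]
        )
        with pytest.raises(ValueError, match="'b'"):
            rp.standardize(ds)

    def test_underdetermined_error(self, rng):
        ds = rp.Dataset(predictors=rng.standard_normal((4, 5)), response=np.arange(4.0))
        with pytest.raises(ValueError, match="underdetermined"):
            rp.standardize(ds)


class TestCanonicalTransform:
    def test_orthogonal_predictors_decouple(self, rng):
        # orthonormalize centered columns -> identity correlation
        X = rng.standard_normal((20, 3))
        X -= X.mean(axis=0)
        Q, _ = np.linalg.qr(X)
        y = rng.standard_normal(20)
        ds = rp.Dataset(predictors=Q, response=y)
        design = rp.standardize(ds)
        canonical = rp.canonical_transform(design)
        np.testing.assert_allclose(canonical.lambdas, 1.0, atol=1e-10)
        # with identity correlation, alpha equals per-column simple slopes of E'X*'y
        slopes = design.Xstar.T @ design.y_centered
        np.testing.assert_allclose(
            canonical.E @ canonical.alpha_ols, slopes, atol=1e-10
        )

    def test_noiseless_response_recovered(self, toy_dataset):
        design = rp.standardize(toy_dataset)
        c = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        ds = rp.Dataset(
            predictors=toy_dataset.predictors, response=design.Xstar @ c + 5.0
        )
        canonical = rp.canonical_transform(rp.standardize(ds))
        assert canonical.sigma2_hat < 1e-20
        np.testing.assert_allclose(
            canonical.alpha_ols, canonical.E.T @ c, atol=1e-8
        )

    def test_eigenstructure_invariants(self, toy_pipeline):
        _, design, canonical = toy_pipeline
        p = design.p
        np.testing.assert_allclose(
            canonical.E.T @ canonical.E, np.eye(p), atol=1e-10
        )
        np.testing.assert_allclose(
            canonical.Z.T @ canonical.Z, np.diag(canonical.lambdas), atol=1e-10
        )
        assert abs(canonical.lambdas.sum() - p) < 1e-10
        assert np.all(np.diff(canonical.lambdas) <= 1e-12)

    def test_ols_oracle_roundtrip(self, rng):
        """Back-transformed canonical OLS equals a direct least-squares fit."""
        ds = make_correlated_dataset(rng, n=30, p=5)
        design = rp.standardize(ds)
        canonical = rp.canonical_transform(design)
        fit = rp.fit_ridge(canonical, design, 0.0)
        oracle = sm.OLS(ds.response, sm.add_constant(ds.predictors)).fit()
        np.testing.assert_allclose(fit.intercept, oracle.params[0], atol=1e-8)
        np.testing.assert_allclose(fit.beta_original, oracle.params[1:], atol=1e-8)
        # residual variance uses divisor n - p (slopes only), so compare RSS
        np.testing.assert_allclose(
            fit.sigma2_hat * (ds.n - ds.p), oracle.ssr, rtol=1e-10
        )

    def test_singular_design_error(self, rng):
        X = rng.standard_normal((12, 2))
        X = np.column_stack([X, X[:, 0] + 2 * X[:, 1]])
        ds = rp.Dataset(predictors=X, response=rng.standard_normal(12))
        with pytest.raises(ValueError, match="singular design"):
            rp.canonical_transform(rp.standardize(ds))


class TestFitRidge:
    def test_k_zero_is_ols_fieldwise(self, toy_pipeline):
        _, design, canonical = toy_pipeline
        fit = rp.fit_ridge(canonical, design, 0.0)
        np.testing.assert_array_equal(fit.alpha_ridge, canonical.alpha_ols)
        np.testing.assert_allclose(fit.sigma2_hat, canonical.sigma2_hat, rtol=1e-12)

    def test_full_shrinkage_limit(self, toy_pipeline):
        ds, design, canonical = toy_pipeline
        fit = rp.fit_ridge(canonical, design, 1e12)
        assert np.abs(fit.beta_original).max() < 1e-9
        np.testing.assert_allclose(fit.intercept, ds.response.mean(), atol=1e-8)

    @pytest.mark.parametrize("k", [0.0, 1.0])
    def test_primal_form_oracle(self, toy_pipeline, k):
        _, design, canonical = toy_pipeline
        fit = rp.fit_ridge(canonical, design, k)
        S = design.Xstar.T @ design.Xstar + k * np.eye(design.p)
        oracle = np.linalg.solve(S, design.Xstar.T @ design.y_centered)
        np.testing.assert_allclose(fit.beta_scaled, oracle, atol=1e-8)

    def test_negative_k_rejected(self, toy_pipeline):
        _, design, canonical = toy_pipeline
        with pytest.raises(ValueError, match="nonnegative"):
            rp.fit_ridge(canonical, design, -0.1)

    def test_alpha_norm_strictly_decreasing_in_k(self, toy_pipeline):
        _, design, canonical = toy_pipeline
        norms = [
            np.linalg.norm(rp.fit_ridge(canonical, design, k).alpha_ridge)
            for k in [0.0, 0.1, 0.5, 1.0, 5.0, 50.0]
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[0] <= np.linalg.norm(canonical.alpha_ols) + 1e-15

    def test_prediction_invariance_at_k_zero(self, toy_pipeline):
        ds, design, canonical = toy_pipeline
        fit = rp.fit_ridge(canonical, design, 0.0)
        # canonical-coordinate fitted values: ybar + Z alpha
        canon_fitted = design.y_mean + canonical.Z @ canonical.alpha_ols
        np.testing.assert_allclose(fit.fitted, canon_fitted, atol=1e-8)
        direct = fit.intercept + ds.predictors @ fit.beta_original
        np.testing.assert_allclose(fit.fitted, direct, atol=1e-8)


class TestTheoreticalMSE:
    def _canonical(self, lambdas, alpha, sigma2):
        p = len(lambdas)
        return CanonicalFit(
            E=np.eye(p),
            lambdas=np.asarray(lambdas, dtype=float),
            Z=np.zeros((p + 1, p)),
            alpha_ols=np.asarray(alpha, dtype=float),
            sigma2_hat=float(sigma2),
            df_resid=1,
        )

    def test_k_zero_equals_ols_formula_exactly(self, toy_pipeline):
        _, _, canonical = toy_pipeline
        assert rp.mse_theoretical(canonical, 0.0) == rp.mse_ols(canonical)

    def test_large_k_limit_is_pure_squared_bias(self):
        c = self._canonical([2.0, 1.0], [1.0, -3.0], 1.0)
        val = rp.mse_theoretical(c, 1e14)
        np.testing.assert_allclose(val, 10.0, rtol=1e-6)

    def test_hand_evaluated_fixture(self):
        # lambdas (2, 1), alpha (1, 1), sigma2 1, k 1:
        # variance 2/9 + 1/4, bias 1/9 + 1/4 -> 5/6
        c = self._canonical([2.0, 1.0], [1.0, 1.0], 1.0)
        np.testing.assert_allclose(rp.mse_theoretical(c, 1.0), 5.0 / 6.0, rtol=1e-14)

    def test_continuity_in_k(self, toy_pipeline):
        _, _, canonical = toy_pipeline
        def max_jump(n_points):
            ks = np.linspace(0.0, 5.0, n_points)
            vals = np.array([rp.mse_theoretical(canonical, k) for k in ks])
            return np.abs(np.diff(vals)).max()

        # halving the grid step roughly halves the largest increment,
        # as it must for a continuously differentiable function
        coarse, fine = max_jump(1000), max_jump(2000)
        assert fine < 0.75 * coarse

    def test_negative_k_rejected(self, toy_pipeline):
        _, _, canonical = toy_pipeline
        with pytest.raises(ValueError):
            rp.mse_theoretical(canonical, -1.0)
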