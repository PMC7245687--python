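"""Standardization, canonical form, base fits and the shrinkage operator."""

import numpy as np
import pytest
import statsmodels.api as sm

import robustridge as rr
from robustridge.core import huber_psi

from conftest import make_dataset


class TestStandardize:
    def test_single_column_example(self):
        data = rr.standardize_design(np.array([[1.0], [2.0], [3.0]]),
                                     np.zeros(3))
        np.testing.assert_allclose(
            data.X[:, 0], [-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)], atol=1e-12)
        np.testing.assert_allclose(data.y, 0.0, atol=1e-12)

    def test_postconditions(self, rng):
        X = rng.normal(2.0, 5.0, size=(25, 3))
        y = rng.normal(size=25)
        data = rr.standardize_design(X, y)
        np.testing.assert_allclose(data.X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(data.X, axis=0), 1.0, atol=1e-10)
        assert abs(data.y.mean()) < 1e-10

    def test_round_trip(self, rng):
        X = rng.normal(size=(20, 3)) * np.array([1.0, 10.0, 0.1]) + 7.0
        data = rr.standardize_design(X, rng.normal(size=20))
        X_back = data.X * data.column_scales + data.column_centers
        np.testing.assert_allclose(X_back, X, atol=1e-10)

    @pytest.mark.parametrize("bad, msg", [
        (np.ones((10, 1)), "zero-variance"),
        (np.arange(6.0).reshape(2, 3), "underdetermined"),
    ])
    def test_errors(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            rr.standardize_design(bad, np.zeros(bad.shape[0]))

    def test_singular_design_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        X = np.column_stack([X, X[:, 0] - X[:, 1]])
        with pytest.raises(ValueError, match="singular"):
            rr.standardize_design(X, rng.normal(size=20))


class TestCanonical:
    def test_known_diagonal_gram(self):
        # X'X = diag(2, 1)
        X = np.array([[np.sqrt(2), 0.0], [0.0, 1.0], [0.0, 0.0]])
        data = rr.RegressionData(X=X, y=np.zeros(3), n=3, p=2, standardized=False)
        cf = rr.canonical_decompose(data)
        np.testing.assert_allclose(cf.lambdas, [2.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(cf.T, np.eye(2), atol=1e-12)

    def test_orthonormal_columns_unit_eigenvalues(self):
        Q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(12, 3)))
        data = rr.RegressionData(X=Q, y=np.zeros(12), n=12, p=3, standardized=False)
        cf = rr.canonical_decompose(data)
        np.testing.assert_allclose(cf.lambdas, 1.0, atol=1e-10)

    def test_rotated_design_is_orthogonal(self, dataset):
        cf = rr.canonical_decompose(dataset)
        np.testing.assert_allclose(cf.Z.T @ cf.Z, np.diag(cf.lambdas), atol=1e-8)
        np.testing.assert_allclose(cf.T.T @ cf.T, np.eye(dataset.p), atol=1e-10)
        assert np.all(np.diff(cf.lambdas) <= 1e-12)

    def test_sign_convention(self, dataset):
        cf = rr.canonical_decompose(dataset)
        for j in range(dataset.p):
            col = cf.T[:, j]
            nz = np.nonzero(np.abs(col) > 1e-12)[0]
            assert col[nz[0]] > 0


class TestOLS:
    def test_noiseless_recovery(self, rng):
        data = make_dataset(rng, sigma=0.0, beta=np.array([1.0, -2.0, 0.5, 3.0]))
        cf = rr.canonical_decompose(data)
        fit = rr.fit_ols(cf, data.y)
        np.testing.assert_allclose(data.X @ fit.beta_hat, data.y, atol=1e-10)

    def test_matches_normal_equations_oracle(self, dataset):
        cf = rr.canonical_decompose(dataset)
        fit = rr.fit_ols(cf, dataset.y)
        beta_direct = np.linalg.solve(dataset.X.T @ dataset.X,
                                      dataset.X.T @ dataset.y)
        np.testing.assert_allclose(fit.beta_hat, beta_direct, atol=1e-10)
        np.testing.assert_allclose(cf.T @ fit.alpha_hat, fit.beta_hat, atol=1e-10)


class TestHuberM:
    def test_all_residuals_in_band_equals_ols(self, rng):
        # residuals in the null space of X', near +-1 so max|e/s| << c
        X = rng.normal(size=(20, 2))
        data_tmp = rr.standardize_design(X, np.zeros(20))
        Xs = data_tmp.X
        t = np.resize([1.0, -1.0], 20)
        P = np.eye(20) - Xs @ np.linalg.solve(Xs.T @ Xs, Xs.T)
        r = P @ t
        s = np.median(np.abs(r)) / 0.6744897501960817
        assert np.max(np.abs(r / s)) <= 1.345  # premise of the check
        y = Xs @ np.array([2.0, -1.0]) + r
        data = rr.RegressionData(X=Xs, y=y - y.mean(), n=20, p=2, standardized=False)
        cf = rr.canonical_decompose(data)
        fit_m = rr.fit_huber_m(cf, data.y)
        fit_ols = rr.fit_ols(cf, data.y)
        np.testing.assert_allclose(fit_m.alpha_hat, fit_ols.alpha_hat, atol=1e-8)
        assert np.all(fit_m.weights == 1.0)

    def test_outlier_resistance(self, rng):
        beta = np.array([1.0, -1.0, 2.0])
        X_raw = rng.normal(size=(20, 3))
        y_raw = X_raw @ beta + 0.5 * rng.standard_normal(20)
        y_raw[3] += 50.0
        data = rr.standardize_design(X_raw, y_raw)
        cf = rr.canonical_decompose(data)
        # truth on the standardized scale
        beta_std = beta * data.column_scales
        alpha_true = cf.T.T @ beta_std
        err_m = np.linalg.norm(rr.fit_huber_m(cf, data.y).alpha_hat - alpha_true)
        err_ols = np.linalg.norm(rr.fit_ols(cf, data.y).alpha_hat - alpha_true)
        assert err_m < err_ols

    def test_estimating_equation_residual(self, rng):
        for trial in range(10):
            data = make_dataset(rng, n=40, p=3)
            y = data.y.copy()
            y[trial] += 25.0
            y -= y.mean()
            cf = rr.canonical_decompose(data)
            fit = rr.fit_huber_m(cf, y)
            assert fit.converged
            e = y - cf.Z @ fit.alpha_hat
            score = cf.Z.T @ huber_psi(e / fit.scale_s, 1.345)
            assert np.max(np.abs(score)) < 1e-6

    def test_large_c_recovers_ols(self, dataset):
        cf = rr.canonical_decompose(dataset)
        fit_m = rr.fit_huber_m(cf, dataset.y, rr.HuberConfig(tuning_c=1e6))
        fit_ols = rr.fit_ols(cf, dataset.y)
        assert np.max(np.abs(fit_m.alpha_hat - fit_ols.alpha_hat)) < 1e-6

    def test_matches_statsmodels_rlm(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(40)
        y[5] += 30.0
        data = rr.standardize_design(X, y)
        cf = rr.canonical_decompose(data)
        fit = rr.fit_huber_m(cf, data.y)
        rlm = sm.RLM(data.y, data.X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            conv="coefs", tol=1e-10, maxiter=200)
        np.testing.assert_allclose(fit.beta_hat, rlm.params, atol=1e-6)

    def test_exact_fit_degenerate_scale(self, rng):
        data = make_dataset(rng, sigma=0.0)
        cf = rr.canonical_decompose(data)
        fit = rr.fit_huber_m(cf, data.y)
        assert fit.converged
        np.testing.assert_allclose(cf.Z @ fit.alpha_hat, data.y, atol=1e-8)

    def test_weights_in_unit_interval(self, rng):
        data = make_dataset(rng, n=40, p=3)
        y = data.y.copy()
        y[0] += 40.0
        y -= y.mean()
        cf = rr.canonical_decompose(data)
        fit = rr.fit_huber_m(cf, y)
        assert np.all(fit.weights > 0) and np.all(fit.weights <= 1.0)
        assert np.any(fit.weights < 1.0)  # the outlier is downweighted


class TestShrinkage:
    def test_k_zero_is_identity(self, rng):
        a = rng.normal(size=5)
        lam = rng.uniform(0.1, 3.0, size=5)
        np.testing.assert_array_equal(rr.apply_shrinkage(a, lam, 0.0, 0.7), a)

    def test_hand_example(self):
        out = rr.apply_shrinkage(np.array([2.0]), np.array([2.0]), 1.0, 1.0)
        assert out[0] == pytest.approx(1.0, abs=1e-15)

    def test_kd_equivalent_to_combined_k(self, rng):
        a = rng.normal(size=4)
        lam = rng.uniform(0.1, 3.0, size=4)
        np.testing.assert_allclose(rr.apply_shrinkage(a, lam, 0.4, 0.5),
                                   rr.apply_shrinkage(a, lam, 0.6, 0.0),
                                   atol=1e-15)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError, match="invalid biasing parameter"):
            rr.apply_shrinkage(np.ones(2), np.ones(2), -0.1, 0.0)
        with pytest.raises(ValueError, match="invalid biasing parameter"):
            rr.apply_shrinkage(np.ones(2), np.ones(2), 0.1, -1.0)

    def test_monotone_in_k_and_d(self, rng):
        a = rng.normal(size=4)
        lam = rng.uniform(0.1, 3.0, size=4)
        ks = [0.0, 0.1, 0.5, 2.0, 10.0, 1e6]
        prev = np.abs(a)
        for k in ks[1:]:
            cur = np.abs(rr.apply_shrinkage(a, lam, k, 0.3))
            assert np.all(cur <= prev + 1e-15)
            prev = cur
        assert np.all(prev < 1e-4)  # -> 0 as k grows
        for d1, d2 in [(0.0, 0.2), (0.2, 0.8), (0.8, 5.0)]:
            assert np.all(np.abs(rr.apply_shrinkage(a, lam, 1.0, d2))
                          <= np.abs(rr.apply_shrinkage(a, lam, 1.0, d1)) + 1e-15)


class TestFitNamed:
    def test_reduction_lattice(self, dataset):
        k, d = 0.7, 0.4
        fits = {name: rr.fit_named(name, dataset, k=k, d=d)
                for name in ("OLS", "M", "RIDGE", "RIDGE_M", "MRT", "RTMME")}
        ridge0 = rr.fit_named("RIDGE", dataset, k=0.0)
        np.testing.assert_allclose(ridge0.alpha_hat, fits["OLS"].alpha_hat, atol=1e-10)
        mrt0 = rr.fit_named("MRT", dataset, k=k, d=0.0)
        ridge_k = rr.fit_named("RIDGE", dataset, k=k)
        np.testing.assert_allclose(mrt0.alpha_hat, ridge_k.alpha_hat, atol=1e-10)
        ridge_kd = rr.fit_named("RIDGE", dataset, k=k * (1 + d))
        np.testing.assert_allclose(fits["MRT"].alpha_hat, ridge_kd.alpha_hat, atol=1e-10)
        rtmme00 = rr.fit_named("RTMME", dataset, k=0.0, d=0.0)
        np.testing.assert_allclose(rtmme00.alpha_hat, fits["M"].alpha_hat, atol=1e-10)
        rtmme_d0 = rr.fit_named("RTMME", dataset, k=k, d=0.0)
        np.testing.assert_allclose(rtmme_d0.alpha_hat, fits["RIDGE_M"].alpha_hat,
                                   atol=1e-10)

    def test_unknown_estimator(self, dataset):
        with pytest.raises(ValueError):
            rr.fit_named("LIU", dataset)

    def test_orthogonal_invariance_of_fitted_values(self, rng, dataset):
        Q, _ = np.linalg.qr(rng.normal(size=(dataset.p, dataset.p)))
        rotated = rr.RegressionData(X=dataset.X @ Q, y=dataset.y,
                                    n=dataset.n, p=dataset.p, standardized=False)
        for name in ("OLS", "M", "RIDGE", "RTMME"):
            f1 = rr.fit_named(name, dataset, k=0.5, d=0.3)
            f2 = rr.fit_named(name, rotated, k=0.5, d=0.3)
            np.testing.assert_allclose(dataset.X @ f1.beta_hat,
                                       rotated.X @ f2.beta_hat, atol=1e-7)


class TestSigma2AndBackTransform:
    def test_noiseless_sigma2_zero(self, rng):
        data = make_dataset(rng, sigma=0.0)
        cf = rr.canonical_decompose(data)
        assert rr.estimate_sigma2(cf, data.y) < 1e-12

    def test_hat_matrix_oracle(self, dataset):
        cf = rr.canonical_decompose(dataset)
        X, y = dataset.X, dataset.y
        H = X @ np.linalg.solve(X.T @ X, X.T)
        expected = y @ (np.eye(dataset.n) - H) @ y / (dataset.n - dataset.p)
        assert rr.estimate_sigma2(cf, y) == pytest.approx(expected, rel=1e-10)

    def test_two_residual_example(self):
        # orthogonal design leaving residuals (1, -1): n=3, p=1
        X = np.array([[1.0], [0.0], [0.0]])
        y = np.array([2.0, 1.0, -1.0])
        data = rr.RegressionData(X=X, y=y, n=3, p=1, standardized=False)
        cf = rr.canonical_decompose(data)
        assert rr.estimate_sigma2(cf, y) == pytest.approx(1.0)

    def test_back_transform_matches_raw_ols(self, rng):
        X_raw = rng.normal(3.0, 2.0, size=(25, 3))
        y_raw = X_raw @ np.array([1.0, 0.5, -2.0]) + rng.standard_normal(25) + 4.0
        data = rr.standardize_design(X_raw, y_raw)
        fit = rr.fit_named("OLS", data)
        beta_raw, intercept = rr.back_transform(fit, data)
        ols = sm.OLS(y_raw, sm.add_constant(X_raw)).fit()
        assert intercept == pytest.approx(ols.params[0], abs=1e-8)
        np.testing.assert_allclose(beta_raw, ols.params[1:], atol=1e-8)
        fitted = intercept + X_raw @ beta_raw
        np.testing.assert_allclose(fitted, data.X @ fit.beta_hat + data.y_center,
                                   atol=1e-8)

    def test_missing_metadata_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        data = rr.RegressionData(X=X, y=np.zeros(10), n=10, p=2, standardized=False)
        fit = rr.fit_named("OLS", data)
        with pytest.raises(ValueError, match="standardization metadata"):
            rr.back_transform(fit, data)
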