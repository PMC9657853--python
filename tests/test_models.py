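import numpy as np
import pytest

from spectroleaf.errors import ContractError, DegenerateInputError, ParameterError
from spectroleaf.models import (
    JointPCAModel,
    PredictorMatrix,
    ResponseVector,
    extract_regression,
    fit_joint_pca,
    fit_plsr,
    predict,
    select_components,
)


def _pm(X, band_nm=None):
    X = np.asarray(X, dtype=float)
    if band_nm is None:
        band_nm = 400.0 + 10.0 * np.arange(X.shape[1])
    return PredictorMatrix(X=X, band_nm=np.asarray(band_nm, dtype=float))


def _random_problem(rng, n, p, informative=None):
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    idx = rng.choice(p, size=informative or p, replace=False)
    beta[idx] = rng.standard_normal(idx.size)
    y = X @ beta + 1.5
    return _pm(X), ResponseVector(y=y), beta


def _ols(X, y):
    """Normal-equation oracle with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    return A @ coef


class TestFitPlsr:
    def test_noiseless_linear_recovery(self, rng):
        X, y, _ = _random_problem(rng, 30, 4)
        model = fit_plsr(X, y, 4)
        assert np.abs(model.Y_resid).max() < 1e-8
        yhat = predict(extract_regression(model), X)
        ss_res = ((y.y - yhat.y) ** 2).sum()
        ss_tot = ((y.y - y.y.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot == pytest.approx(1.0, abs=1e-10)

    def test_univariate_matches_ols_slope(self):
        X = _pm(np.array([[1.0], [2.0], [3.0], [4.0]]))
        y = ResponseVector(np.array([2.0, 4.0, 5.0, 9.0]))
        model = fit_plsr(X, y, 1)
        coeffs = extract_regression(model)
        # cov(x, y)/var(x) = 11/5 on these points
        assert coeffs.beta[0] == pytest.approx(11.0 / 5.0, rel=1e-12)

    def test_full_rank_equals_ols(self, rng):
        for _ in range(20):
            n, p = int(rng.integers(8, 40)), int(rng.integers(2, 7))
            X = rng.standard_normal((n, p))
            y = X @ rng.standard_normal(p) + rng.standard_normal(n)
            model = fit_plsr(_pm(X), ResponseVector(y), min(n - 1, p))
            yhat = predict(extract_regression(model), _pm(X)).y
            np.testing.assert_allclose(yhat, _ols(X, y), rtol=1e-8, atol=1e-8)

    def test_matches_sklearn_pls(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((40, 12))
        y = X[:, :4] @ rng.standard_normal(4) + 0.05 * rng.standard_normal(40)
        model = fit_plsr(_pm(X), ResponseVector(y), 3)
        ours = predict(extract_regression(model), _pm(X)).y
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(ours, ref.predict(X).ravel(), rtol=1e-8)

    def test_score_orthogonality(self, rng):
        X, y, _ = _random_problem(rng, 50, 10)
        model = fit_plsr(X, y, 6)
        gram = model.T.T @ model.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_reconstruction_identities(self, rng):
        X, y, _ = _random_problem(rng, 25, 8)
        for h in (1, 3, 5):
            model = fit_plsr(X, y, h)
            Xc = X.X - X.X.mean(axis=0)
            yc = y.y - y.y.mean()
            np.testing.assert_allclose(model.T @ model.P.T + model.X_resid, Xc, atol=1e-10)
            np.testing.assert_allclose(model.U @ model.Q + model.Y_resid, yc, atol=1e-10)

    def test_h_too_large_rejected(self, rng):
        X, y, _ = _random_problem(rng, 10, 3)
        with pytest.raises(ParameterError):
            fit_plsr(X, y, 4)

    def test_zero_variance_y_rejected(self, rng):
        X = _pm(rng.standard_normal((10, 3)))
        with pytest.raises(DegenerateInputError):
            fit_plsr(X, ResponseVector(np.full(10, 2.0)), 1)


class TestJointPca:
    def test_full_rank_reconstruction(self, rng):
        X, y, _ = _random_problem(rng, 20, 4)
        model = fit_joint_pca(X, y, 5)
        assert np.abs(model.Z_resid).max() < 1e-10

    def test_identical_columns_weighted_equally(self):
        col = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        X = _pm(np.column_stack([col, col]))
        y = ResponseVector(np.array([2.0, 3.9, 8.2, 6.1, 9.8]))
        model = fit_joint_pca(X, y, 1)
        w = model.P_z[1:, 0]
        assert abs(abs(w[0]) - abs(w[1])) < 1e-10

    def test_variance_non_increasing(self, rng):
        X, y, _ = _random_problem(rng, 30, 6)
        model = fit_joint_pca(X, y, 4)
        assert np.all(np.diff(model.explained_var) <= 1e-12)

    def test_extraction_recovers_noiseless_beta(self, rng):
        X = rng.standard_normal((40, 2))
        y = 2.0 * X[:, 0] - 3.0 * X[:, 1] + 1.0
        model = fit_joint_pca(_pm(X), ResponseVector(y), 2)
        coeffs = extract_regression(model)
        np.testing.assert_allclose(coeffs.beta, [2.0, -3.0], rtol=1e-8)
        assert coeffs.intercept == pytest.approx(1.0, abs=1e-8)

    def test_full_h_extraction_degenerate(self, rng):
        X, y, _ = _random_problem(rng, 20, 3)
        y.y = y.y + 0.3 * rng.standard_normal(20)
        model = fit_joint_pca(X, y, 4)  # retains the complete Y direction
        with pytest.raises(DegenerateInputError):
            extract_regression(model)


class TestExtractPredict:
    def test_plsr_noiseless_beta(self, rng):
        X = rng.standard_normal((30, 2))
        y = 2.0 * X[:, 0] - 3.0 * X[:, 1] + 1.0
        coeffs = extract_regression(fit_plsr(_pm(X), ResponseVector(y), 2))
        np.testing.assert_allclose(coeffs.beta, [2.0, -3.0], rtol=1e-10)
        assert coeffs.intercept == pytest.approx(1.0, abs=1e-10)

    def test_predict_equals_internal_fit(self, rng):
        X, y, _ = _random_problem(rng, 30, 5)
        y.y = y.y + 0.1 * rng.standard_normal(30)
        model = fit_plsr(X, y, 3)
        internal = model.T @ model.b + model.Y_mean
        external = predict(extract_regression(model), X).y
        np.testing.assert_allclose(external, internal, rtol=1e-9)

    def test_constant_coefficients(self, rng):
        from spectroleaf.models import RegressionCoefficients

        X = _pm(rng.standard_normal((7, 3)))
        coeffs = RegressionCoefficients(
            beta=np.zeros(3), intercept=5.0, band_nm=X.band_nm, source="PLSR"
        )
        np.testing.assert_allclose(predict(coeffs, X).y, 5.0)

    def test_hand_computed_two_by_two(self):
        from spectroleaf.models import RegressionCoefficients

        X = _pm(np.array([[1.0, 2.0], [3.0, 4.0]]))
        coeffs = RegressionCoefficients(
            beta=np.array([0.5, -1.0]), intercept=2.0, band_nm=X.band_nm, source="PLSR"
        )
        # Row dot products by hand: 0.5*1 - 2 + 2 = 0.5; 0.5*3 - 4 + 2 = -0.5
        np.testing.assert_allclose(predict(coeffs, X).y, [0.5, -0.5])

    def test_band_mismatch_raises(self, rng):
        X, y, _ = _random_problem(rng, 10, 3)
        coeffs = extract_regression(fit_plsr(X, y, 2))
        other = _pm(X.X, band_nm=X.band_nm + 5.0)
        with pytest.raises(ContractError, match="band"):
            predict(coeffs, other)

    def test_affine_superposition(self, rng):
        X, y, _ = _random_problem(rng, 20, 4)
        coeffs = extract_regression(fit_plsr(X, y, 3))
        A, B = rng.standard_normal((6, 4)), rng.standard_normal((6, 4))
        pa = predict(coeffs, _pm(A, X.band_nm)).y
        pb = predict(coeffs, _pm(B, X.band_nm)).y
        pmix = predict(coeffs, _pm(0.25 * A + 0.75 * B, X.band_nm)).y
        np.testing.assert_allclose(pmix, 0.25 * pa + 0.75 * pb, rtol=1e-9)


class TestSelectComponents:
    def test_rank_two_chooses_two(self, rng):
        n = 40
        t1, t2 = rng.standard_normal(n), rng.standard_normal(n)
        X = np.column_stack([t1, t2, t1 + t2, t1 - t2])
        y = 2.0 * t1 - t2
        profile = select_components(_pm(X), ResponseVector(y), 3, variance_threshold_pct=99.99)
        assert profile.chosen_h == 2

    def test_zero_threshold_chooses_one(self, rng):
        X, y, _ = _random_problem(rng, 20, 5)
        assert select_components(X, y, 4, variance_threshold_pct=0.0).chosen_h == 1

    def test_cumulative_curve_monotone(self, rng):
        X, y, _ = _random_problem(rng, 30, 8)
        y.y = y.y + rng.standard_normal(30)
        profile = select_components(X, y, 6)
        assert np.all(np.diff(profile.cum_y_pct) >= -1e-10)
        assert profile.cum_y_pct[-1] <= 100.0 + 1e-9


class TestParameterRecovery:
    def test_beta_correlation_with_truth(self, rng):
        # n=64, p=6, noise SD = 1% of the signal SD.
        n, p = 64, 6
        X = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        signal = X @ beta
        y = signal + 0.01 * signal.std() * rng.standard_normal(n)
        coeffs = extract_regression(fit_plsr(_pm(X), ResponseVector(y), p))
        assert np.corrcoef(coeffs.beta, beta)[0, 1] >= 0.99
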