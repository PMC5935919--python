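"""Penalized-logistic solver: oracles, KKT conditions, path behaviour, CV."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from breathvoc.errors import FitError, ValidationError
from breathvoc.lasso import (
    adaptive_weights,
    cv_select_lambda,
    fit_penalized,
    lambda_grid,
    lambda_max,
    standardize,
)
from breathvoc._solver import penalized_objective
from _helpers import logistic_data as _logistic_data


class TestStandardize:
    def test_closed_form_three_points(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Z, params = standardize(X, ["a"])
        expect = np.array([-1.0, 0.0, 1.0]) * np.sqrt(3.0 / 2.0)
        np.testing.assert_allclose(Z[:, 0], expect, atol=1e-12)
        assert params.scale[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_idempotence(self):
        X, _ = _logistic_data(2, n=30, p=3)
        Z, _ = standardize(X, list("abc"))
        Z2, p2 = standardize(Z, list("abc"))
        np.testing.assert_allclose(Z, Z2, atol=1e-12)
        np.testing.assert_allclose(p2.center, 0.0, atol=1e-12)
        np.testing.assert_allclose(p2.scale, 1.0, atol=1e-12)

    def test_zero_variance_named_in_error(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        with pytest.raises(ValidationError, match="b"):
            standardize(X, ["a", "b"])

    def test_back_transform_predicts_identically(self):
        X, y = _logistic_data(5, n=80, p=4)
        Z, params = standardize(X, list("abcd"))
        fit = fit_penalized(Z, y, 2.0)
        b0_raw, beta_raw = params.beta_to_raw(fit.intercept, fit.beta)
        np.testing.assert_allclose(
            b0_raw + X @ beta_raw, fit.intercept + Z @ fit.beta, atol=1e-10
        )
        # and the inverse map returns to the standardized coefficients
        b0_std, beta_std = params.beta_to_std(b0_raw, beta_raw)
        assert b0_std == pytest.approx(fit.intercept, abs=1e-10)
        np.testing.assert_allclose(beta_std, fit.beta, atol=1e-10)


class TestFitPenalized:
    def test_null_model_limit_above_lambda_max(self):
        X, y = _logistic_data(1)
        Z, _ = standardize(X, [f"x{i}" for i in range(X.shape[1])])
        lam = lambda_max(Z, y) * 1.001
        fit = fit_penalized(Z, y, lam)
        assert np.all(fit.beta == 0.0)
        ybar = y.mean()
        assert fit.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-8)

    def test_unpenalized_matches_mle(self):
        X, y = _logistic_data(3, n=150, p=4)
        fit = fit_penalized(X, y, 0.0)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.beta], mle.params, atol=1e-6
        )

    def test_doubling_weight_equals_doubling_lambda_single_feature(self):
        X, y = _logistic_data(4, n=60, p=1, beta=np.array([1.0]))
        f1 = fit_penalized(X, y, 3.0, np.array([2.0]))
        f2 = fit_penalized(X, y, 6.0, np.array([1.0]))
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-7)
        assert f1.intercept == pytest.approx(f2.intercept, abs=1e-7)

    def test_infinite_weight_forces_zero(self):
        X, y = _logistic_data(6, n=80, p=3)
        fit = fit_penalized(X, y, 1.0, np.array([1.0, np.inf, 1.0]))
        assert fit.beta[1] == 0.0
        assert fit.kkt <= 1e-6

    def test_perfect_separation_detected(self):
        X = np.linspace(-2, 2, 30).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)
        with pytest.raises(FitError):
            fit_penalized(X, y, 0.0)

    def test_kkt_residual_small_across_lambda_and_weights(self):
        X, y = _logistic_data(7, n=90, p=6)
        Z, _ = standardize(X, [f"x{i}" for i in range(6)])
        w = np.array([1.0, 0.5, 2.0, 1.0, np.inf, 1.0])
        for lam in lambda_grid(Z, y, w, n_lambda=12, min_ratio=1e-3):
            fit = fit_penalized(Z, y, lam, w)
            assert fit.kkt <= 1e-6
            assert fit.converged

    def test_path_monotonicity(self):
        X, y = _logistic_data(8, n=100, p=8)
        Z, _ = standardize(X, [f"x{i}" for i in range(8)])
        grid = lambda_grid(Z, y, n_lambda=25, min_ratio=1e-2)
        l1_norms, objectives = [], []
        for lam in grid:
            fit = fit_penalized(Z, y, lam)
            l1_norms.append(np.abs(fit.beta).sum())
            objectives.append(fit.objective_value)
        assert all(b - a >= -1e-8 for a, b in zip(l1_norms, l1_norms[1:]))
        assert all(b - a <= 1e-8 for a, b in zip(objectives, objectives[1:]))

    def test_solver_matches_brute_force_small_instances(self):
        # independent oracle: derivative-free minimization of the same
        # objective (multi-start Nelder-Mead) on p <= 3, n <= 40 problems
        from scipy.optimize import minimize

        cases = [
            (10, 20, 1, 0.5, np.array([0.5])),
            (11, 30, 2, 3.0, np.array([1.0, 2.0])),
            (12, 40, 3, 1.5, np.array([1.0, 1.0, 0.3])),
        ]
        for seed, n, p, lam, w in cases:
            X, y = _logistic_data(seed, n=n, p=p)
            fit = fit_penalized(X, y, lam, w)

            def obj(theta):
                return penalized_objective(X, y, theta[1:], theta[0], lam, w)

            best = None
            for start in (np.zeros(p + 1), np.r_[np.log(y.mean() / (1 - y.mean())), np.zeros(p)],
                          np.full(p + 1, 0.3)):
                res = minimize(obj, start, method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000,
                                        "maxfev": 20000})
                if best is None or res.fun < best.fun:
                    best = res
            assert fit.objective_value == pytest.approx(best.fun, abs=1e-6)
            np.testing.assert_allclose(
                np.r_[fit.intercept, fit.beta], best.x, atol=1e-3
            )

    def test_adaptive_equals_rescaled_design_lasso(self):
        X, y = _logistic_data(13, n=100, p=5)
        Z, _ = standardize(X, [f"x{i}" for i in range(5)])
        pilot = fit_penalized(Z, y, 4.0)
        w = adaptive_weights(pilot.beta)
        finite = np.isfinite(w)
        lam = 2.0
        direct = fit_penalized(Z, y, lam, w)
        rescaled = fit_penalized(Z[:, finite] / w[finite], y, lam)
        back = np.zeros(5)
        back[finite] = rescaled.beta / w[finite]
        np.testing.assert_allclose(direct.beta, back, atol=1e-6)
        assert direct.intercept == pytest.approx(rescaled.intercept, abs=1e-6)


class TestAdaptiveWeights:
    def test_definition(self):
        np.testing.assert_allclose(
            adaptive_weights(np.array([2.0, -0.5])), [0.5, 2.0]
        )

    def test_zero_maps_to_infinity(self):
        w = adaptive_weights(np.array([0.0, 1.0]))
        assert np.isinf(w[0])

    @given(c=st.floats(0.01, 100.0))
    def test_homogeneity(self, c):
        beta = np.array([0.5, -2.0, 0.0])
        w1 = adaptive_weights(beta)
        wc = adaptive_weights(c * beta)
        finite = np.isfinite(w1)
        np.testing.assert_allclose(wc[finite], w1[finite] / c, rtol=1e-9)
        assert np.isinf(wc[~finite]).all()


class TestCvSelectLambda:
    def test_same_seed_reproduces_folds_and_choice(self):
        X, y = _logistic_data(20, n=80, p=6)
        a = cv_select_lambda(X, y, n_folds=8, seed=42, n_lambda=20)
        b = cv_select_lambda(X, y, n_folds=8, seed=42, n_lambda=20)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        assert a.lambda_chosen == b.lambda_chosen
        np.testing.assert_array_equal(a.cv_score, b.cv_score)

    def test_tie_break_prefers_larger_lambda(self):
        X, y = _logistic_data(21, n=60, p=4)
        lmax = lambda_max(X, y)
        # every grid point is above lambda_max: all fits are the null model,
        # all scores tie, so the largest lambda must win
        grid = np.array([4.0, 3.0, 2.0]) * lmax
        cv = cv_select_lambda(X, y, n_folds=5, seed=0, grid=grid)
        assert cv.lambda_chosen == grid[0]
        assert np.allclose(cv.cv_score, cv.cv_score[0])

    def test_signal_beats_null_model_out_of_fold(self):
        X, y = _logistic_data(22, n=167, p=12, beta=np.r_[[1.5, -1.5, 1.0], np.zeros(9)])
        Z, _ = standardize(X, [f"x{i}" for i in range(12)])
        cv = cv_select_lambda(Z, y, n_folds=10, seed=3, n_lambda=40)
        lmax = lambda_max(Z, y)
        null_score = cv_select_lambda(Z, y, n_folds=10, seed=3,
                                      grid=np.array([2 * lmax])).cv_score[0]
        assert cv.cv_score.max() > null_score

    def test_too_many_folds_is_error(self):
        X, y = _logistic_data(23, n=30, p=3)
        with pytest.raises(ValidationError):
            cv_select_lambda(X, y, n_folds=29, seed=0, n_lambda=5)
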