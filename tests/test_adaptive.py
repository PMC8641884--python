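"""Ridge step, penalty factors, lambda cross-validation and the two-step
estimator, each checked against an independent route."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from dfcselect import (
    AdaptiveLassoLogistic,
    adaptive_lasso_logistic,
    compute_penalty_factors,
    cross_validate_lambda,
    fit_ridge_logistic,
    generate_case1,
    generate_case2,
    sis_screen,
)
from dfcselect.solver import binomial_deviance


class TestRidge:
    def test_null_limit_under_permuted_labels(self, small_instance):
        X, y = small_instance
        rng = np.random.default_rng(0)
        yp = rng.permutation(y)
        fit = fit_ridge_logistic(X, yp, alphas=[1e6], folds=3, seed=0)
        assert np.max(np.abs(fit.coef)) < 1e-4
        ybar = yp.mean()
        assert fit.intercept == pytest.approx(math.log(ybar / (1 - ybar)), abs=1e-3)

    def test_matches_sklearn_at_fixed_penalty(self):
        # independent convex-optimizer oracle: sklearn solves
        # C * sum(logloss) + ||beta||^2/2, i.e. alpha = 1/(C*n) on our scale
        rng = np.random.default_rng(1)
        n = 200
        y = (rng.random(n) < 0.5).astype(float)
        X = rng.standard_normal((n, 2)) + np.outer(y, [0.8, -0.5])
        Xs = (X - X.mean(0)) / X.std(0)
        alpha = 0.05
        mine = fit_ridge_logistic(Xs, y, alphas=[alpha], standardize=False)
        sk = LogisticRegression(
            C=1.0 / (alpha * n), tol=1e-12, max_iter=100_000
        ).fit(Xs, y)
        np.testing.assert_allclose(mine.coef, sk.coef_.ravel(), atol=1e-6)
        assert mine.intercept == pytest.approx(sk.intercept_[0], abs=1e-6)

    def test_single_class_rejected(self, small_instance):
        X, _ = small_instance
        with pytest.raises(ValueError, match="degenerate"):
            fit_ridge_logistic(X, np.zeros(X.shape[0]))

    def test_zero_variance_feature_gets_zero(self, small_instance):
        X, y = small_instance
        Xz = np.hstack([X, np.full((X.shape[0], 1), 3.0)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            fit = fit_ridge_logistic(Xz, y, alphas=[0.1])
        assert fit.coef[3] == 0.0


class TestPenaltyFactors:
    def test_forced_arithmetic(self):
        pf = compute_penalty_factors([2.0, 0.5], gamma=1.0)
        np.testing.assert_allclose(pf, [0.4, 1.6])

    def test_gamma_zero_is_uniform(self):
        pf = compute_penalty_factors([2.0, -0.5, 0.01], gamma=0.0)
        np.testing.assert_allclose(pf, [1.0, 1.0, 1.0])

    def test_zero_coefficient_excluded(self):
        pf = compute_penalty_factors([1.0, 0.0], gamma=1.0)
        assert np.isinf(pf[1])
        assert pf[0] == pytest.approx(1.0)  # finite factors sum to their count

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            compute_penalty_factors([1.0], gamma=-1.0)

    @given(
        st.lists(st.floats(0.01, 50.0), min_size=2, max_size=20),
        st.floats(0.0, 2.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_finite_factors_normalized(self, betas, gamma):
        pf = compute_penalty_factors(betas, gamma)
        assert pf.sum() == pytest.approx(len(betas), rel=1e-9)
        assert np.all(pf > 0)


class TestCrossValidation:
    def test_deviance_at_null_lambda_is_null_deviance(self, small_instance):
        # above every fold's own lambda_max the model is intercept-only, so
        # the held-out deviance equals the null deviance of train-fold means
        X, y = small_instance
        from dfcselect.solver import weighted_l1_logistic_path
        from dfcselect.adaptive import _fold_seed

        path = weighted_l1_logistic_path(X, y)
        lambdas = np.r_[4 * path.lambdas[0], path.lambdas]
        cv = cross_validate_lambda(X, y, lambdas, folds=5, seed=42)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=_fold_seed(42))
        expected = np.mean(
            [
                binomial_deviance(y[te], np.full(te.size, y[tr].mean()))
                for tr, te in skf.split(X, y)
            ]
        )
        assert cv.mean_deviance[0] == pytest.approx(expected, abs=1e-8)

    def test_separable_data_deviance_decreases(self):
        rng = np.random.default_rng(3)
        n = 200
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = np.column_stack([np.r_[rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n // 2)],
                             rng.standard_normal(n)])
        from dfcselect.solver import weighted_l1_logistic_path

        path = weighted_l1_logistic_path(X, y)
        cv = cross_validate_lambda(X, y, path.lambdas, folds=5, seed=0)
        assert cv.mean_deviance[cv.index_selected] < 0.1
        assert cv.index_selected > 0

    def test_fold_reduction_warning(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 2))
        y = np.r_[np.ones(4), np.zeros(16)]
        X[:, 0] += y
        with pytest.warns(RuntimeWarning, match="reducing folds"):
            cross_validate_lambda(X, y, [0.1, 0.05], folds=10, seed=0)


class TestSIS:
    def test_perfect_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 100
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = rng.standard_normal((n, 5))
        X[:, 2] = y * 4 + rng.normal(0, 0.05, n)
        assert sis_screen(X, y, keep=1)[0] == 2

    def test_matches_welch_t_ranking_on_gaussian_design(self):
        ds = generate_case1(seed=17)
        X, y = ds.matrix.values, ds.y
        Xs = (X - X.mean(0)) / X.std(0)
        idx = sis_screen(Xs, y, keep=4)
        t = np.abs(stats.ttest_ind(Xs[y == 1], Xs[y == 0], axis=0, equal_var=False).statistic)
        np.testing.assert_array_equal(idx, np.argsort(-t, kind="stable"))

    def test_keep_exceeding_features_warns_and_returns_all(self, small_instance):
        X, y = small_instance
        with pytest.warns(RuntimeWarning, match="exceeds"):
            idx = sis_screen(X, y, keep=10)
        assert sorted(idx) == [0, 1, 2]

    def test_default_keep(self):
        rng = np.random.default_rng(2)
        n = 200
        X = rng.standard_normal((n, 80))
        y = (rng.random(n) < 0.5).astype(float)
        assert sis_screen(X, y).size == int(n / math.log(n))


class TestTwoStepEstimator:
    def test_case1_selects_correlated_pair(self, case1):
        m = adaptive_lasso_logistic(case1.matrix.values, case1.y, seed=0)
        assert {2, 3} <= set(m.selected_)
        assert set(m.entry_order_[:2]) == {2, 3}

    def test_case2_prioritizes_exclusive_pair(self, case2):
        m = AdaptiveLassoLogistic(cv=None, random_state=0).fit(
            case2.matrix.values, case2.y
        )
        assert set(m.entry_order_[:2]) == {0, 1}

    def test_constant_labels_rejected(self, small_instance):
        X, _ = small_instance
        with pytest.raises(ValueError, match="degenerate"):
            AdaptiveLassoLogistic().fit(X, np.ones(X.shape[0]))

    def test_predict_roundtrip(self, case1):
        m = AdaptiveLassoLogistic(cv=None, random_state=0).fit(
            case1.matrix.values, case1.y
        )
        pred = m.predict(case1.matrix.values)
        assert np.mean(pred == case1.y) > 0.95
        proba = m.predict_proba(case1.matrix.values)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_sklearn_get_set_params(self):
        m = AdaptiveLassoLogistic(gamma=0.5)
        assert m.get_params()["gamma"] == 0.5
        m.set_params(gamma=2.0, cv=5)
        assert m.gamma == 2.0 and m.cv == 5
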