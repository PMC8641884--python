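"""Two-step adaptive LASSO-logistic regression.

Step one fits an L2-penalized (ridge) logistic regression with the ridge
strength chosen by cross-validated binomial deviance.  Step two solves a
weighted-L1 logistic path whose per-feature penalty factor is
``1 / |beta_ridge_j|^gamma`` (infinite for exactly-zero ridge coefficients),
and the sparsity parameter lambda is chosen by stratified K-fold
cross-validation of binomial deviance.  Features with nonzero coefficients
at the selected lambda form the discriminative feature set.

The ridge weighting gives the adaptive LASSO its oracle property: strongly
informative features receive light penalties and survive to the sparse end
of the path, so the entry order of the path ranks features by joint
discriminative value rather than by marginal mean shift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .solver import (
    LassoPathResult,
    binomial_deviance,
    weighted_l1_logistic_path,
)

__all__ = [
    "RidgeLogisticFit",
    "CVLambdaResult",
    "AdaptiveLassoLogistic",
    "fit_ridge_logistic",
    "compute_penalty_factors",
    "cross_validate_lambda",
    "adaptive_lasso_logistic",
    "sis_screen",
]

_DEFAULT_RIDGE_ALPHAS = np.geomspace(1e2, 1e-5, 25)


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y).ravel()
    uniq = np.unique(y)
    if uniq.size != 2:
        raise ValueError(
            f"degenerate response: expected exactly 2 classes, got {uniq.size}"
        )
    return (y == uniq[1]).astype(float)


def _ridge_solve(Xs, y, alpha, w0=None):
    """Minimize mean binomial NLL + alpha/2 ||beta||^2 (intercept free)."""
    n, p = Xs.shape

    def fg(w):
        b, beta = w[0], w[1:]
        eta = b + Xs @ beta
        prob = expit(eta)
        f = float(np.mean(np.logaddexp(0.0, eta) - y * eta)) + 0.5 * alpha * float(
            beta @ beta
        )
        g = np.empty(p + 1)
        resid = prob - y
        g[0] = float(np.mean(resid))
        g[1:] = Xs.T @ resid / n + alpha * beta
        return f, g

    if w0 is None:
        w0 = np.zeros(p + 1)
        ybar = float(np.mean(y))
        w0[0] = math.log(ybar / (1.0 - ybar))
    res = minimize(
        fg,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-10},
    )
    return res.x


@dataclass
class RidgeLogisticFit:
    """Cross-validated ridge logistic regression (first adaptive-LASSO step)."""

    coef: np.ndarray
    intercept: float
    alpha: float
    alphas: np.ndarray
    cv_deviance: np.ndarray
    cv_se: np.ndarray


def fit_ridge_logistic(
    X,
    y,
    folds: int = 10,
    seed: int | None = None,
    alphas=None,
    standardize: bool = True,
) -> RidgeLogisticFit:
    """Ridge-logistic coefficients at the CV-deviance-minimizing penalty.

    The internal alpha grid spans seven decades by default.  Coefficients
    are reported on the original feature scale; zero-variance features get
    coefficient 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = _as_binary(y)
    n, p = X.shape
    alphas = _DEFAULT_RIDGE_ALPHAS if alphas is None else np.sort(np.asarray(alphas, float))[::-1]

    if standardize:
        center, scale = X.mean(axis=0), X.std(axis=0)
    else:
        center, scale = np.zeros(p), np.ones(p)
    zero_var = scale == 0.0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s) get coefficient 0",
            RuntimeWarning,
        )
        scale = np.where(zero_var, 1.0, scale)
    Xs = (X - center) / scale

    if alphas.size > 1:
        folds = _effective_folds(y, folds)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_fold_seed(seed))
        dev = np.zeros((folds, alphas.size))
        for k, (tr, te) in enumerate(skf.split(Xs, y)):
            w = None
            for a_i, alpha in enumerate(alphas):
                w = _ridge_solve(Xs[tr], y[tr], alpha, w0=w)
                p_te = expit(w[0] + Xs[te] @ w[1:])
                dev[k, a_i] = binomial_deviance(y[te], p_te)
        mean_dev = dev.mean(axis=0)
        se_dev = dev.std(axis=0, ddof=1) / math.sqrt(folds)
        best = int(np.argmin(mean_dev))
    else:
        mean_dev = np.array([np.nan])
        se_dev = np.array([np.nan])
        best = 0

    w = None
    for alpha in alphas[: best + 1]:  # warm-started final fit on full data
        w = _ridge_solve(Xs, y, alpha, w0=w)
    beta_std = w[1:]
    beta = np.where(zero_var, 0.0, beta_std / scale)
    intercept = float(w[0] - beta_std @ (center / scale))
    return RidgeLogisticFit(
        coef=beta,
        intercept=intercept,
        alpha=float(alphas[best]),
        alphas=alphas,
        cv_deviance=mean_dev,
        cv_se=se_dev,
    )


def compute_penalty_factors(beta_ridge, gamma: float = 1.0) -> np.ndarray:
    """Adaptive penalty factors ``w_j = 1 / |beta_ridge_j|^gamma``.

    Exactly-zero ridge coefficients receive an infinite factor (the feature
    is excluded from selection).  Finite factors are rescaled to sum to the
    number of finite-penalty features, so the overall penalty strength of
    the lambda grid is comparable across gamma.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    beta = np.asarray(beta_ridge, dtype=float)
    with np.errstate(divide="ignore"):
        raw = np.where(beta == 0.0, np.inf, 1.0 / np.abs(beta) ** gamma)
    finite = np.isfinite(raw)
    if finite.any():
        raw = raw.copy()
        raw[finite] *= finite.sum() / raw[finite].sum()
    return raw


def _fold_seed(seed):
    if seed is None:
        return None
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))


def _effective_folds(y, folds):
    if folds < 2:
        raise ValueError("folds must be >= 2")
    min_class = int(np.bincount(y.astype(int)).min())
    if min_class < 2:
        raise ValueError("each class needs >= 2 members for stratified folding")
    if min_class < folds:
        warnings.warn(
            f"reducing folds from {folds} to {min_class} so every fold is stratified",
            RuntimeWarning,
        )
        return min_class
    return folds


@dataclass
class CVLambdaResult:
    """Cross-validated binomial deviance along the lambda grid."""

    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_selected: float
    index_selected: int


def cross_validate_lambda(
    X,
    y,
    lambdas,
    penalty_factors=None,
    folds: int = 10,
    seed: int | None = None,
    standardize: bool = True,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
) -> CVLambdaResult:
    """Per-lambda held-out binomial deviance; the minimizer is selected."""
    X = np.asarray(X, dtype=float)
    y = _as_binary(y)
    lambdas = np.asarray(lambdas, dtype=float)
    folds = _effective_folds(y, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_fold_seed(seed))
    dev = np.zeros((folds, lambdas.size))
    for k, (tr, te) in enumerate(skf.split(X, y)):
        path = weighted_l1_logistic_path(
            X[tr],
            y[tr],
            penalty_factors=penalty_factors,
            lambdas=lambdas,
            standardize=standardize,
            tol=tol,
            max_sweeps=max_sweeps,
        )
        probs = expit(path.intercept[None, :] + X[te] @ path.coef)
        probs = np.clip(probs, 1e-12, 1 - 1e-12)
        yte = y[te][:, None]
        dev[k] = -2.0 * np.mean(yte * np.log(probs) + (1 - yte) * np.log1p(-probs), axis=0)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / math.sqrt(folds)
    best = int(np.argmin(mean_dev))
    return CVLambdaResult(
        lambdas=lambdas,
        mean_deviance=mean_dev,
        se_deviance=se_dev,
        lambda_selected=float(lambdas[best]),
        index_selected=best,
    )


def sis_screen(X, y, keep: int | None = None) -> np.ndarray:
    """Sure independence screening by the univariate logistic score statistic.

    Features are ranked by the absolute score-test statistic of the
    per-feature univariate logistic regression,
    ``z_j = x_j^T (y - ybar) / sqrt(ybar (1 - ybar) ||x_j||^2)`` with
    centered ``x_j``; the top ``keep`` feature indices are returned in rank
    order.  The default keep is ``floor(n / log n)``.
    """
    X = np.asarray(X, dtype=float)
    y = _as_binary(y)
    n, p = X.shape
    if keep is None:
        keep = int(n / math.log(n))
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if keep > p:
        warnings.warn(
            f"keep={keep} exceeds the {p} available features; returning all",
            RuntimeWarning,
        )
        keep = p
    Xc = X - X.mean(axis=0)
    ybar = float(y.mean())
    num = Xc.T @ (y - ybar)
    ss = np.einsum("ij,ij->j", Xc, Xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / np.sqrt(ybar * (1.0 - ybar) * ss)
    z = np.where(np.isfinite(z), z, 0.0)
    order = np.argsort(-np.abs(z), kind="stable")
    return order[:keep]


def entry_order_from_path(path: LassoPathResult) -> np.ndarray:
    """Feature indices in the order they first become nonzero along the path.

    Ties at the same grid point are broken by larger absolute coefficient
    at that lambda, then by feature index.
    """
    nz = path.coef_std != 0.0
    ever = nz.any(axis=1)
    feats = np.flatnonzero(ever)
    first = np.array([int(np.argmax(nz[j])) for j in feats])
    mag = np.array([abs(path.coef_std[j, f]) for j, f in zip(feats, first)])
    order = sorted(range(len(feats)), key=lambda i: (first[i], -mag[i], feats[i]))
    return feats[order]


class AdaptiveLassoLogistic(ClassifierMixin, BaseEstimator):
    """Adaptive LASSO-logistic classifier with cross-validated sparsity.

    Parameters
    ----------
    gamma : float, default 1.0
        Exponent of the ridge-based penalty factors ``1/|beta_ridge|^gamma``.
        ``gamma=0`` reduces to the plain (uniform-penalty) LASSO.
    cv : int or None, default 10
        Stratified folds for both the ridge-penalty and lambda selection.
        ``None`` skips lambda cross-validation and reports the sparsest end
        of the path.
    n_lambdas, lambda_min_ratio : grid of the L1 path, log-spaced from the
        data-determined lambda_max down to ``lambda_min_ratio*lambda_max``.
    ridge_alphas : optional explicit grid for the ridge step.
    standardize : bool, default True
        Standardize columns internally; coefficients are always reported on
        the original feature scale.
    tol, max_sweeps : coordinate-descent convergence controls.
    random_state : seed for all cross-validation folding.

    Attributes
    ----------
    ridge_ : RidgeLogisticFit of the first step.
    penalty_factors_ : normalized adaptive weights (inf = excluded).
    path_ : LassoPathResult with the full coefficient path.
    cv_ : CVLambdaResult or None.
    lambda_selected_, coef_, intercept_ : the chosen model.
    entry_order_ : feature indices ordered by first entry along the path.
    selected_ : indices with nonzero coefficient at the chosen lambda.
    """

    def __init__(
        self,
        gamma: float = 1.0,
        cv: int | None = 10,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.01,
        ridge_alphas=None,
        standardize: bool = True,
        tol: float = 1e-7,
        max_sweeps: int = 100_000,
        random_state: int | None = None,
    ):
        self.gamma = gamma
        self.cv = cv
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.ridge_alphas = ridge_alphas
        self.standardize = standardize
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        yraw = np.asarray(y).ravel()
        self.classes_ = np.unique(yraw)
        y01 = _as_binary(yraw)
        self.n_features_in_ = X.shape[1]

        folds = self.cv if self.cv is not None else 10
        self.ridge_ = fit_ridge_logistic(
            X,
            y01,
            folds=folds,
            seed=self.random_state,
            alphas=self.ridge_alphas,
            standardize=self.standardize,
        )
        self.penalty_factors_ = compute_penalty_factors(self.ridge_.coef, self.gamma)
        self.path_ = weighted_l1_logistic_path(
            X,
            y01,
            penalty_factors=self.penalty_factors_,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            standardize=self.standardize,
            tol=self.tol,
            max_sweeps=self.max_sweeps,
        )
        if self.cv is not None:
            self.cv_ = cross_validate_lambda(
                X,
                y01,
                lambdas=self.path_.lambdas,
                penalty_factors=self.penalty_factors_,
                folds=self.cv,
                seed=self.random_state,
                standardize=self.standardize,
                tol=self.tol,
                max_sweeps=self.max_sweeps,
            )
            idx = self.cv_.index_selected
        else:
            self.cv_ = None
            idx = self.path_.lambdas.size - 1
        self.lambda_index_ = idx
        self.lambda_selected_ = float(self.path_.lambdas[idx])
        self.coef_ = self.path_.coef[:, idx].copy()
        self.intercept_ = float(self.path_.intercept[idx])
        self.entry_order_ = entry_order_from_path(self.path_)
        self.selected_ = np.flatnonzero(self.coef_ != 0.0)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0.0).astype(int)]


def adaptive_lasso_logistic(
    X, y, gamma: float = 1.0, folds: int | None = 10, seed: int | None = None, **kwargs
) -> AdaptiveLassoLogistic:
    """Two-step adaptive LASSO-logistic fit; returns the fitted estimator."""
    est = AdaptiveLassoLogistic(
        gamma=gamma, cv=folds, random_state=seed, **kwargs
    )
    return est.fit(X, y)
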