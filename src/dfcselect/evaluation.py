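"""Model evaluation: accuracy, precision-recall, imbalance sweeps, and a
Welch-t DEG baseline for synthetic comparisons.

Precision-recall is the imbalance-aware diagnostic of choice here: the
positive class (the population of interest) is typically a small fraction
of the cells, and a constant classifier already reaches high accuracy and
high ROC-AUC, while its PR-AUC collapses to the prevalence.
"""

from __future__ import annotations

import math
import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

from .adaptive import AdaptiveLassoLogistic
from .pipeline import _as_matrix, make_poi_labels

__all__ = [
    "PRSummary",
    "classification_accuracy",
    "pr_curve",
    "imbalance_sweep",
    "welch_t_deg",
    "overlap_summary",
    "OverlapSummary",
]


def _resolve_features(matrix, features):
    matrix = _as_matrix(matrix)
    if features is None:
        return matrix.dense(), list(matrix.gene_ids)
    feats = list(features)
    if len(feats) == 0:
        raise ValueError("feature subset must not be empty")
    if all(isinstance(f, (int, np.integer)) for f in feats):
        idx = np.asarray(feats, dtype=int)
    else:
        lookup = {g: i for i, g in enumerate(matrix.gene_ids)}
        missing = [f for f in feats if f not in lookup]
        if missing:
            raise ValueError(f"unknown feature(s): {missing[:10]}")
        idx = np.asarray([lookup[f] for f in feats], dtype=int)
    return matrix.dense()[:, idx], [matrix.gene_ids[i] for i in idx]


def classification_accuracy(matrix, y, features=None, model=None, ridge_c: float = 1e4):
    """Resubstitution accuracy of a logistic discrimination.

    When ``model`` is None (or a feature subset is requested) a lightly
    ridge-regularized logistic regression is refit on the requested
    features and scored on the same cells; predicted class is probability
    >= 0.5.
    """
    y = np.asarray(y).ravel()
    if model is not None and features is None:
        X = _as_matrix(matrix).dense()
        return float(np.mean(model.predict(X) == y))
    X, _ = _resolve_features(matrix, features)
    clf = LogisticRegression(C=ridge_c, max_iter=5000)
    clf.fit(X, y)
    return float(clf.score(X, y))


@dataclass
class PRSummary:
    """Precision-recall curve over all score thresholds, with its AUC."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auc_pr: float
    prevalence: float


def pr_curve(scores, y) -> PRSummary:
    """Precision-recall curve and its area by step integration.

    Points are computed at every distinct score threshold (ties grouped),
    ordered by decreasing threshold so recall is nondecreasing.  The area
    is the sum of precision times recall increments (the average-precision
    form of the step-curve integral); a constant score therefore yields
    exactly the prevalence, the random-classifier baseline.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    if scores.shape != y.shape:
        raise ValueError("scores and y must have equal length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PR curve undefined without positive labels")
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    # indices where a threshold ends (last element of each tie group)
    distinct = np.r_[np.flatnonzero(np.diff(ss) != 0.0), ss.size - 1]
    tp = np.cumsum(ys)[distinct].astype(float)
    n_pred = distinct + 1.0
    precision = tp / n_pred
    recall = tp / n_pos
    auc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return PRSummary(
        precision=precision,
        recall=recall,
        thresholds=ss[distinct],
        auc_pr=auc,
        prevalence=n_pos / y.size,
    )


def imbalance_sweep(
    matrix,
    annotation,
    poi=None,
    fractions=(1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1),
    seed: int | None = None,
    holdout: float = 0.2,
    gamma: float = 1.0,
    cv: int | None = 10,
    sis_keep: int | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """PR-AUC of the discriminative model as the POI is thinned.

    For each fraction, only POI cells are subsampled to that fraction (all
    other cells are kept), an 80/20 stratified holdout is split off, the
    adaptive LASSO-logistic model is refit on the training part, and the
    PR-AUC of its POI probability is reported on the held-out cells
    (training-set PR-AUC is reported alongside).
    """
    matrix = _as_matrix(matrix)
    y = make_poi_labels(annotation, poi) if poi is not None else np.asarray(annotation, int)
    X = matrix.dense()
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    ss = np.random.SeedSequence(seed)
    rows = []
    for frac, child in zip(fractions, ss.spawn(len(list(fractions)))):
        if not 0.0 < frac <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(3)]
        rng = np.random.default_rng(child_seeds[0])
        n_keep = max(1, int(math.floor(frac * pos.size)))
        folds = cv if cv is not None else 10
        if n_keep < folds:
            warnings.warn(
                f"POI subsample of {n_keep} cells is smaller than {folds} folds; skipping",
                RuntimeWarning,
            )
            continue
        keep_pos = rng.choice(pos, size=n_keep, replace=False) if frac < 1.0 else pos
        idx = np.sort(np.concatenate([keep_pos, neg]))
        tr, te = train_test_split(
            np.arange(idx.size),
            test_size=holdout,
            stratify=y[idx],
            random_state=child_seeds[1],
        )
        if sis_keep is not None:
            from .adaptive import sis_screen

            cols = np.sort(sis_screen(X[idx][tr], y[idx][tr], keep=sis_keep))
        else:
            cols = slice(None)
        model = AdaptiveLassoLogistic(
            gamma=gamma, cv=cv, random_state=child_seeds[2], **fit_kwargs
        ).fit(X[idx][tr][:, cols], y[idx][tr])
        auc_te = pr_curve(model.decision_function(X[idx][te][:, cols]), y[idx][te]).auc_pr
        auc_tr = pr_curve(model.decision_function(X[idx][tr][:, cols]), y[idx][tr]).auc_pr
        rows.append(
            {
                "poi_fraction": frac,
                "n_poi": n_keep,
                "auc_pr": auc_te,
                "auc_pr_train": auc_tr,
                "n_selected": int(model.selected_.size),
            }
        )
    return pd.DataFrame(rows)


def welch_t_deg(matrix, y) -> pd.DataFrame:
    """Per-gene Welch t-test with Benjamini-Hochberg FDR.

    A baseline differential-expression caller for synthetic comparisons:
    two-sided Welch (unequal-variance) t per gene, BH-adjusted FDR, the
    difference of group means and, where both means are positive, their
    log2 ratio.  Genes with zero variance in both groups get t = 0, p = 1
    and are flagged ``degenerate``.
    """
    matrix = _as_matrix(matrix)
    y = np.asarray(y).ravel().astype(int)
    X = matrix.dense()
    g1, g0 = X[y == 1], X[y == 0]
    if min(g1.shape[0], g0.shape[0]) < 2:
        raise ValueError("both groups need at least 2 cells")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant genes produce nan t-statistics; they are flagged below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(g1, g0, axis=0, equal_var=False)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.where((m1 > 0) & (m0 > 0), np.log2(m1 / m0), np.nan)
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "t": t,
            "p_value": p,
            "fdr": fdr,
            "mean_poi": m1,
            "mean_other": m0,
            "mean_diff": m1 - m0,
            "log2_fc": log2_fc,
            "degenerate": degenerate,
        }
    )


OverlapSummary = namedtuple("OverlapSummary", ["n_dfc_only", "n_shared", "n_deg_only"])


def overlap_summary(dfc_genes, deg_genes) -> OverlapSummary:
    """Venn counts of the discriminative set against a DEG list."""
    a, b = set(dfc_genes), set(deg_genes)
    return OverlapSummary(len(a - b), len(a & b), len(b - a))
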