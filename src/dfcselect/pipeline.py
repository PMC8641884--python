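"""End-to-end discriminative-feature extraction from expression + clusters.

The pipeline mirrors the workflow applied to clustered scRNA-seq data:
filter rarely expressed genes, turn the designated cluster into a binary
population-of-interest (POI) indicator, stratified-subsample the cells,
optionally screen features marginally, then run the two-step adaptive
LASSO-logistic fit.  Genes with nonzero weight at the selected sparsity
are the discriminative feature set (DFC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .adaptive import AdaptiveLassoLogistic
from .containers import CellAnnotation, ExpressionMatrix
from .solver import LassoPathResult

__all__ = [
    "DFCResult",
    "DFCExtractor",
    "filter_genes",
    "make_poi_labels",
    "subsample_cells",
    "extract_dfc",
    "decision_boundary_2d",
    "constrain_selection_size",
]


def _as_matrix(X) -> ExpressionMatrix:
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ExpressionMatrix.from_frame(X)
    return ExpressionMatrix(np.asarray(X, dtype=float))


def filter_genes(matrix, min_cells: int = 10) -> ExpressionMatrix:
    """Keep genes expressed (value > 0) in at least ``min_cells`` cells.

    A gene expressed in exactly ``min_cells`` cells is kept (the filter
    removes genes expressed in *fewer* cells).
    """
    matrix = _as_matrix(matrix)
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    vals = matrix.values
    if hasattr(vals, "tocsc"):
        n_expressing = np.asarray((vals > 0).sum(axis=0)).ravel()
    else:
        n_expressing = (vals > 0).sum(axis=0)
    keep = n_expressing >= min_cells
    if not keep.any():
        raise ValueError(
            f"no gene is expressed in at least {min_cells} cells; nothing left"
        )
    return matrix.subset_genes(keep)


def make_poi_labels(annotation, poi_cluster) -> np.ndarray:
    """Binary y with 1 for cells whose cluster equals ``poi_cluster``."""
    if not isinstance(annotation, CellAnnotation):
        labels = np.asarray(annotation)
        annotation = CellAnnotation(
            np.array([f"C{i}" for i in range(len(labels))], dtype=object), labels
        )
    return annotation.poi_indicator(poi_cluster)


def subsample_cells(
    annotation, fraction: float = 0.3, seed: int | None = None
) -> np.ndarray:
    """Per-cluster simple random sample of ``floor(fraction * n_c)`` cells.

    Every nonempty cluster contributes at least one cell.  Returns sorted
    cell indices; deterministic for a given seed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if isinstance(annotation, CellAnnotation):
        labels = annotation.cluster
    else:
        labels = np.asarray([str(c) for c in np.asarray(annotation)], dtype=object)
    if fraction == 1.0:
        return np.arange(len(labels))
    rng = np.random.default_rng(seed)
    picked = []
    for c in pd.unique(labels):
        idx = np.flatnonzero(labels == c)
        k = max(1, int(math.floor(fraction * idx.size)))
        picked.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(picked))


@dataclass
class DFCResult:
    """Genes selected as the discriminative feature set, with signed weights."""

    genes: np.ndarray
    weights: np.ndarray
    intercept: float
    lambda_selected: float
    entry_order: np.ndarray  # gene ids ordered by first entry along the path

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rank = {g: i + 1 for i, g in enumerate(self.entry_order)}
        return pd.DataFrame(
            {
                "gene": self.genes,
                "weight": self.weights,
                "entry_rank": [rank.get(g, np.nan) for g in self.genes],
            }
        )


class DFCExtractor(BaseEstimator):
    """Extract the discriminative feature set for one cell cluster.

    ``fit(X, y)`` takes a cells x genes matrix (ExpressionMatrix, DataFrame
    or ndarray) and per-cell cluster labels ``y``; the cluster named by
    ``poi`` becomes the positive class.  When ``poi`` is None, ``y`` must
    already be a binary 0/1 POI indicator (the non-cluster use case).

    Parameters follow the analysis defaults: genes expressed in fewer than
    ``min_cells`` cells are dropped, a per-cluster ``fraction`` of cells is
    subsampled before fitting, ``sis_keep`` optionally applies marginal
    (sure-independence) screening after subsampling, and the adaptive
    LASSO runs with exponent ``gamma`` and ``cv``-fold lambda selection.
    """

    def __init__(
        self,
        poi=None,
        min_cells: int = 10,
        fraction: float = 0.3,
        sis_keep: int | None = None,
        gamma: float = 1.0,
        cv: int | None = 10,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.01,
        standardize: bool = True,
        tol: float = 1e-7,
        max_sweeps: int = 100_000,
        random_state: int | None = None,
    ):
        self.poi = poi
        self.min_cells = min_cells
        self.fraction = fraction
        self.sis_keep = sis_keep
        self.gamma = gamma
        self.cv = cv
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.random_state = random_state

    def fit(self, X, y=None):
        from .adaptive import sis_screen

        matrix = _as_matrix(X)
        labels = None if y is None else np.asarray(y)
        if labels is not None and len(labels) != matrix.n_cells:
            raise ValueError("cluster labels must have one entry per cell")
        if labels is None and not isinstance(self.poi, (list, tuple, set, np.ndarray)):
            raise ValueError("cluster labels are required unless poi is a cell-id list")
        matrix = filter_genes(matrix, self.min_cells)

        if isinstance(self.poi, (list, tuple, set, np.ndarray)):
            # POI given as an explicit cell-id list, bypassing clusters
            poi_cells = {str(c) for c in self.poi}
            y01 = np.array([str(c) in poi_cells for c in matrix.cell_ids], dtype=int)
            if y01.sum() == 0:
                raise ValueError("none of the given POI cell ids are in the matrix")
            strata = np.where(y01 == 1, "poi", "other")
        elif self.poi is not None:
            ann = CellAnnotation(matrix.cell_ids, labels)
            y01 = ann.poi_indicator(self.poi)
            strata = ann.cluster
        else:
            y01 = np.asarray(labels, dtype=int)
            if not np.isin(np.unique(y01), [0, 1]).all():
                raise ValueError("without a poi cluster, y must be binary 0/1")
            strata = y01.astype(str)

        if self.random_state is None:
            sub_seed = cv_seed = None
        else:
            ss = np.random.SeedSequence(self.random_state).spawn(2)
            sub_seed, cv_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss)

        idx = subsample_cells(strata, self.fraction, seed=sub_seed)
        Xfit = matrix.dense()[idx]
        yfit = y01[idx]
        if np.unique(yfit).size < 2:
            raise ValueError("both classes must be present after subsampling")

        gene_ids = matrix.gene_ids
        if self.sis_keep is not None:
            keep = np.sort(sis_screen(Xfit, yfit, keep=self.sis_keep))
            Xfit = Xfit[:, keep]
            gene_ids = gene_ids[keep]
            self.sis_index_ = keep
        else:
            self.sis_index_ = None

        model = AdaptiveLassoLogistic(
            gamma=self.gamma,
            cv=self.cv,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            standardize=self.standardize,
            tol=self.tol,
            max_sweeps=self.max_sweeps,
            random_state=cv_seed,
        ).fit(Xfit, yfit)

        self.model_ = model
        self.gene_universe_ = gene_ids
        self.subsample_idx_ = idx
        self.y_ = y01
        sel = model.selected_
        if sel.size == 0:
            warnings.warn("no gene has nonzero weight at the selected lambda", RuntimeWarning)
        self.genes_ = gene_ids[sel]
        self.weights_ = model.coef_[sel]
        self.intercept_ = model.intercept_
        self.lambda_selected_ = model.lambda_selected_
        self.entry_genes_ = gene_ids[model.entry_order_]
        self.result_ = DFCResult(
            genes=self.genes_,
            weights=self.weights_,
            intercept=self.intercept_,
            lambda_selected=self.lambda_selected_,
            entry_order=self.entry_genes_,
        )
        return self


def extract_dfc(
    matrix,
    annotation=None,
    poi=None,
    gamma: float = 1.0,
    folds: int | None = 10,
    fraction: float = 0.3,
    sis_keep: int | None = None,
    seed: int | None = None,
    min_cells: int = 10,
    **kwargs,
) -> DFCResult:
    """Filter, label, subsample, (optionally screen) and fit; return the DFC."""
    if isinstance(annotation, CellAnnotation):
        matrix = _as_matrix(matrix)
        annotation = annotation.align_to(matrix.cell_ids)
        labels = annotation.cluster
    elif annotation is None:
        labels = None
    else:
        labels = np.asarray(annotation)
    ext = DFCExtractor(
        poi=poi,
        min_cells=min_cells,
        fraction=fraction,
        sis_keep=sis_keep,
        gamma=gamma,
        cv=folds,
        random_state=seed,
        **kwargs,
    ).fit(matrix, labels)
    return ext.result_


def _get_path(fit) -> LassoPathResult:
    if isinstance(fit, LassoPathResult):
        return fit
    if isinstance(fit, AdaptiveLassoLogistic):
        return fit.path_
    if isinstance(fit, DFCExtractor):
        return fit.model_.path_
    raise TypeError("expected a path result, AdaptiveLassoLogistic or DFCExtractor")


def decision_boundary_2d(fit, pair) -> tuple[float, float]:
    """Slope and intercept of the 2-D decision boundary for a feature pair.

    Uses the smallest lambda on the grid at which exactly the two requested
    features are nonzero and returns the line ``x2 = slope * x1 + intercept``
    from ``b1*x1 + b2*x2 + b0 = 0``.  If the second coefficient is zero the
    boundary is vertical: slope ``inf`` and the intercept is the x1 crossing.
    """
    path = _get_path(fit)
    i, j = pair
    nz = path.coef != 0.0
    want = np.zeros(path.coef.shape[0], dtype=bool)
    want[[i, j]] = True
    match = (nz == want[:, None]).all(axis=0)
    if not match.any():
        raise ValueError(
            "no lambda on the grid selects exactly the two requested features"
        )
    li = int(np.flatnonzero(match)[-1])  # smallest qualifying lambda
    b1, b2 = path.coef[i, li], path.coef[j, li]
    b0 = path.intercept[li]
    if b2 == 0.0:
        return math.inf, -b0 / b1
    return -b1 / b2, -b0 / b2


def constrain_selection_size(fit, k: int) -> np.ndarray:
    """Feature indices at the sparsity level closest to (at most) ``k``.

    Scans the path for the maximal nonzero count not exceeding ``k`` and
    returns the nonzero features at the largest lambda achieving it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    path = _get_path(fit)
    counts = path.n_nonzero
    eligible = counts <= k
    if not eligible.any():  # even the path start exceeds k (cannot happen: start is 0)
        raise ValueError("no lambda on the grid has a selection of size <= k")
    target = int(counts[eligible].max())
    li = int(np.flatnonzero(eligible & (counts == target))[0])
    return np.flatnonzero(path.coef[:, li] != 0.0)
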