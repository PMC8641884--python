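"""In-memory containers shared across the package.

An :class:`ExpressionMatrix` is the cells x genes universe every stage
operates on; a :class:`CellAnnotation` carries the per-cell cluster label
from which the binary population-of-interest (POI) indicator is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["ExpressionMatrix", "CellAnnotation", "LabeledDataset"]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        seen: set = set()
        for x in ids:
            if x in seen:
                raise ValueError(f"duplicate {what} id: {x!r}")
            seen.add(x)


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with string identifiers.

    Parameters
    ----------
    values : ndarray or scipy sparse matrix, shape (n_cells, n_genes)
        Expression values. Counts are nonnegative; normalized log-scale
        values may be real.
    gene_ids : array-like of str
        Unique gene identifiers, one per column.
    cell_ids : array-like of str
        Unique cell identifiers (barcodes), one per row.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes matrix")
        n_cells, n_genes = self.values.shape
        if self.gene_ids is None:
            self.gene_ids = np.array([f"G{j}" for j in range(n_genes)], dtype=object)
        else:
            self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.cell_ids is None:
            self.cell_ids = np.array([f"C{i}" for i in range(n_cells)], dtype=object)
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} rows")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=df.columns.to_numpy(dtype=object),
            cell_ids=df.index.to_numpy(dtype=object),
        )

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        vals = self.values[:, idx]
        return ExpressionMatrix(vals, self.gene_ids[idx], self.cell_ids)

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        vals = self.values[idx, :]
        return ExpressionMatrix(vals, self.gene_ids, self.cell_ids[idx])


@dataclass
class CellAnnotation:
    """Per-cell cluster labels.

    Cluster identifiers are kept as strings throughout so that a cluster
    named ``"12"`` never silently collides with the integer ``12``.
    """

    cell_ids: np.ndarray
    cluster: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cluster = np.asarray([str(c) for c in self.cluster], dtype=object)
        if len(self.cell_ids) != len(self.cluster):
            raise ValueError("cell_ids and cluster must have equal length")
        _check_unique(self.cell_ids, "cell")

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def clusters(self) -> np.ndarray:
        """Distinct cluster labels in order of first appearance."""
        return pd.unique(self.cluster)

    def poi_indicator(self, poi_cluster) -> np.ndarray:
        """Binary y with 1 for cells in the designated POI cluster."""
        poi = str(poi_cluster)
        if poi not in set(self.cluster):
            raise ValueError(f"POI cluster {poi!r} not present among labels")
        return (self.cluster == poi).astype(int)

    def align_to(self, cell_ids) -> "CellAnnotation":
        """Reorder to match ``cell_ids``; error on missing cells."""
        order = pd.Index(self.cell_ids).get_indexer(np.asarray(cell_ids, dtype=object))
        missing = np.asarray(cell_ids, dtype=object)[order < 0]
        if missing.size:
            shown = ", ".join(map(str, missing[:10]))
            raise ValueError(
                f"{missing.size} cells missing from the annotation: {shown}"
            )
        return CellAnnotation(self.cell_ids[order], self.cluster[order])


@dataclass
class LabeledDataset:
    """A synthetic expression matrix with group (and optional subgroup) labels."""

    matrix: ExpressionMatrix
    group: np.ndarray
    subgroup: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=object)
        if len(self.group) != self.matrix.n_cells:
            raise ValueError("group length must equal the number of cells")
        if self.subgroup is not None:
            self.subgroup = np.asarray(self.subgroup, dtype=object)
            if len(self.subgroup) != self.matrix.n_cells:
                raise ValueError("subgroup length must equal the number of cells")

    @property
    def y(self) -> np.ndarray:
        """Binary indicator: 1 for group A (the population of interest)."""
        return (self.group == "A").astype(int)

    def annotation(self) -> CellAnnotation:
        return CellAnnotation(self.matrix.cell_ids, self.group)

    def labels_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"cell_id": self.matrix.cell_ids, "group": self.group}
        )
        df["subgroup"] = self.subgroup if self.subgroup is not None else ""
        return df
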