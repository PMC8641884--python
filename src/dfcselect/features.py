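"""Strong / Weak / Niche taxonomy of selected genes.

A selected gene is classified by the number of clusters in which it is
expressed (value > 0) in at least ``threshold`` (default 25%) of the
cluster's cells:

* **Strong** - expressed in 1 or 2 clusters: a conventional marker-like
  gene, specific to the population of interest or to one other population.
* **Weak**  - expressed in 3 or more clusters: discriminative only in
  combination with other genes.
* **Niche** - under the threshold in every cluster: marks a minor
  subpopulation within the population of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellAnnotation
from .pipeline import _as_matrix

__all__ = ["FeatureClassification", "expression_fraction", "classify_features"]

CLASSES = ("Strong", "Weak", "Niche")


def expression_fraction(matrix, cluster_labels) -> pd.DataFrame:
    """Per-gene, per-cluster fraction of cells with expression > 0.

    Returns a genes x clusters DataFrame with entries in [0, 1].
    """
    matrix = _as_matrix(matrix)
    if isinstance(cluster_labels, CellAnnotation):
        labels = cluster_labels.align_to(matrix.cell_ids).cluster
    else:
        labels = np.asarray([str(c) for c in np.asarray(cluster_labels)], dtype=object)
    if len(labels) != matrix.n_cells:
        raise ValueError("cluster labels must cover all cells")
    vals = matrix.dense()
    out = {}
    for c in pd.unique(labels):
        idx = labels == c
        if not idx.any():
            raise ValueError(f"cluster {c!r} is empty")
        out[c] = (vals[idx] > 0).mean(axis=0)
    return pd.DataFrame(out, index=matrix.gene_ids)


@dataclass
class FeatureClassification:
    """Per-gene expression fractions and the Strong/Weak/Niche labels."""

    fractions: pd.DataFrame
    labels: pd.Series
    n_above: pd.Series
    threshold: float

    def to_frame(self, weights: pd.Series | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene": self.labels.index,
                "class": self.labels.to_numpy(),
                "n_clusters_above_threshold": self.n_above.to_numpy(),
            }
        )
        if weights is not None:
            df["weight_sign"] = np.sign(weights.reindex(self.labels.index)).astype(int)
        return df

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(CLASSES, fill_value=0)


def classify_features(
    fractions: pd.DataFrame, dfc_genes=None, threshold: float = 0.25
) -> FeatureClassification:
    """Label genes Strong (1-2 clusters >= threshold), Weak (>= 3) or Niche (0).

    The boundary counts as expressed: a fraction of exactly ``threshold``
    is "25% or more" with the default.  Every gene gets exactly one label.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if dfc_genes is None:
        sub = fractions
    else:
        dfc_genes = list(dfc_genes)
        missing = [g for g in dfc_genes if g not in fractions.index]
        if missing:
            raise ValueError(f"unknown gene(s): {', '.join(map(str, missing[:10]))}")
        sub = fractions.loc[dfc_genes]
    n_above = (sub >= threshold).sum(axis=1)
    labels = pd.Series(
        np.where(n_above == 0, "Niche", np.where(n_above <= 2, "Strong", "Weak")),
        index=sub.index,
        name="class",
    )
    return FeatureClassification(
        fractions=sub, labels=labels, n_above=n_above, threshold=threshold
    )
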