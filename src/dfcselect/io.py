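"""Readers and writers for the standard exchange formats.

Expression matrices are read either from a dense TSV (cells in rows, first
column the cell id, header row the gene names) or from a MatrixMarket
triplet (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``).  MTX files
follow the CellRanger convention of genes as rows; the orientation is
auto-detected from the sidecar lengths and transposed to cells x genes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CellAnnotation, ExpressionMatrix, LabeledDataset

__all__ = [
    "read_expression",
    "read_clusters",
    "write_labeled_dataset",
    "write_expression",
    "save_fit_bundle",
]


def _read_ids(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_expression(
    path,
    fmt: str | None = None,
    features=None,
    barcodes=None,
) -> ExpressionMatrix:
    """Read a cells x genes expression matrix.

    ``fmt`` is ``"mtx"`` or ``"tsv"``; by default it is inferred from the
    file extension.  For MTX input the ``features``/``barcodes`` sidecar
    paths default to ``features.tsv`` and ``barcodes.tsv`` next to the
    matrix file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        # validate the raw header first: pandas would silently rename
        # duplicate gene columns (g1 -> g1.1)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        seen: set = set()
        for g in header:
            if g in seen:
                raise ValueError(f"duplicate gene id: {g!r}")
            seen.add(g)
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = header
        return ExpressionMatrix.from_frame(df)
    if fmt != "mtx":
        raise ValueError(f"unknown format {fmt!r}; expected 'mtx' or 'tsv'")

    features = path.with_name("features.tsv") if features is None else Path(features)
    barcodes = path.with_name("barcodes.tsv") if barcodes is None else Path(barcodes)
    gene_ids = _read_ids(features)
    cell_ids = _read_ids(barcodes)
    mat = scipy.io.mmread(path).tocsr()
    ng, nc = len(gene_ids), len(cell_ids)
    if mat.shape == (ng, nc):
        mat = mat.T.tocsr()  # genes-as-rows (CellRanger) -> cells x genes
    elif mat.shape == (nc, ng):
        pass
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {ng} features x {nc} barcodes "
            "nor its transpose"
        )
    return ExpressionMatrix(mat, gene_ids, cell_ids)


def read_clusters(path, cell_ids=None) -> CellAnnotation:
    """Read a two-column TSV of (cell_id, cluster), with or without header.

    When ``cell_ids`` is given, the annotation is realigned to that order
    and missing cells raise an error listing the first ten.
    """
    first = open(path).readline().split("\t")[0].strip().lower()
    header = 0 if first in {"cell_id", "cell", "barcode"} else None
    df = pd.read_csv(path, sep="\t", header=header, dtype=str)
    ann = CellAnnotation(
        df.iloc[:, 0].to_numpy(dtype=object), df.iloc[:, 1].to_numpy(dtype=object)
    )
    if cell_ids is not None:
        ann = ann.align_to(cell_ids)
    return ann


def write_expression(matrix: ExpressionMatrix, outdir, fmt: str = "tsv") -> None:
    """Write an expression matrix as dense TSV or as an MTX triplet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        df = matrix.to_frame()
        df.index.name = "cell_id"
        df.to_csv(outdir / "matrix.tsv", sep="\t")
    elif fmt == "mtx":
        vals = matrix.values
        spmat = sp.csr_matrix(vals) if not sp.issparse(vals) else vals.tocsr()
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), spmat.T.tocoo())  # genes x cells
        pd.Series(matrix.gene_ids).to_csv(
            outdir / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(matrix.cell_ids).to_csv(
            outdir / "barcodes.tsv", sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_labeled_dataset(dataset: LabeledDataset, outdir, fmt: str = "tsv") -> None:
    """Write a synthetic dataset: the matrix plus a labels.tsv sidecar."""
    outdir = Path(outdir)
    write_expression(dataset.matrix, outdir, fmt=fmt)
    dataset.labels_frame().to_csv(outdir / "labels.tsv", sep="\t", index=False)


def _sig6(x: float) -> float:
    return float(f"{x:.6g}")


def save_fit_bundle(extractor, outdir, extra: dict | None = None) -> None:
    """Serialize a fitted DFCExtractor: fit.json, path.tsv, dfc_genes.tsv.

    ``fit.json`` keeps full precision; the TSV reports round to six
    significant digits.
    """
    from .pipeline import DFCExtractor  # local import to avoid cycle

    if not isinstance(extractor, DFCExtractor):
        raise TypeError("save_fit_bundle expects a fitted DFCExtractor")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = extractor.model_
    bundle = {
        "params": extractor.get_params(),
        "lambda_grid": model.path_.lambdas.tolist(),
        "lambda_selected": model.lambda_selected_,
        "penalty_factors": [
            None if not np.isfinite(w) else w for w in model.penalty_factors_
        ],
        "ridge_alpha": model.ridge_.alpha,
        "cv_deviance_mean": None
        if model.cv_ is None
        else model.cv_.mean_deviance.tolist(),
        "cv_deviance_se": None if model.cv_ is None else model.cv_.se_deviance.tolist(),
        "intercept": extractor.intercept_,
        "genes": list(map(str, extractor.genes_)),
        "weights": extractor.weights_.tolist(),
        "entry_order": list(map(str, extractor.entry_genes_)),
        "n_cells_fit": int(extractor.subsample_idx_.size),
        "n_genes_universe": int(extractor.gene_universe_.size),
    }
    if extra:
        bundle.update(extra)
    (outdir / "fit.json").write_text(json.dumps(bundle, indent=1))

    path_df = pd.DataFrame(
        model.path_.coef,
        index=extractor.gene_universe_
        if extractor.sis_index_ is None or len(extractor.gene_universe_) == model.path_.coef.shape[0]
        else extractor.gene_universe_,
        columns=[f"{lam:.6g}" for lam in model.path_.lambdas],
    )
    path_df.index.name = "gene"
    path_df.map(_sig6).to_csv(outdir / "path.tsv", sep="\t")

    genes_df = extractor.result_.to_frame()
    genes_df["weight"] = genes_df["weight"].map(_sig6)
    genes_df.to_csv(outdir / "dfc_genes.tsv", sep="\t", index=False)
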