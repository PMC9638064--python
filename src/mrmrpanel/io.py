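"""Reading and writing expression matrices and cell annotations.

Two on-disk layouts are supported:

``mtx_triplet``
    10x-style: a Matrix Market coordinate file (1-based indices, genes as
    rows) with sibling ``features.tsv`` (gene ids) and ``barcodes.tsv``
    (cell ids).  Entries absent from the triplet file are zeros.
``dense_csv``
    Genes as rows, a header row of cell barcodes, first column gene ids.

The annotation table is a CSV with columns ``cell_id``, ``patient_id``,
``tissue`` (values ``tumor`` / ``normal``).  Cell order in the returned
dataset follows the annotation table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import ExpressionDataset, TISSUE_VALUES

logger = logging.getLogger(__name__)

FORMATS = ("mtx_triplet", "dense_csv")


def _mtx_paths(matrix_path: Path) -> tuple[Path, Path, Path]:
    """Resolve (matrix.mtx, features.tsv, barcodes.tsv) from a file or directory path."""
    matrix_path = Path(matrix_path)
    directory = matrix_path if matrix_path.is_dir() else matrix_path.parent
    mtx = matrix_path if matrix_path.suffix == ".mtx" else directory / "matrix.mtx"
    features = directory / "features.tsv"
    if not features.exists() and (directory / "genes.tsv").exists():
        features = directory / "genes.tsv"
    barcodes = directory / "barcodes.tsv"
    return mtx, features, barcodes


def read_dataset(
    matrix_path: str | Path,
    annotation_path: str | Path,
    format: str = "mtx_triplet",
) -> ExpressionDataset:
    """Read a genes x cells matrix plus its cell annotation table.

    Returns a raw (``normalized=False``) :class:`ExpressionDataset` whose cell
    order matches the annotation table.  Hard errors on matrix/annotation
    dimension mismatch, duplicate gene ids, and unknown tissue values.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")

    if format == "mtx_triplet":
        mtx, features, barcodes = _mtx_paths(Path(matrix_path))
        values = sp.csr_matrix(scipy.io.mmread(mtx))
        gene_ids = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
        cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    else:
        table = pd.read_csv(matrix_path, index_col=0)
        values = table.to_numpy()
        gene_ids = table.index.astype(str).tolist()
        cell_ids = table.columns.astype(str).tolist()

    ann = pd.read_csv(annotation_path, dtype=str)
    for col in ("cell_id", "patient_id", "tissue"):
        if col not in ann.columns:
            raise ValueError(f"annotation table lacks required column {col!r}")
    bad = set(ann["tissue"]) - set(TISSUE_VALUES)
    if bad:
        raise ValueError(f"unknown tissue values {sorted(bad)}; expected {TISSUE_VALUES}")

    if values.shape[0] != len(gene_ids):
        raise ValueError(
            f"matrix has {values.shape[0]} rows but {len(gene_ids)} gene ids"
        )
    if values.shape[1] != len(cell_ids) or len(ann) != len(cell_ids):
        raise ValueError(
            f"matrix has {values.shape[1]} columns, {len(cell_ids)} barcodes, "
            f"and {len(ann)} annotation rows; all three must agree"
        )
    if set(ann["cell_id"]) != set(cell_ids):
        raise ValueError("annotation cell_id set does not match matrix barcodes")

    # reorder matrix columns to the annotation order
    order = {c: i for i, c in enumerate(cell_ids)}
    col_order = np.array([order[c] for c in ann["cell_id"]], dtype=int)
    values = values[:, col_order]

    return ExpressionDataset(
        values=values,
        gene_ids=gene_ids,
        cell_ids=ann["cell_id"].tolist(),
        annotations=ann[["patient_id", "tissue"]].copy(),
        normalized=False,
    )


def write_dataset(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    annotation_path: str | Path,
    format: str = "mtx_triplet",
) -> None:
    """Write a dataset in a layout :func:`read_dataset` can read back.

    Integer counts round-trip exactly; normalized (float) values round-trip
    to Matrix Market's printed precision.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    matrix_path = Path(matrix_path)
    annotation_path = Path(annotation_path)
    annotation_path.parent.mkdir(parents=True, exist_ok=True)

    if format == "mtx_triplet":
        directory = matrix_path if matrix_path.suffix != ".mtx" else matrix_path.parent
        directory.mkdir(parents=True, exist_ok=True)
        mtx = matrix_path if matrix_path.suffix == ".mtx" else directory / "matrix.mtx"
        values = sp.coo_matrix(ds.values)
        field = "real" if ds.normalized else "integer"
        if field == "integer":
            values = values.astype(np.int64)
        scipy.io.mmwrite(mtx, values, field=field, precision=10)
        pd.Series(ds.gene_ids).to_csv(directory / "features.tsv", sep="\t",
                                      header=False, index=False)
        pd.Series(ds.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    else:
        matrix_path.parent.mkdir(parents=True, exist_ok=True)
        dense = ds.values.toarray() if sp.issparse(ds.values) else np.asarray(ds.values)
        if not ds.normalized:
            dense = dense.astype(np.int64)
        pd.DataFrame(dense, index=ds.gene_ids, columns=ds.cell_ids).to_csv(matrix_path)

    ann = ds.annotations.copy()
    ann.insert(0, "cell_id", ds.cell_ids)
    ann.to_csv(annotation_path, index=False)
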