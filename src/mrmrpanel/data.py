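"""Labelled single-cell expression matrices and their basic transformations.

The central container is :class:`ExpressionDataset`: a genes x cells matrix
(sparse or dense) plus a per-cell annotation table carrying the patient of
origin and the tissue label (``tumor`` / ``normal``).  Tumor is the positive
class everywhere in this package, so a true positive always means "tumor cell
called tumor".

Matrices are stored genes-as-rows, cells-as-columns.  Sparse inputs stay
sparse; per-gene operations may densify one gene row at a time but never the
whole matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

TISSUE_VALUES = ("tumor", "normal")
POSITIVE_TISSUE = "tumor"


@dataclass
class ExpressionDataset:
    """Genes x cells expression matrix with per-cell annotations.

    Parameters
    ----------
    values
        Matrix of shape ``(n_genes, n_cells)``.  Raw counts are non-negative
        integers; normalized values are non-negative reals.  May be a scipy
        sparse matrix or a dense ndarray.
    gene_ids
        Ordered, unique gene identifiers (the universe of genes considered).
    cell_ids
        Ordered, unique cell barcodes, aligned with matrix columns.
    annotations
        One row per cell (same order as ``cell_ids``) with columns
        ``patient_id`` and ``tissue`` (values ``tumor`` or ``normal``).
    normalized
        False for raw counts, True after :func:`normalize_counts`.
    """

    values: sp.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    annotations: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        dup = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene ids: {sorted(set(dup))}")
        required = {"patient_id", "tissue"}
        missing = required - set(self.annotations.columns)
        if missing:
            raise ValueError(f"annotation table lacks columns {sorted(missing)}")
        if len(self.annotations) != n_cells:
            raise ValueError(
                f"annotation table has {len(self.annotations)} rows for "
                f"{n_cells} matrix columns"
            )
        bad = set(self.annotations["tissue"]) - set(TISSUE_VALUES)
        if bad:
            raise ValueError(
                f"unknown tissue values {sorted(bad)}; expected one of {TISSUE_VALUES}"
            )
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        self.annotations = self.annotations.reset_index(drop=True)

    # -- basic properties -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Binary labels per cell; tumor (positive class) = 1, normal = 0."""
        return (self.annotations["tissue"].to_numpy() == POSITIVE_TISSUE).astype(int)

    @property
    def patients(self) -> list[str]:
        """Unique patient ids in order of first appearance."""
        return list(dict.fromkeys(self.annotations["patient_id"]))

    # -- views ------------------------------------------------------------

    def gene_index(self, gene_ids: list[str]) -> np.ndarray:
        """Integer row positions of the given genes; raises on missing ids."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def gene_row(self, i: int) -> np.ndarray:
        """Dense 1-D expression vector of gene row ``i``."""
        row = self.values[i]
        return row.toarray().ravel() if sp.issparse(row) else np.asarray(row).ravel()

    def expression_for(self, gene_ids: list[str]) -> np.ndarray:
        """Dense cells x genes matrix restricted to ``gene_ids`` (column order preserved)."""
        idx = self.gene_index(gene_ids)
        sub = self.values[idx, :]
        dense = sub.toarray() if sp.issparse(sub) else np.asarray(sub)
        return dense.T.astype(float)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionDataset(
            values=self.values[:, np.flatnonzero(mask)],
            gene_ids=self.gene_ids,
            cell_ids=[c for c, m in zip(self.cell_ids, mask) if m],
            annotations=self.annotations.loc[mask].reset_index(drop=True),
            normalized=self.normalized,
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionDataset(
            values=self.values[np.flatnonzero(mask), :],
            gene_ids=[g for g, m in zip(self.gene_ids, mask) if m],
            cell_ids=self.cell_ids,
            annotations=self.annotations,
            normalized=self.normalized,
        )


def normalize_counts(ds: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """Library-size normalize and log-transform raw counts.

    Each count ``c`` in a cell with total count ``S`` becomes
    ``log(1 + c * scale / S)``.  Cells with zero total count are dropped with
    a warning.  Zeros stay zeros, so sparsity is preserved.

    Raises
    ------
    ValueError
        If the dataset is already normalized.
    """
    if ds.normalized:
        raise ValueError("dataset is already normalized")
    if scale <= 0:
        raise ValueError("scale must be positive")

    X = ds.values
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=0)).ravel()
    else:
        totals = np.asarray(X, dtype=float).sum(axis=0)

    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d cells with zero total count", n_dropped)
        ds = ds.subset_cells(keep)
        totals = totals[keep]

    if sp.issparse(ds.values):
        norm = sp.csr_matrix(ds.values, dtype=float)
        # scale each column by scale/S, then log1p on stored entries only
        norm = norm @ sp.diags(scale / totals)
        norm = sp.csr_matrix(norm)
        np.log1p(norm.data, out=norm.data)
    else:
        norm = np.log1p(np.asarray(ds.values, dtype=float) * (scale / totals))

    return ExpressionDataset(
        values=norm,
        gene_ids=ds.gene_ids,
        cell_ids=ds.cell_ids,
        annotations=ds.annotations,
        normalized=True,
    )


def filter_genes(ds: ExpressionDataset, min_cells_frac: float = 0.01) -> ExpressionDataset:
    """Keep genes detected (value > 0) in at least ``ceil(min_cells_frac * n_cells)`` cells.

    Gene order is preserved.  Raises if every gene would be removed.
    """
    if not 0 <= min_cells_frac <= 1:
        raise ValueError("min_cells_frac must lie in [0, 1]")
    threshold = math.ceil(min_cells_frac * ds.n_cells)

    X = ds.values
    if sp.issparse(X):
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        detected = (np.asarray(X) > 0).sum(axis=1)
    keep = detected >= threshold
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError(
            f"gene filter at min_cells_frac={min_cells_frac} "
            f"(threshold {threshold} cells) removed all {ds.n_genes} genes"
        )
    logger.info(
        "gene filter: kept %d / %d genes (detected in >= %d of %d cells)",
        n_keep, ds.n_genes, threshold, ds.n_cells,
    )
    if n_keep == ds.n_genes:
        return ds
    return ds.subset_genes(keep)


def split_cohorts(
    ds: ExpressionDataset, train_patients: set[str]
) -> tuple[ExpressionDataset, dict[str, ExpressionDataset]]:
    """Partition cells into a training cohort and one validation cohort per remaining patient.

    Every cell lands in exactly one output; gene order is identical across all
    outputs.  A validation patient carrying only one tissue label triggers a
    warning (its per-patient MCC will be undefined downstream).
    """
    train_patients = set(train_patients)
    if not train_patients:
        raise ValueError("train_patients must be nonempty")
    known = set(ds.annotations["patient_id"])
    unknown = train_patients - known
    if unknown:
        raise ValueError(f"unknown patient ids: {sorted(unknown)}")

    pid = ds.annotations["patient_id"].to_numpy()
    train = ds.subset_cells(np.isin(pid, sorted(train_patients)))

    validation: dict[str, ExpressionDataset] = {}
    for p in ds.patients:
        if p in train_patients:
            continue
        sub = ds.subset_cells(pid == p)
        tissues = set(sub.annotations["tissue"])
        if len(tissues) < 2:
            logger.warning(
                "validation patient %s has only %s cells; "
                "per-patient MCC will be undefined", p, tissues.pop(),
            )
        validation[p] = sub
    return train, validation
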