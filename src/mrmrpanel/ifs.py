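"""Incremental feature selection with LOOCV-evaluated maximum-margin classifiers.

For each k = 1..K the top-k prefix S_k of the mRMR ranking is evaluated by
leave-one-out cross-validation of a linear soft-margin SVM (C = 1.0, no
class weighting) on the continuous normalized expression of those genes;
each fold refits the per-feature standardization on its own training cells
so no information from the held-out cell leaks into the model.  The curve of
Matthews correlation coefficients (MCC) over k is the IFS curve, and the
selected panel is the smallest k attaining the global maximum MCC — the
"few genes, high accuracy" peak.

MCC is used rather than accuracy because tumor/normal cell counts are
imbalanced: a majority-class predictor on 90/10 labels scores accuracy 0.9
but MCC 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .data import ExpressionDataset
from .mrmr import MrmrRanking

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN for one evaluation; positive class = tumor."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    @classmethod
    def from_labels(cls, actual: np.ndarray, predicted: np.ndarray) -> "ConfusionCounts":
        actual = np.asarray(actual, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        if actual.shape != predicted.shape:
            raise ValueError("actual and predicted must have equal length")
        return cls(
            tp=int(np.sum((actual == 1) & (predicted == 1))),
            tn=int(np.sum((actual == 0) & (predicted == 0))),
            fp=int(np.sum((actual == 0) & (predicted == 1))),
            fn=int(np.sum((actual == 1) & (predicted == 0))),
        )

    def as_dict(self) -> dict[str, int]:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with the
    convention that a zero denominator factor gives 0.  Exact integer
    arithmetic in the numerator and under the root.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


class PanelClassifier:
    """Linear SVM plus the per-feature standardization fitted on its training set.

    Falls back to a majority-class predictor when every standardized training
    row is identical (e.g. all-constant features), where a margin is undefined.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.majority_: int | None = None
        self.svm_: SVC | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PanelClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_
        if np.all(Xs == Xs[0]):
            counts = np.bincount(y, minlength=2)
            self.majority_ = int(np.argmax(counts))
            return self
        self.svm_ = SVC(kernel="linear", C=self.C)
        self.svm_.fit(Xs, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.majority_ is not None:
            return np.full(X.shape[0], self.majority_, dtype=int)
        if self.svm_ is None:
            raise RuntimeError("classifier is not fitted")
        Xs = (X - self.mean_) / self.scale_
        return self.svm_.predict(Xs).astype(int)


def fit_classifier(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> PanelClassifier:
    """Train a linear maximum-margin classifier on cells x features data.

    Standardization statistics are fitted on ``X`` only and travel with the
    model.  Raises on single-class ``y``.
    """
    return PanelClassifier(C=C).fit(X, y)


def loocv_predict(
    ds: ExpressionDataset,
    gene_set: list[str],
    labels: np.ndarray | None = None,
    C: float = 1.0,
) -> tuple[np.ndarray, ConfusionCounts]:
    """Leave-one-out cross-validated predictions on the given gene set.

    Exactly N fits: round r trains on all cells except r (standardization
    refit within the fold) and predicts cell r.  A fold whose training set
    is single-class predicts the training majority class, with a warning.
    Deterministic given its inputs.
    """
    y = ds.labels if labels is None else np.asarray(labels, dtype=int)
    N = ds.n_cells
    if N < 3:
        raise ValueError("LOOCV needs at least 3 cells")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    X = ds.expression_for(gene_set)

    predicted = np.empty(N, dtype=int)
    for r in range(N):
        mask = np.ones(N, dtype=bool)
        mask[r] = False
        y_train = y[mask]
        if np.unique(y_train).size < 2:
            maj = int(np.argmax(np.bincount(y_train, minlength=2)))
            warnings.warn(
                f"LOOCV fold {r}: single-class training set, predicting majority class",
                stacklevel=2,
            )
            predicted[r] = maj
            continue
        model = fit_classifier(X[mask], y_train, C=C)
        predicted[r] = int(model.predict(X[r:r + 1])[0])

    return predicted, ConfusionCounts.from_labels(y, predicted)


@dataclass
class IfsEntry:
    k: int
    gene_set: list[str]
    counts: ConfusionCounts
    mcc: float


@dataclass
class IfsCurve:
    """MCC over nested top-k gene prefixes (the incremental feature selection curve)."""

    entries: list[IfsEntry]

    @property
    def K(self) -> int:
        return len(self.entries)

    @property
    def mccs(self) -> np.ndarray:
        return np.array([e.mcc for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"k": e.k, "mcc": e.mcc, **e.counts.as_dict()}
                for e in self.entries
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def plot(self, path: str | Path) -> None:
        """Write the IFS curve (k vs MCC) with the selected peak marked."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        k_opt, _, mcc_opt = select_optimal_panel(self)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot([e.k for e in self.entries], self.mccs, marker="o", ms=3)
        ax.axvline(k_opt, color="crimson", ls="--", lw=1,
                   label=f"peak MCC {mcc_opt:.3f} at k={k_opt}")
        ax.set_xlabel("number of top-ranked genes (k)")
        ax.set_ylabel("LOOCV MCC")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_ifs_curve(
    ds: ExpressionDataset,
    ranking: MrmrRanking,
    K: int = 50,
    C: float = 1.0,
) -> IfsCurve:
    """Evaluate each nested prefix S_k, k = 1..K, by LOOCV and record counts + MCC."""
    if not 1 <= K <= len(ranking):
        raise ValueError(f"K={K} outside 1..{len(ranking)}")
    entries = []
    for k in range(1, K + 1):
        genes = ranking.top(k)
        _, counts = loocv_predict(ds, genes, C=C)
        entries.append(IfsEntry(k=k, gene_set=genes, counts=counts, mcc=mcc(counts)))
        logger.info("IFS k=%d/%d: MCC=%.4f", k, K, entries[-1].mcc)
    return IfsCurve(entries=entries)


def select_optimal_panel(curve: IfsCurve) -> tuple[int, list[str], float]:
    """Smallest k attaining the global maximum MCC — the final marker panel."""
    if not curve.entries:
        raise ValueError("IFS curve is empty")
    mccs = curve.mccs
    best = int(np.argmax(mccs))  # first occurrence -> smallest k on ties
    e = curve.entries[best]
    return e.k, e.gene_set, e.mcc
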