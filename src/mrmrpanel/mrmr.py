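"""Max-relevance min-redundancy (mRMR) gene ranking on discretized expression.

The ranking criterion is the difference form: at each greedy step, pick from
the remaining candidates Omega_t the gene g_j maximizing

    I(g_j, t)  -  (1/m) * sum over selected g_i of I(g_j, g_i)

where I is plug-in mutual information (in bits) over discretized expression
states, t is the binary tissue label, and m is the number of genes already
selected (the redundancy term vanishes at the first step).  Ties are broken
deterministically toward the lowest input gene index.

Discretization follows the three-state convention of the original mRMR work
on continuous features: per gene, values below mean - 0.5*sd map to -1,
above mean + 0.5*sd to +1, and 0 otherwise, with statistics pooled over all
cells (never per class, which would leak labels into the representation).

The greedy loop maintains incremental per-candidate redundancy sums, so each
step costs one new column of MI values instead of a full recomputation; only
(candidate, selected) MI pairs are ever evaluated, never the full gene x
gene matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class DiscretizedMatrix:
    """Per-gene ternary state codes used for mutual-information estimation.

    ``states`` is genes x cells with entries in {-1, 0, +1}; ``bin_edges``
    holds the per-gene (low, high) thresholds in normalized-expression units.
    Constant genes (sd = 0) map entirely to state 0.
    """

    states: np.ndarray
    gene_ids: list[str]
    bin_edges: np.ndarray  # (n_genes, 2), low <= high

    @property
    def n_genes(self) -> int:
        return self.states.shape[0]

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]


@dataclass
class MrmrRanking:
    """Result of the greedy mRMR loop.

    ``ranked_genes`` is the ordered list S; smaller rank index means better
    trade-off between label relevance and redundancy with the genes already
    selected.  ``relevance`` (bits) is indexed like the candidate input
    order; ``step_scores[r]`` is the criterion value of the gene picked at
    rank ``r`` at the moment of its selection.
    """

    ranked_genes: list[str]
    ranked_idx: np.ndarray
    relevance: np.ndarray
    step_scores: np.ndarray
    gene_ids: list[str]

    def __len__(self) -> int:
        return len(self.ranked_genes)

    def top(self, k: int) -> list[str]:
        """The nested top-k gene prefix S_k."""
        if not 1 <= k <= len(self):
            raise ValueError(f"k={k} outside 1..{len(self)}")
        return self.ranked_genes[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "gene_id": self.ranked_genes,
                "relevance_bits": self.relevance[self.ranked_idx],
                "step_score": self.step_scores,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ranking_tsv(path: str | Path) -> MrmrRanking:
    """Load a ranking written by :meth:`MrmrRanking.write_tsv`."""
    df = pd.read_csv(path, sep="\t")
    genes = df["gene_id"].astype(str).tolist()
    return MrmrRanking(
        ranked_genes=genes,
        ranked_idx=np.arange(len(genes)),
        relevance=df["relevance_bits"].to_numpy(),
        step_scores=df["step_score"].to_numpy(),
        gene_ids=genes,
    )


def discretize(ds: ExpressionDataset, sigma_factor: float = 0.5) -> DiscretizedMatrix:
    """Map normalized expression to ternary states at mean +/- sigma_factor * sd.

    Statistics are computed per gene over all cells pooled (both classes).
    Requires a normalized dataset.
    """
    if not ds.normalized:
        raise ValueError("discretize expects a normalized dataset")
    if sigma_factor < 0:
        raise ValueError("sigma_factor must be >= 0")

    n_genes, n_cells = ds.n_genes, ds.n_cells
    states = np.zeros((n_genes, n_cells), dtype=np.int8)
    bin_edges = np.zeros((n_genes, 2))
    for i in range(n_genes):
        row = ds.gene_row(i)
        mu = row.mean()
        sd = row.std()  # population sd; sd == 0 -> all state 0
        lo, hi = mu - sigma_factor * sd, mu + sigma_factor * sd
        bin_edges[i] = (lo, hi)
        if sd > 0:
            states[i, row < lo] = -1
            states[i, row > hi] = 1
    return DiscretizedMatrix(states=states, gene_ids=list(ds.gene_ids), bin_edges=bin_edges)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information between two integer state vectors, in bits.

    I = sum over observed joint states (a, b) of
    p(a,b) * log2[ p(a,b) / (p(a) p(b)) ]; empty joint cells contribute 0.
    Symmetric, and non-negative up to floating tolerance.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] == 0:
        raise ValueError("vectors must have length >= 1")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    """MI in bits from a joint count table (rows: x states, cols: y states)."""
    n = joint.sum()
    px = joint.sum(axis=1) / n
    py = joint.sum(axis=0) / n
    ix, iy = np.nonzero(joint)
    pxy = joint[ix, iy] / n
    return float(np.sum(pxy * np.log2(pxy / (px[ix] * py[iy]))))


def _codes(v: np.ndarray) -> np.ndarray:
    """Shift ternary {-1,0,1} states to {0,1,2} for bincount indexing."""
    return (v + 1).astype(np.intp)


def _mi_states_vs_binary(states: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """MI (bits) of each ternary state row with a binary 0/1 label vector."""
    lab = np.asarray(labels, dtype=np.intp)
    out = np.empty(states.shape[0])
    for i in range(states.shape[0]):
        joint = np.bincount(_codes(states[i]) * 2 + lab, minlength=6).reshape(3, 2)
        out[i] = _mi_from_joint(joint)
    return out


def _mi_one_vs_all(states: np.ndarray, j: int) -> np.ndarray:
    """MI (bits) of ternary state row j with every row of ``states``."""
    xj = _codes(states[j]) * 3
    out = np.empty(states.shape[0])
    for i in range(states.shape[0]):
        joint = np.bincount(xj + _codes(states[i]), minlength=9).reshape(3, 3)
        out[i] = _mi_from_joint(joint)
    return out


def relevance_scores(dm: DiscretizedMatrix, labels: np.ndarray) -> np.ndarray:
    """Per-gene relevance D = I(gene states, tissue label), in bits."""
    labels = np.asarray(labels)
    if labels.shape[0] != dm.n_cells:
        raise ValueError(
            f"labels length {labels.shape[0]} != cell count {dm.n_cells}"
        )
    return _mi_states_vs_binary(dm.states, labels)


def mrmr_rank(
    dm: DiscretizedMatrix,
    labels: np.ndarray,
    n_select: int,
    relevance: np.ndarray | None = None,
) -> MrmrRanking:
    """Greedy mRMR ranking of ``n_select`` genes.

    Step 1 picks the maximum-relevance gene (the redundancy term is absent
    while the selected set is empty); each later step picks the candidate
    maximizing relevance minus mean MI with the genes selected so far.
    Redundancy sums are maintained incrementally: selecting a gene adds one
    MI column over the remaining candidates.
    """
    if not 1 <= n_select <= dm.n_genes:
        raise ValueError(f"n_select={n_select} outside 1..{dm.n_genes}")
    rel = relevance_scores(dm, labels) if relevance is None else np.asarray(relevance, float)

    n = dm.n_genes
    red_sum = np.zeros(n)
    available = np.ones(n, dtype=bool)
    ranked_idx = np.empty(n_select, dtype=int)
    step_scores = np.empty(n_select)

    for step in range(n_select):
        scores = rel - red_sum / step if step else rel.copy()
        scores[~available] = -np.inf
        j = int(np.argmax(scores))  # ties -> lowest input index
        ranked_idx[step] = j
        step_scores[step] = scores[j]
        available[j] = False
        if step < n_select - 1:
            red_sum += _mi_one_vs_all(dm.states, j)

    return MrmrRanking(
        ranked_genes=[dm.gene_ids[j] for j in ranked_idx],
        ranked_idx=ranked_idx,
        relevance=rel,
        step_scores=step_scores,
        gene_ids=list(dm.gene_ids),
    )
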