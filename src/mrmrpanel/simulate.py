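"""Seeded two-class single-cell count simulator with known ground truth.

Emulates the structure that marker-panel discovery assumes in paired
tumor/normal single-cell data: several patients each contributing tumor and
normal cells, sparse overdispersed counts, a small set of truly
discriminative marker genes, one or more blocks of mutually redundant genes
co-expressed with a marker, and a large majority of uninformative genes.

Counts are negative binomial (the standard overdispersed scRNA-seq count
model) with a single global dispersion.  Redundant blocks copy a designated
marker's per-cell *latent mean* (with multiplicative lognormal noise) before
count sampling, so the redundancy survives count noise — exactly the
situation the min-redundancy penalty of mRMR exists for.  Patient effects
are a per-patient lognormal scaling of library size.  All randomness flows
from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import ExpressionDataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic two-class cohort.

    Defaults describe the reference condition used throughout the test
    suite: 8 patients x 200 cells per class, 500 genes of which 10 are
    markers with a 4-fold (log2FC = 2) tumor effect, and one 10-gene block
    cloned from the strongest marker.
    """

    n_patients: int = 8
    cells_per_patient_per_class: int = 200
    n_genes: int = 500
    n_markers: int = 10
    marker_log2fc: float = 2.0
    n_redundant_blocks: int = 1
    block_size: int = 10
    block_noise_sd: float = 0.2
    nb_mean_range: tuple[float, float] = (1.0, 20.0)
    nb_dispersion: float = 2.0
    dropout_extra: float = 0.05
    patient_effect_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.cells_per_patient_per_class < 1:
            raise ValueError("cells_per_patient_per_class must be >= 1")
        if self.n_markers < 0 or self.n_redundant_blocks < 0 or self.block_size < 0:
            raise ValueError("n_markers, n_redundant_blocks, block_size must be >= 0")
        if self.n_markers + self.n_redundant_blocks * self.block_size > self.n_genes:
            raise ValueError(
                "n_markers + n_redundant_blocks * block_size exceeds n_genes"
            )
        if self.n_redundant_blocks > 0 and self.n_markers == 0:
            raise ValueError("redundant blocks require at least one marker gene")
        lo, hi = self.nb_mean_range
        if not (0 < lo <= hi):
            raise ValueError("nb_mean_range must satisfy 0 < low <= high")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.dropout_extra < 1:
            raise ValueError("dropout_extra must lie in [0, 1)")
        if self.block_noise_sd < 0 or self.patient_effect_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """Generator bookkeeping used as a test oracle."""

    marker_gene_ids: list[str]
    block_membership: dict[str, int]  # block gene id -> block index
    block_source_marker: dict[int, str]  # block index -> marker gene id it clones
    labels: np.ndarray  # per cell, tumor = 1
    cells_per_patient: dict[str, int] = field(default_factory=dict)


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one seeded dataset from the generative model.

    Gene layout: marker genes first (baseline means sorted descending, so
    the first marker is the most expressed and, in practice, the most
    detectable one), then redundant-block genes (block ``b`` clones marker
    ``b mod n_markers``), then uninformative baseline genes.  Identical
    ``spec`` (including seed) gives a bit-identical dataset.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    G, P = spec.n_genes, spec.n_patients
    cpc = spec.cells_per_patient_per_class
    n_cells = P * 2 * cpc
    theta = spec.nb_dispersion

    # gene identities
    n_block_genes = spec.n_redundant_blocks * spec.block_size
    gene_ids = (
        [f"MARK{i + 1:03d}" for i in range(spec.n_markers)]
        + [
            f"BLK{b + 1:02d}_{j + 1:02d}"
            for b in range(spec.n_redundant_blocks)
            for j in range(spec.block_size)
        ]
        + [f"GENE{i + 1:04d}" for i in range(G - spec.n_markers - n_block_genes)]
    )

    # baseline means, log-uniform; marker means sorted descending
    lo, hi = spec.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    m = spec.n_markers
    base_mean[:m] = np.sort(base_mean[:m])[::-1]

    # cells: per patient, tumor block then normal block
    patient_ids, tissues, cell_ids = [], [], []
    for p in range(P):
        pid = f"P{p + 1}"
        for cls, tag in (("tumor", "T"), ("normal", "N")):
            patient_ids += [pid] * cpc
            tissues += [cls] * cpc
            cell_ids += [f"{pid}_{tag}{i + 1:04d}" for i in range(cpc)]
    labels = (np.array(tissues) == "tumor").astype(int)

    # expected per-cell means: baseline x tumor fold (markers) x patient library effect
    M = np.outer(base_mean, np.ones(n_cells))
    fold = 2.0 ** spec.marker_log2fc
    M[:m, labels == 1] *= fold
    patient_factor = rng.lognormal(mean=0.0, sigma=spec.patient_effect_sd, size=P)
    pidx = np.repeat(np.arange(P), 2 * cpc)
    M *= patient_factor[pidx][np.newaxis, :]

    # NB counts via the Gamma-Poisson mixture: the gamma draw is the per-cell
    # latent mean, so cell-to-cell biological variability is explicit and can
    # be shared by redundant-block genes.
    lam = rng.gamma(shape=theta, scale=M / theta)

    block_membership: dict[str, int] = {}
    block_source: dict[int, str] = {}
    for b in range(spec.n_redundant_blocks):
        src = b % m
        block_source[b] = gene_ids[src]
        for j in range(spec.block_size):
            g = m + b * spec.block_size + j
            noise = rng.lognormal(mean=0.0, sigma=spec.block_noise_sd, size=n_cells)
            lam[g, :] = lam[src, :] * noise
            block_membership[gene_ids[g]] = b

    counts = rng.poisson(lam)
    if spec.dropout_extra > 0:
        keep = rng.random(size=counts.shape) >= spec.dropout_extra
        counts = counts * keep

    values = sp.csr_matrix(counts.astype(np.int32))
    annotations = pd.DataFrame({"patient_id": patient_ids, "tissue": tissues})
    ds = ExpressionDataset(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        annotations=annotations,
        normalized=False,
    )
    truth = GroundTruth(
        marker_gene_ids=gene_ids[:m],
        block_membership=block_membership,
        block_source_marker=block_source,
        labels=labels,
        cells_per_patient={f"P{p + 1}": 2 * cpc for p in range(P)},
    )
    return ds, truth
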