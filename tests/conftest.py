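import numpy as np
import pandas as pd
import pytest

from mrmrpanel import (
    ExpressionDataset,
    SyntheticSpec,
    filter_genes,
    generate_dataset,
    normalize_counts,
    split_cohorts,
)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Scaled-down cohort: 3 patients x 40 cells/class, 80 genes, 5 markers."""
    return SyntheticSpec(
        n_patients=3,
        cells_per_patient_per_class=40,
        n_genes=80,
        n_markers=5,
        n_redundant_blocks=1,
        block_size=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_raw(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_prepared(small_raw):
    ds, truth = small_raw
    return filter_genes(normalize_counts(ds)), truth


@pytest.fixture(scope="session")
def small_train(small_prepared):
    ds, truth = small_prepared
    train, validation = split_cohorts(ds, {"P1"})
    return train, validation, truth


@pytest.fixture()
def tiny_dataset() -> ExpressionDataset:
    """Hand-written 3 genes x 4 cells raw dataset, 2 patients, balanced labels."""
    values = np.array(
        [
            [0, 5, 0, 2],
            [1, 0, 3, 0],
            [4, 4, 0, 1],
        ]
    )
    ann = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P2", "P2"],
            "tissue": ["tumor", "normal", "tumor", "normal"],
        }
    )
    return ExpressionDataset(
        values=values,
        gene_ids=["G1", "G2", "G3"],
        cell_ids=["c1", "c2", "c3", "c4"],
        annotations=ann,
    )


def make_normalized(values, labels=None, patients=None) -> ExpressionDataset:
    """Wrap a dense genes x cells float array as an already-normalized dataset."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    if labels is None:
        labels = [1] * (n_cells // 2) + [0] * (n_cells - n_cells // 2)
    tissue = ["tumor" if l == 1 else "normal" for l in labels]
    ann = pd.DataFrame(
        {
            "patient_id": patients if patients is not None else ["P1"] * n_cells,
            "tissue": tissue,
        }
    )
    return ExpressionDataset(
        values=values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{j}" for j in range(n_cells)],
        annotations=ann,
        normalized=True,
    )
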