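"""expression I/O, normalization, gene filtering and cohort splitting."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mrmrpanel import (
    ExpressionDataset,
    filter_genes,
    generate_dataset,
    normalize_counts,
    read_dataset,
    split_cohorts,
    write_dataset,
)
from mrmrpanel.simulate import SyntheticSpec


def _write_tiny_csv(tmp_path):
    matrix = tmp_path / "expr.csv"
    matrix.write_text(
        "gene,c1,c2,c3,c4\n"
        "G1,0,5,0,2\n"
        "G2,1,0,3,0\n"
        "G3,4,4,0,1\n"
    )
    ann = tmp_path / "ann.csv"
    ann.write_text(
        "cell_id,patient_id,tissue\n"
        "c1,P1,tumor\nc2,P1,normal\nc3,P2,tumor\nc4,P2,normal\n"
    )
    return matrix, ann


class TestReadDataset:
    def test_dense_csv_round_trip_of_handwritten_fixture(self, tmp_path):
        matrix, ann = _write_tiny_csv(tmp_path)
        ds = read_dataset(matrix, ann, format="dense_csv")
        assert (ds.n_genes, ds.n_cells) == (3, 4)
        assert ds.gene_ids == ["G1", "G2", "G3"]
        assert list(ds.annotations["patient_id"]) == ["P1", "P1", "P2", "P2"]
        assert list(ds.labels) == [1, 0, 1, 0]
        assert not ds.normalized

    def test_mtx_triplet_absent_entries_are_zeros(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            "3 4 2\n"
            "1 2 5\n"
            "3 1 4\n"
        )
        (tmp_path / "features.tsv").write_text("G1\nG2\nG3\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\nc3\nc4\n")
        ann = tmp_path / "ann.csv"
        ann.write_text(
            "cell_id,patient_id,tissue\n"
            "c1,P1,tumor\nc2,P1,normal\nc3,P2,tumor\nc4,P2,normal\n"
        )
        ds = read_dataset(tmp_path, ann, format="mtx_triplet")
        dense = ds.values.toarray()
        assert dense[0, 1] == 5 and dense[2, 0] == 4
        assert (dense == 0).sum() == 10  # 12 entries, 2 nonzero

    @pytest.mark.parametrize("fmt", ["mtx_triplet", "dense_csv"])
    def test_write_then_read_reproduces_counts_exactly(self, tmp_path, fmt):
        ds, _ = generate_dataset(
            SyntheticSpec(n_patients=2, cells_per_patient_per_class=10,
                          n_genes=30, n_markers=3, n_redundant_blocks=0,
                          block_size=0, seed=11)
        )
        matrix = tmp_path / ("out" if fmt == "mtx_triplet" else "out.csv")
        ann = tmp_path / "ann.csv"
        write_dataset(ds, matrix, ann, format=fmt)
        back = read_dataset(matrix, ann, format=fmt)
        a = ds.values.toarray() if sp.issparse(ds.values) else ds.values
        b = back.values.toarray() if sp.issparse(back.values) else back.values
        np.testing.assert_array_equal(a, b)
        assert back.gene_ids == ds.gene_ids
        assert back.cell_ids == ds.cell_ids
        pd.testing.assert_frame_equal(back.annotations, ds.annotations)

    def test_dimension_mismatch_names_both_counts(self, tmp_path):
        matrix, _ = _write_tiny_csv(tmp_path)
        bad = tmp_path / "bad.csv"
        bad.write_text("cell_id,patient_id,tissue\nc1,P1,tumor\nc2,P1,normal\n")
        with pytest.raises(ValueError, match="4 columns.*2 annotation"):
            read_dataset(matrix, bad, format="dense_csv")

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        matrix = tmp_path / "expr.csv"
        matrix.write_text("gene,c1,c2\nG1,1,2\nG1,3,4\n")
        ann = tmp_path / "ann.csv"
        ann.write_text("cell_id,patient_id,tissue\nc1,P1,tumor\nc2,P1,normal\n")
        with pytest.raises(ValueError, match="duplicate.*G1"):
            read_dataset(matrix, ann, format="dense_csv")

    def test_unknown_tissue_value_rejected(self, tmp_path):
        matrix, _ = _write_tiny_csv(tmp_path)
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "cell_id,patient_id,tissue\n"
            "c1,P1,tumor\nc2,P1,stroma\nc3,P2,tumor\nc4,P2,normal\n"
        )
        with pytest.raises(ValueError, match="stroma"):
            read_dataset(matrix, bad, format="dense_csv")


class TestNormalize:
    def test_zero_total_cell_dropped_with_warning(self, caplog):
        ds = ExpressionDataset(
            values=np.array([[0, 2], [0, 3]]),
            gene_ids=["G1", "G2"],
            cell_ids=["c1", "c2"],
            annotations=pd.DataFrame(
                {"patient_id": ["P1", "P1"], "tissue": ["tumor", "normal"]}
            ),
        )
        with caplog.at_level("WARNING"):
            norm = normalize_counts(ds)
        assert norm.n_cells == 1 and norm.cell_ids == ["c2"]
        assert "zero total" in caplog.text

    def test_exact_values_against_scalar_formula(self):
        # equal raw count 10; the smaller-library cell gets the larger value
        ds = ExpressionDataset(
            values=np.array([[10, 10], [90, 190]]),
            gene_ids=["G1", "G2"],
            cell_ids=["c1", "c2"],
            annotations=pd.DataFrame(
                {"patient_id": ["P1", "P1"], "tissue": ["tumor", "normal"]}
            ),
        )
        norm = normalize_counts(ds, scale=1e4)
        v = np.asarray(norm.values)
        assert v[0, 0] == pytest.approx(math.log(1 + 10 * 1e4 / 100), rel=1e-12)
        assert v[0, 1] == pytest.approx(math.log(1 + 10 * 1e4 / 200), rel=1e-12)
        assert v[0, 0] > v[0, 1]

    def test_zero_count_stays_zero_and_sparsity_preserved(self, small_raw):
        ds, _ = small_raw
        norm = normalize_counts(ds)
        assert sp.issparse(norm.values)
        assert norm.values.nnz == ds.values.nnz
        assert norm.normalized

    def test_double_normalization_is_an_error(self, tiny_dataset):
        norm = normalize_counts(tiny_dataset)
        with pytest.raises(ValueError, match="already normalized"):
            normalize_counts(norm)

    def test_normalization_preserves_within_cell_order(self, tiny_dataset):
        norm = normalize_counts(tiny_dataset)
        raw = np.asarray(tiny_dataset.values, dtype=float)
        new = np.asarray(norm.values)
        for j in range(raw.shape[1]):
            assert list(np.argsort(raw[:, j], kind="stable")) == list(
                np.argsort(new[:, j], kind="stable")
            )


class TestFilterGenes:
    def test_zero_threshold_is_identity(self, tiny_dataset):
        out = filter_genes(tiny_dataset, min_cells_frac=0.0)
        assert out.gene_ids == tiny_dataset.gene_ids

    def test_single_detection_boundary_kept_at_one_percent(self):
        values = np.zeros((2, 100), dtype=int)
        values[0, 17] = 3  # detected in exactly 1 of 100 cells: ceil(0.01*100)=1
        values[1, :] = 1
        ann = pd.DataFrame(
            {"patient_id": ["P1"] * 100,
             "tissue": ["tumor"] * 50 + ["normal"] * 50}
        )
        ds = ExpressionDataset(values, ["G1", "G2"],
                               [f"c{i}" for i in range(100)], ann)
        out = filter_genes(ds, min_cells_frac=0.01)
        assert out.gene_ids == ["G1", "G2"]

    def test_survivors_match_bruteforce_recount(self, small_raw):
        ds, _ = small_raw
        frac = 0.1
        out = filter_genes(ds, min_cells_frac=frac)
        dense = ds.values.toarray()
        expected = [
            g
            for g, row in zip(ds.gene_ids, dense)
            if (row > 0).sum() >= math.ceil(frac * ds.n_cells)
        ]
        assert out.gene_ids == expected

    def test_all_genes_removed_is_an_error(self):
        ann = pd.DataFrame({"patient_id": ["P1"] * 3,
                            "tissue": ["tumor", "normal", "normal"]})
        ds = ExpressionDataset(np.zeros((2, 3), dtype=int), ["G1", "G2"],
                               ["c1", "c2", "c3"], ann)
        with pytest.raises(ValueError, match="removed all"):
            filter_genes(ds, min_cells_frac=0.5)


class TestSplitCohorts:
    def test_all_patients_in_training_gives_empty_validation(self, small_prepared):
        ds, _ = small_prepared
        train, val = split_cohorts(ds, set(ds.patients))
        assert val == {}
        assert train.n_cells == ds.n_cells

    def test_partition_conserves_cells_and_barcodes(self, small_prepared):
        ds, _ = small_prepared
        train, val = split_cohorts(ds, {"P1"})
        assert set(val) == {"P2", "P3"}
        parts = [train] + list(val.values())
        assert sum(p.n_cells for p in parts) == ds.n_cells
        barcodes = [c for p in parts for c in p.cell_ids]
        assert len(barcodes) == len(set(barcodes))
        for p in parts:
            assert p.gene_ids == ds.gene_ids

    def test_split_counts_match_generator_bookkeeping(self, small_prepared):
        ds, truth = small_prepared
        train, val = split_cohorts(ds, {"P1"})
        assert train.n_cells == truth.cells_per_patient["P1"]
        for pid, sub in val.items():
            assert sub.n_cells == truth.cells_per_patient[pid]

    def test_unknown_patient_is_an_error(self, small_prepared):
        ds, _ = small_prepared
        with pytest.raises(ValueError, match="P99"):
            split_cohorts(ds, {"P99"})

    def test_single_tissue_validation_patient_warns(self, caplog):
        ann = pd.DataFrame(
            {
                "patient_id": ["P1", "P1", "P2", "P2"],
                "tissue": ["tumor", "normal", "tumor", "tumor"],
            }
        )
        ds = ExpressionDataset(np.ones((2, 4), dtype=int), ["G1", "G2"],
                               ["c1", "c2", "c3", "c4"], ann)
        with caplog.at_level("WARNING"):
            split_cohorts(ds, {"P1"})
        assert "P2" in caplog.text
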