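"""Cohort-level validation of a selected panel and the end-to-end pipeline.

The validation protocol mirrors a single-training-patient design: one
classifier is fitted once on the full training cohort restricted to the
panel genes, then applied unchanged to every held-out patient.  The report
carries per-patient and pooled confusion matrices (the pooled matrix is the
element-wise sum of the per-patient ones) plus training-resubstitution
counts, the panel, the configuration snapshot and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .data import ExpressionDataset, filter_genes, normalize_counts, split_cohorts
from .ifs import ConfusionCounts, IfsCurve, build_ifs_curve, fit_classifier, mcc, select_optimal_panel
from .mrmr import MrmrRanking, discretize, mrmr_rank
from .simulate import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PatientResult:
    patient_id: str
    counts: ConfusionCounts
    mcc: float


@dataclass
class CohortReport:
    """Validation outcome of one panel across training and validation cohorts."""

    panel: list[str]
    training_counts: ConfusionCounts
    training_mcc: float
    per_patient: list[PatientResult]
    pooled_counts: ConfusionCounts
    pooled_mcc: float | None
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "training": {**self.training_counts.as_dict(), "mcc": self.training_mcc},
            "per_patient": [
                {"patient_id": r.patient_id, **r.counts.as_dict(), "mcc": r.mcc}
                for r in self.per_patient
            ],
            "pooled": {**self.pooled_counts.as_dict(), "mcc": self.pooled_mcc},
            "config": self.config,
            "seed": self.seed,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortReport":
        d = json.loads(Path(path).read_text())

        def counts(block: dict) -> ConfusionCounts:
            return ConfusionCounts(block["TP"], block["TN"], block["FP"], block["FN"])

        return cls(
            panel=list(d["panel"]),
            training_counts=counts(d["training"]),
            training_mcc=d["training"]["mcc"],
            per_patient=[
                PatientResult(p["patient_id"], counts(p), p["mcc"])
                for p in d["per_patient"]
            ],
            pooled_counts=counts(d["pooled"]),
            pooled_mcc=d["pooled"]["mcc"],
            config=d.get("config", {}),
            seed=d.get("seed"),
        )


def validate_panel(
    train: ExpressionDataset,
    validation: dict[str, ExpressionDataset],
    panel: list[str],
    C: float = 1.0,
    config: dict | None = None,
    seed: int | None = None,
) -> CohortReport:
    """Fit once on the training cohort, apply unchanged to each validation patient.

    A validation patient whose cells carry only one tissue label gets MCC
    reported as 0 (undefined-by-convention) with a warning.  Missing panel
    genes in any dataset are a hard error listing them.
    """
    if not panel:
        raise ValueError("panel is empty")
    for name, ds in [("training", train)] + [(p, d) for p, d in validation.items()]:
        missing = sorted(set(panel) - set(ds.gene_ids))
        if missing:
            raise ValueError(f"panel genes missing from {name} dataset: {missing}")

    model = fit_classifier(train.expression_for(panel), train.labels, C=C)

    train_pred = model.predict(train.expression_for(panel))
    training_counts = ConfusionCounts.from_labels(train.labels, train_pred)

    per_patient: list[PatientResult] = []
    pooled = ConfusionCounts()
    for pid, ds in validation.items():
        pred = model.predict(ds.expression_for(panel))
        counts = ConfusionCounts.from_labels(ds.labels, pred)
        pooled = pooled + counts
        if np.unique(ds.labels).size < 2:
            warnings.warn(
                f"validation patient {pid} has a single tissue class; "
                "MCC reported as 0 by convention", stacklevel=2,
            )
            patient_mcc = 0.0
        else:
            patient_mcc = mcc(counts)
        per_patient.append(PatientResult(pid, counts, patient_mcc))

    pooled_mcc = mcc(pooled) if pooled.total else None
    return CohortReport(
        panel=list(panel),
        training_counts=training_counts,
        training_mcc=mcc(training_counts),
        per_patient=per_patient,
        pooled_counts=pooled,
        pooled_mcc=pooled_mcc,
        config=config or {},
        seed=seed,
    )


def embed_cells_qc(
    ds: ExpressionDataset,
    panel: list[str],
    predicted: np.ndarray,
    actual: np.ndarray,
    seed: int,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """Seeded 2-D t-SNE of panel-restricted expression, for visual QC of calls.

    Returns one row per cell with columns ``tsne1``, ``tsne2``,
    ``predicted``, ``actual`` so false calls can be plotted against true
    ones.  Purely a visualization aid: no numeric contract on coordinates.
    """
    from sklearn.manifold import TSNE

    if not panel:
        raise ValueError("panel is empty")
    if ds.n_cells <= 3 * perplexity:
        raise ValueError(
            f"{ds.n_cells} cells is too few for perplexity={perplexity}; "
            "pass a smaller perplexity"
        )
    X = ds.expression_for(panel)
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(X)
    return pd.DataFrame(
        {
            "tsne1": coords[:, 0],
            "tsne2": coords[:, 1],
            "predicted": np.asarray(predicted, dtype=int),
            "actual": np.asarray(actual, dtype=int),
        },
        index=pd.Index(ds.cell_ids, name="cell_id"),
    )


@dataclass
class PipelineConfig:
    """Declarative run configuration; every convention the method leaves open
    (normalization, discretization width, SVM cost, list length K) surfaces here."""

    # input: either file paths ...
    matrix_path: str | None = None
    annotation_path: str | None = None
    input_format: str = "mtx_triplet"
    # ... or a synthetic cohort
    synthetic: SyntheticSpec | None = None

    train_patients: list[str] = field(default_factory=list)
    normalize: bool = True
    scale: float = 1e4
    min_cells_frac: float = 0.01
    sigma_factor: float = 0.5
    top_n: int = 50
    K: int = 50
    svm_C: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
            d["synthetic"]["nb_mean_range"] = list(self.synthetic.nb_mean_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            if "nb_mean_range" in syn:
                syn["nb_mean_range"] = tuple(syn["nb_mean_range"])
            syn = SyntheticSpec(**syn)
        return cls(synthetic=syn, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _load_input(config: PipelineConfig) -> ExpressionDataset:
    if config.synthetic is not None:
        ds, _ = generate_dataset(config.synthetic)
        return ds
    if config.matrix_path is None or config.annotation_path is None:
        raise ValueError("config must name input files or a synthetic spec")
    return mio.read_dataset(config.matrix_path, config.annotation_path,
                            format=config.input_format)


def prepare_dataset(config: PipelineConfig) -> ExpressionDataset:
    """Load (or generate), normalize and gene-filter the input dataset."""
    ds = _load_input(config)
    if config.normalize:
        ds = normalize_counts(ds, scale=config.scale)
    ds = filter_genes(ds, min_cells_frac=config.min_cells_frac)
    return ds


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> CohortReport:
    """Execute the full discovery pipeline and write all artifacts.

    Stages: load/generate -> normalize -> filter -> split cohorts ->
    discretize -> mRMR rank -> IFS curve (LOOCV) -> peak panel selection ->
    cross-patient validation.  Writes ranking.tsv, ifs_curve.tsv, panel.tsv,
    ifs_curve.png and report.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    stage("load")
    ds = prepare_dataset(config)

    stage("split")
    train_patients = set(config.train_patients) or {ds.patients[0]}
    train, validation = split_cohorts(ds, train_patients)

    stage("discretize + mRMR rank")
    dm = discretize(train, sigma_factor=config.sigma_factor)
    n_select = min(config.top_n, dm.n_genes)
    ranking = mrmr_rank(dm, train.labels, n_select=n_select)
    ranking.write_tsv(outdir / "ranking.tsv")

    stage("IFS (LOOCV)")
    K = min(config.K, len(ranking))
    curve = build_ifs_curve(train, ranking, K=K, C=config.svm_C)
    curve.write_tsv(outdir / "ifs_curve.tsv")
    try:
        curve.plot(outdir / "ifs_curve.png")
    except Exception as exc:  # plotting is best-effort, never fatal
        logger.warning("IFS plot failed: %s", exc)

    stage("panel selection")
    k_opt, panel, mcc_opt = select_optimal_panel(curve)
    logger.info("selected panel: k=%d, LOOCV MCC=%.4f", k_opt, mcc_opt)
    panel_frame = ranking.to_frame().head(k_opt)
    panel_frame.to_csv(outdir / "panel.tsv", sep="\t", index=False, float_format="%.10g")

    stage("validation")
    report = validate_panel(
        train, validation, panel, C=config.svm_C,
        config=config.to_dict(), seed=config.seed,
    )
    report.write_json(outdir / "report.json")
    return report
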