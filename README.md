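# mrmrpanel

Marker-panel discovery for two-class single-cell expression data.

`mrmrpanel` finds a small panel of genes that separates two cell
populations — the motivating use case is distinguishing tumor cells from
normal cells in paired single-cell RNA-seq cohorts (e.g. hepatocellular
carcinoma vs. adjacent normal liver) — and validates the panel on held-out
patients. It is aimed at computational biologists who have a labelled
gene × cell count matrix and want a compact, classifier-backed gene
signature rather than a long differential-expression list.

## Method

Given a training cohort with binary tissue labels *t* (tumor = positive
class):

1. **Normalization and discretization.** Counts are library-size
   normalized to 10⁴ per cell and log1p-transformed. For mutual-information
   estimation each gene is discretized into three states at
   μ ± 0.5σ (statistics pooled over all cells).

2. **mRMR ranking (max-relevance, min-redundancy).** Genes are ranked
   greedily. Relevance of gene *g* is *D* = *I*(*g*, *t*), the mutual
   information between its discretized expression and the label; redundancy
   is *R* = (1/*m*) Σ<sub>*g<sub>i</sub>* ∈ Ω<sub>s</sub></sub> *I*(*g*, *g<sub>i</sub>*), the mean MI with the *m*
   genes already selected. Each step picks

   max<sub>*g<sub>j</sub>* ∈ Ω<sub>t</sub></sub> [ *I*(*g<sub>j</sub>*, *t*) − (1/*m*) Σ<sub>*g<sub>i</sub>* ∈ Ω<sub>s</sub></sub> *I*(*g<sub>j</sub>*, *g<sub>i</sub>*) ]

   so blocks of co-expressed, mutually redundant genes contribute one
   representative instead of crowding the list.

3. **Incremental feature selection (IFS) with LOOCV.** For each prefix
   S<sub>k</sub> of the ranking (k = 1..K, default K = 50) a linear SVM
   (C = 1) is evaluated by leave-one-out cross-validation — N fits, each
   refitting feature standardization on its own training fold — and scored
   by the Matthews correlation coefficient

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

   which stays honest under tumor/normal class imbalance (a majority-class
   predictor has accuracy 0.9 on 90/10 labels but MCC 0).

4. **Peak selection and validation.** The panel is the smallest k reaching
   the global maximum of the MCC-vs-k curve. One classifier is then fitted
   on the full training cohort and applied unchanged to every held-out
   patient, yielding per-patient and pooled confusion matrices.

A seeded negative-binomial (Gamma–Poisson) simulator generates cohorts with
known ground truth — planted markers, a redundant co-expressed block, and
patient-level library effects — so the whole pipeline is testable without
any external dataset.

## Worked example

```python
from mrmrpanel import (SyntheticSpec, generate_dataset, normalize_counts,
                       filter_genes, split_cohorts, discretize, mrmr_rank,
                       build_ifs_curve, select_optimal_panel, validate_panel)

spec = SyntheticSpec(seed=0)          # 8 patients, 200 cells/class, 500 genes
ds, truth = generate_dataset(spec)    # 10 markers at log2FC=2 + 10-gene block
ds = filter_genes(normalize_counts(ds))
train, validation = split_cohorts(ds, {"P1"})

dm = discretize(train)
ranking = mrmr_rank(dm, train.labels, n_select=50)
curve = build_ifs_curve(train, ranking, K=50)     # LOOCV over 400 cells
k_opt, panel, mcc_opt = select_optimal_panel(curve)
print(k_opt, round(mcc_opt, 4))
# 18 0.9651

report = validate_panel(train, validation, panel)
print(round(report.pooled_mcc, 3),
      [round(r.mcc, 3) for r in report.per_patient])
# 0.904 [0.906, 0.91, 0.893, 0.916, 0.888, 0.912, 0.904]
```

The selected 18-gene panel reaches LOOCV MCC 0.965 on the training patient
and MCC ≈ 0.89–0.92 on each of the seven held-out patients; 10/10 planted
markers sit in the mRMR top 20, while the redundant block — whose genes
dominate a relevance-only top 10 — is almost entirely suppressed.

The same run from a shell:

```bash
mrmrpanel run --seed 0 --outdir out/          # writes ranking.tsv,
                                              # ifs_curve.tsv (+ .png),
                                              # panel.tsv, report.json
```

`report.json` schema: `panel` (gene list), `training` and `pooled`
(`TP/TN/FP/FN/mcc`), `per_patient` (one such block per held-out patient),
`config` (full run configuration snapshot), `seed`. Pooled counts are the
element-wise sum of the per-patient counts.

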