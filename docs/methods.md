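# Methods

This note documents the models, conventions and numerical choices behind
`mrmrpanel`, including the places where the procedure is a design decision
rather than a forced consequence of the method.

## Problem setting

Input is a genes × cells expression matrix with per-cell annotations:
patient of origin and a binary tissue label (`tumor` / `normal`; tumor is
the positive class throughout, so TP always means "tumor cell called
tumor"). One patient (or a set of patients) serves as the training cohort;
every remaining patient is a separate validation cohort. Patients whose
cells carry only one tissue label are flagged at split time — their
per-patient MCC is undefined and is reported as 0 by convention, with a
warning, to keep reports machine-readable.

## Preprocessing

- **Normalization** (default on, configurable off): each count *c* in a
  cell with library size *S* becomes log(1 + c·10⁴/S). This is the
  dominant convention for droplet scRNA-seq counts; the method itself does
  not dictate a normalization, so the choice is exposed in the run
  configuration. Cells with zero total count are dropped with a warning.
  Zeros map to zeros, so sparse matrices stay sparse end to end; per-gene
  operations densify one gene row at a time, never the whole matrix.
- **Gene filter** (default 1% of cells, configurable): genes detected in
  fewer than ⌈frac · n_cells⌉ cells are removed before ranking. Ranking
  tens of thousands of all-zero genes is wasted work and adds nothing but
  MI noise-floor candidates.

## Discretization and mutual information

The MI estimator needs discrete states. Each gene is mapped to three
states using its pooled mean μ and population σ over *all* training cells:
state −1 below μ − 0.5σ, +1 above μ + 0.5σ, 0 between. This is the
three-state convention of the classic mRMR literature for continuous
features; the 0.5 width (`sigma_factor`) is configurable. Two deliberate
constraints:

- Statistics are pooled over both classes. Computing them per class would
  leak the labels into the representation.
- A constant gene (σ = 0) maps entirely to state 0 and therefore has MI 0
  with everything.

MI is the plug-in estimate I = Σ p(a,b) log₂[p(a,b)/(p(a)p(b))] over the
observed joint histogram, in bits. The base is irrelevant to any ranking
(it rescales relevance and redundancy equally) but is fixed so that
reported step scores are reproducible. No bias correction is applied; the
plug-in estimator's positive bias affects all candidate genes equally and
the greedy criterion compares differences.

## mRMR ranking

Greedy difference-form criterion: step 1 picks the maximum-relevance gene
(the redundancy term vanishes while the selected set is empty); each later
step picks argmax over remaining candidates of relevance minus mean MI
with the already-selected genes. The quotient variant of the criterion is
intentionally not implemented.

Implementation notes:

- Per-candidate redundancy sums are maintained incrementally — selecting a
  gene adds one MI column over the remaining candidates — so a ranking of
  n_select genes costs n_select MI columns, not a gene × gene matrix. A
  from-scratch reference implementation exists in the test suite and the
  two are verified to produce identical permutations on random instances.
- Ties in the criterion break deterministically toward the lowest input
  gene index. Consequently, permuting input gene order can permute exactly
  tied ranks; this is documented rather than hidden.

## IFS, LOOCV and MCC

For k = 1..K (default K = 50, matching the ranking length) the top-k
prefix is evaluated by leave-one-out cross-validation: exactly N fits,
fold r training on all cells but r. The classifier is a linear soft-margin
SVM, C = 1, no class weights, consuming the *continuous* normalized
expression of the prefix genes (discretization exists only for MI
estimation). Per-feature standardization (mean/sd) is refit inside every
fold so the held-out cell never influences the scaling. Degenerate fits
(all standardized training rows identical, e.g. all-constant features)
fall back to a majority-class predictor; a fold whose training set is
single-class predicts the training majority with a warning. These choices
are the smallest deterministic assumption set for high-dimensional
expression panels; kernel, cost and K are all exposed in the
configuration.

MCC is computed with exact integer arithmetic in the numerator and under
the square root; any zero denominator factor yields 0 by the usual
convention. The panel is the smallest k attaining the global maximum of
the curve (ties → smaller k), encoding the "fewest genes at peak
performance" rule.

### Known optimism of LOOCV inside IFS

The ranking is computed once on the full training cohort, *including*
every cell that LOOCV later holds out. Feature selection outside the
cross-validation loop biases LOOCV performance upward (the classic
selection-bias result of Ambroise & McLachlan, 2002), and peak selection
additionally takes a maximum over K correlated estimates. On null cohorts
with no planted effect this inflates the selected panel's LOOCV MCC to
roughly 0.15–0.26 at 200 cells/class and 500 genes (growing with K), even
though per-gene association is pure noise. The cross-patient validation
MCC, computed on cells the selection never saw, stays at |MCC| ≤ ~0.04
under the same null and is the honest generalization estimate. This is a
property of the protocol being implemented, preserved deliberately;
sweeping it under a nested cross-validation would change the method.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: several
patients, paired tumor/normal cells per patient, sparse overdispersed
counts, a few truly discriminative genes, one or more redundant blocks,
and many uninformative genes.

Model, per gene g and cell c:

- Baseline mean m_g ~ log-uniform on `nb_mean_range`. Marker genes get
  their mean multiplied by 2^`marker_log2fc` in tumor cells. Marker
  baseline means are sorted descending, so the first marker is the most
  expressed (and in practice the most detectable); the default single
  block therefore clones the strongest marker.
- Counts are negative binomial via the explicit Gamma–Poisson mixture:
  λ_gc ~ Gamma(shape = θ, mean = m_gc), count ~ Poisson(λ_gc), with a
  single global dispersion θ (`nb_dispersion`). The gamma draw is the
  per-cell latent mean.
- Each redundant-block gene copies its source marker's *realized* latent
  λ, times per-cell lognormal noise (sd `block_noise_sd`), before Poisson
  sampling. Copying the realization (not the expectation) is essential:
  block genes share the marker's cell-to-cell biological variability and
  remain mutually informative after count noise — the situation the
  min-redundancy penalty exists for. Copying expectations would leave
  block genes conditionally independent given the class, i.e. no more
  redundant than any two markers.
- Patient effects are a per-patient lognormal scaling of library size
  (sd `patient_effect_sd`); extra Bernoulli dropout at `dropout_extra`
  zeroes entries independently.
- All randomness flows from one `numpy` Generator seeded by `spec.seed`;
  identical spec ⇒ bit-identical dataset.

### Default parameters and calibration

Defaults: 8 patients × 200 cells per class, 500 genes, 10 markers at
log2FC = 2, one 10-gene block with `block_noise_sd` 0.2, means log-uniform
on (1, 20), θ = 2, dropout 0.05, patient effect sd 0.2.

The reference regime these defaults must represent is: markers strong
enough that a small panel classifies nearly perfectly, and the block
redundant enough that mRMR retains at most a couple of its members while a
relevance-only top-10 fills up with them. Two parameters interact
non-obviously here. Low dispersion (θ = 2, latent CV ≈ 0.7) *saturates*
marker relevance — all well-expressed markers hit the same noise-limited
MI — which keeps the relevance spread across markers small; that matters
because the mean-redundancy penalty dilutes as the selected set grows
(a clone's penalty is ≈ I_clone-clone/m after m selections), so
suppression only holds when clones have no large relevance head-start
over distinct markers. The mean floor of 1 (rather than, say, 0.1) keeps
every marker detectable at 200 cells/class; genes below the 1% detection
filter would contribute nothing but rank noise anyway. Block noise sd 0.2
sits well below the latent CV, so block genes share most of their
variance with their source marker. This calibration was established once
with a small parameter sweep and then frozen; at these defaults (10 seeds)
the mRMR top-10 carries on average 1.9 block genes vs 6.5 for
relevance-only ranking, every seed recovers 10/10 markers in the top-20,
and the seed-0 IFS peak is MCC 0.965 at k = 18.

### What the simulator does not capture

No batch effects, cell-cycle structure, doublets, ambient RNA, per-gene
dispersion variation, or compositional shifts between tumor and normal
beyond the planted markers; tissue labels are exact (no tumor-purity
mislabeling). Passing tests therefore demonstrate that the pipeline's
logic is correct and that its statistical behavior matches the generative
model — not that any particular gene panel from real tumor data is
biologically right, nor that real-data preprocessing choices are
inconsequential.

## Problem sizes used in tests

Unit tests run scaled-down cohorts (3 patients × 40 cells/class, 60–100
genes, K ≤ 10). End-to-end checks run the reference conditions above
(LOOCV over 400 training cells at K = 50, ≈ 1 minute); the null-cohort
checks use K = 10, which if anything *understates* the selection-bias
optimism they measure. `scripts/acceptance.py` uses the reference cohort
plus one null cohort and completes in a few minutes on one CPU.

## Other conventions and edge cases

- Matrix Market I/O uses 1-based 10x-style triplets with sibling
  `features.tsv`/`barcodes.tsv`; integer counts round-trip exactly
  (integer field), normalized values to 10 printed digits. Cell order
  follows the annotation table.
- `k_opt` reporting, ranking TSVs and report JSON are fully deterministic
  given the seed; repeated runs are byte-identical (tested).
- The t-SNE QC embedding is seeded and deterministic given the seed but
  carries no numeric contract; it exists to visualize false calls against
  true ones.
- The CLI is a thin layer over the library; `rank`/`ifs`/`select`/
  `validate` stage their artifacts (ranking.tsv → ifs_curve.tsv →
  panel.tsv → report.json) in the output directory so stages can be rerun
  independently.
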