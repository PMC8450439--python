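# Methods

`sepsiskit` implements an early-warning analysis for sepsis in ICU and
post-liver-transplant patients: continuous bedside-monitor streams are
aligned to a clinically defined onset time, summarized into a fixed feature
vector at a prediction horizon, reduced by feature selection, and
benchmarked with repeated balanced-subsample cross-validation. Because the
hospital data such an analysis runs on are access-restricted, the package
ships a first-class synthetic cohort generator that reproduces the
statistical structure the pipeline assumes; every stage is developed and
validated against it.

## Case definition (Sepsis-3, applied serially)

A patient becomes a case at the first hour `t_sepsis` at which *suspicion of
infection* co-occurs with *acute organ dysfunction*:

* **Suspicion of infection** — a culture order followed by an antibiotic
  start within 72 h, or a culture drawn within 24 h after an antibiotic
  start; the suspicion time is the earlier member of the pair. All
  qualifying pairs are evaluated, sorted and deduplicated.
* **Organ dysfunction** — total SOFA (six subsystems scored 0–4 from the
  published lookup: respiration by PaO2/FiO2, coagulation by platelets,
  liver by bilirubin, cardiovascular by MAP and vasopressor dose, CNS by
  GCS, renal by creatinine) rising **≥ 2 points above the patient's rolling
  24-h minimum**. The rolling-minimum baseline, rather than a fixed
  admission baseline, tolerates patients admitted with already-elevated
  scores — the typical fresh post-transplant admission.
* The two are combined serially: for each suspicion time, hours in
  `[t_susp − 48 h, t_susp + 24 h]` are scanned in order and the first
  qualifying hour is the onset. When the SOFA rise precedes the suspicion
  inside the window, the rise time is used (earliest-evidence convention).

SOFA trajectories are hourly and piecewise-constant between lab updates:
analytes carry forward up to a 24-h staleness limit, after which the
affected subscore falls to 0 (the conservative floor). Unknown analyte
names are rejected by name rather than silently ignored.

Controls — patients who never meet the criteria — receive a seeded uniform
random anchor between admission and discharge. Cases and controls alike
must pass a **24-h data-availability filter** before their anchor: ≥ 50%
minute-grid coverage for HR, RR and SpO2 and at least one blood-pressure
sample per 4-h block. The paper-level requirement is only "data in the
prior 24 h"; the coverage fractions are this package's operationalization
and are configurable. All intervals are left-closed/right-open; timestamps
are UTC.

## Observation window and features

Each labeled event contributes one observation window of `window_h` = 3 h
ending `horizon_h` = 12 h before the anchor, i.e. `[t − 15 h, t − 12 h)` on
the minute grid, split into three 1-h sub-windows of 60 slots. Per channel
(HR, RR, SpO2, SBP, DBP, MAP) and sub-window the extractor computes 43
values:

* **8 statistics** — mean, sum, minimum, maximum, observed length,
  standard deviation, variance (both n−1), excess kurtosis (population
  moments, `m4/m2² − 3`, null for constant input). *Length* counts
  pre-imputation observed samples — the measurement frequency — because on
  the imputed grid it would be the constant 60 and carry no information.
* **25 FFT magnitudes** — |k-th DFT coefficient| for k = 0, 4, …, 96.
  Indices beyond the one-sided spectrum of a 60-sample hour (k > 30) are
  structurally null.
* **10 wavelet coefficients** — the Ricker (Mexican-hat) continuous wavelet
  transform at widths 2, 4, …, 20, reduced to the coefficient at the
  window's central time point. Width 0 is degenerate for the Ricker kernel
  and is rejected; the transform is an in-package direct convolution with
  the classic kernel normalization `A = 2/(√(3a)·π^{1/4})` and kernel
  length `min(10·width, n)`.

That grid gives 6 × 3 × 43 = **774 named columns**
(`{channel}__{extractor}__{param}__h{subwindow}`) before null-column
removal. Columns null for every row are dropped and logged by name; at the
default grid these are exactly the 306 FFT indices beyond the one-sided
spectrum. The count of always-null columns is data- and grid-dependent, so
removal is data-driven rather than hard-coded.

Missing slots are imputed last-observation-carried-forward inside the
window; leading gaps take the per-channel population median fitted on
training rows only. After null-column removal, residual per-row nulls (the
kurtosis of a constant hour, statistics of an hour with zero observations)
are filled with training-row column medians so downstream estimators see a
complete matrix; tree models could tolerate NaN, linear models cannot, and
a uniform rule keeps the routes comparable.

## Feature selection

Four routes rank the same matrix and return interchangeable results:

* **Univariate screen** — per-feature independent-sample t-test and
  Mann-Whitney U against the label; the t-test gates selection at
  α = 0.05, both p-values are reported, zero-variance columns are flagged
  undefined. No multiple-testing correction is applied — deliberately, to
  match the analysis this package operationalizes; the screen is a
  dimensionality-reduction device, not an inference.
* **Penalized thresholding** — L2 (ridge) or L1 (lasso) logistic fits on
  standardized features; features with |coefficient| ≥ 0.5 are selected,
  ordered by magnitude. Standardization is required for a fixed
  coefficient cut to be meaningful. Defaults `ridge_C = 10`, `lasso_C = 1`:
  L2 spreads weight across correlated columns and shrinks every
  coefficient, so the ridge route needs a weaker penalty for the same cut
  to stay comparably selective (≈ 5–10% of columns at cohort scale, versus
  the lasso's deliberately extreme sparsity, which can collapse onto a
  single channel).
* **Recursive feature elimination** — the ridge logistic estimator, one
  feature dropped per step, down to a target count ("auto" chooses it by
  cross-validated AUROC).
* **Forest importances** — random-forest rankings under both Gini-impurity
  and information-gain criteria, each normalized to sum to 1.

The ridge route feeds modeling by default; the others remain available via
configuration.

## Modeling protocol

Training uses **balanced subsampling**: every iteration takes all cases
plus an equal-count random control subset (without replacement), then runs
stratified 5-fold cross-validation — stratification prevents empty-class
folds after balancing. The default protocol re-subsamples controls each of
the 100 iterations (re-splitting folds only is available via
configuration). Metrics per fold: sensitivity, specificity and PPV at the
0.5 probability threshold, AUROC as the tie-averaged rank statistic, and
AUPRC by precision-recall integration. The summary reports the mean and a
normal-approximation 95% CI (±1.96·SD/√n) across iteration means.

Four classifiers share the protocol: gradient-boosted trees (defaults
max_depth 6, subsample 1, min_child_weight 1, learning rate 0.1), logistic
regression, a linear SVM (margins squashed through the logistic function so
scores live in [0, 1] and the 0.5 threshold is the decision boundary), and
a random forest. A multilayer perceptron is deliberately out of scope.

Hyperparameters are chosen by a **stability-aware grid search**: candidates
whose mean specificity falls below 0.6 are excluded; among those whose
AUROC cross-iteration variance lies within a 10% band of the minimum, the
highest mean AUROC wins; grid order breaks exact ties. External validation
fits once on the (balanced) training cohort and scores an untouched holdout
whose columns must match exactly; imputation medians and scalers come from
training data only.

## The synthetic cohort generator

The generator defines the study conditions every test runs under.

* **Baseline kernel** — per channel, a first-order mean-reverting
  autoregressive process plus a 24-h sinusoid with random phase: the
  simplest stationary process with tunable variance and autocorrelation.
  Per-minute AR coefficients of 0.95–0.97 give fluctuation timescales of
  tens of minutes; stationary SDs ≈ 5 bpm (HR), 2 breaths/min (RR), 1%
  (SpO2), 4–6 mmHg (pressures); between-patient baseline means are jittered
  (e.g. HR 78 ± 7). Pressures are generated as DBP plus a positive pulse
  pressure, with SBP = DBP + PP and MAP = DBP + PP/3, so SBP ≥ DBP and MAP
  lies between them by construction; SpO2 is clipped to [0, 100].
* **Planted prodrome** — cases receive an onset uniform in
  [24 h, duration − 1 h] after admission; effects ramp linearly from
  onset − 18 h to onset so that windows at a 12-h horizon contain signal:
  the HR innovation SD is scaled by `1 − hrv_reduction·effect_size` (HRV
  damping), the RR mean drifts up by `rr_drift` breaths/min per ramp hour,
  and the DBP/pulse-pressure innovation SD gains
  `bp_instability·effect_size` mmHg (blood-pressure instability).
  Defaults — `hrv_reduction` 0.5, `rr_drift` 0.5 (RR ≈ 18 → 27 at onset,
  classic sepsis tachypnea), `bp_instability` 2.0 — are fixed clinically
  plausible prodrome magnitudes. `effect_size` scales all three; at 0 the
  case and control generating laws are identical.
* **Labs and events** — hourly SOFA inputs at normal baselines; cases step
  platelets to ~90 ×10³/µL and creatinine to ~2.2 mg/dL at onset (a ≥ 2
  point SOFA rise), with a culture order 1 h and an antibiotic start 2 h
  after onset, so every planted case is labelable and the detected onset
  falls within the hourly discretization of the true one.
* **Missingness** — HR/RR/SpO2 have small independent dropout (0.6%, 2.7%,
  0.1%); non-invasive pressures are thinned to one cuff cycle per hour.
  During the prodrome, extra cuff samples arrive *stochastically* with
  intensity proportional to the ramp (expected interval shrinking toward
  15 min at full ramp): clinicians measure more often as deterioration
  becomes apparent, so measurement frequency is genuinely informative — but
  it overlaps the control sampling law rather than marking cases
  deterministically, and it is absent entirely at `effect_size` 0. MAP
  samples are additionally dropped at 12%, and DBP is forced missing
  wherever MAP is missing with probability `coupling` (default 1),
  reproducing the coupled MAP↔DBP missingness of cuff measurements.
* **Reproducibility** — every draw is keyed by
  `(seed, patient index, stream)` through `numpy.random.SeedSequence`, so
  identical configurations are byte-identical on disk and adding patients
  never perturbs existing ones.

**What the generator does not emulate:** waveform-level (sub-second)
dynamics, pharmacology and interventions, demographic structure, mortality,
multi-day non-stationarity, and real EMR artifacts (clock skew, unit
errors, duplicated rows). Passing tests therefore demonstrate that the
pipeline recovers planted effects of the stated form under realistic
sampling and missingness — not that the paper-level performance numbers
transfer to any particular hospital's data.

## Numerical and degenerate-input conventions

* Empty sub-window: all statistics null, length 0; constant sub-window:
  SD/variance 0, kurtosis null.
* FFT index beyond `n // 2`: null (dropped later if null for all rows).
* The control-anchor sampler retries up to 100 draws against the
  availability check before declaring a patient infeasible.
* Balanced subsampling with fewer controls than cases takes all controls
  and warns rather than failing.
* A degenerate CV fold (single-class) is reshuffled once, then the
  iteration fails loudly.
* `metrics.json` is serialized with sorted keys and 10-decimal rounding so
  identical runs are byte-identical; the config hash excludes the output
  directory (provenance, not a parameter).

## Problem sizes

Tests and the acceptance script run the full pipeline at 100 cases + 100
controls with 20 CV iterations, and module tests at 8–40 patients — sizes
chosen so the planted-effect recovery is statistically stable while the
whole suite runs on a single CPU in minutes. The protocol's reference
configuration (100 iterations) is the package default for real use.

## Known limitations

* SOFA's respiration subscore uses the PaO2/FiO2 ratio without the
  mechanical-ventilation qualifier for scores 3–4; the cardiovascular
  subscore supports the standard vasopressor dose tiers but the simulator
  never emits vasopressors.
* The univariate screen's lack of multiplicity control inflates its
  selection size by design (see above).
* The lasso route's extreme sparsity can concentrate on one channel; use
  the ridge or RFE routes when channel coverage matters.
* AUPRC is computed by average precision, which slightly exceeds trapezoid
  integration under heavy score ties.
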