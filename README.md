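# sepsiskit

Early prediction of sepsis onset from continuous ICU vital-sign streams,
with a focus on post-liver-transplant patients. `sepsiskit` is a tested,
reusable implementation of the full analysis pipeline — Sepsis-3 onset
labeling, horizon-anchored feature extraction from minute-resolution
physiology, multi-route feature selection, and repeated balanced-subsample
benchmarking — together with a seeded synthetic ICU cohort generator, so the
entire analysis is runnable and verifiable without access-restricted
hospital data.

It is written for clinical-informatics and biostatistics practitioners who
work with bedside-monitor exports (minute-by-minute HR, RR, SpO2 and
intermittent cuff pressures SBP/DBP/MAP) and want a transparent, seeded
pipeline rather than a black-box score.

## The analysis

**Labeling (Sepsis-3, serial).** A patient's onset `t_sepsis` is the first
hour at which suspicion of infection (a culture/antibiotic pair: antibiotic
within 72 h after culture, or culture within 24 h after antibiotic)
co-occurs with an acute rise in organ dysfunction,

&nbsp;&nbsp;&nbsp;&nbsp;SOFA(t) − min{ SOFA(s) : t − 24 h ≤ s < t } ≥ 2,

scanned serially over `[t_susp − 48 h, t_susp + 24 h]`. Controls get a
seeded random anchor; everyone must have 24 h of monitoring data before the
anchor.

**Features.** Each event contributes the 3-h window `[t − 15 h, t − 12 h)`
(a 12-h prediction horizon), split into hourly sub-windows. Per channel and
hour: 8 statistics (mean, sum, min, max, observed length, SD, variance,
excess kurtosis), 25 FFT coefficient magnitudes |X(k)| for k = 0, 4, …, 96,
and 10 Ricker continuous-wavelet coefficients at widths 2, 4, …, 20 —
6 × 3 × 43 = **774 columns**, LOCF/median-imputed, with always-null columns
dropped and logged.

**Selection.** Four routes: t-test/Mann-Whitney screening at p < 0.05,
ridge and lasso logistic fits on standardized features thresholded at
|β| ≥ 0.5, recursive feature elimination, and random-forest importances
(Gini + information gain). The ridge route feeds modeling by default.

**Benchmarking.** Each of 100 iterations draws all cases plus an equal
number of random controls and runs stratified 5-fold CV; gradient-boosted
trees (max_depth 6, subsample 1, min_child_weight 1, η = 0.1), logistic
regression, linear SVM and random forest are scored by sensitivity,
specificity, PPV (at threshold 0.5), AUROC and AUPRC, reported as mean
[95% CI] over iteration means. A stability-aware grid search prefers the
lowest-variance configuration within a band, subject to a specificity
floor of 0.6, and selected models are validated on a held-out (transplant)
cohort.

See [docs/methods.md](docs/methods.md) for the full model description,
parameter defaults and limitations.

## Worked example

```python
from sepsiskit import (
    SimulationConfig, simulate_cohort, label_cohort,
    build_feature_matrix, ModelSpec, run_cv_iterations,
)
from sepsiskit.selection import SelectionConfig, select_features

cohort = simulate_cohort(SimulationConfig(n_cases=100, n_controls=100, seed=7))
labels = label_cohort(cohort.vitals, cohort.events, cohort.labs, seed=7)
fm = build_feature_matrix(labels.labels, cohort.vitals)

sel = select_features(fm, SelectionConfig(rfe_target=22, seed=7))
ridge = sel["ridge"].features
summary, _ = run_cv_iterations(
    (fm.X[ridge], fm.y.to_numpy(int)), ModelSpec(seed=7),
    n_iterations=20, seed=7,
)
print(fm.X.shape, len(ridge))
print(summary.table.round(3))
```

prints

```
(200, 468) 22
              mean  ci_lower  ci_upper
sensitivity  0.888     0.883     0.894
specificity  0.921     0.915     0.927
ppv          0.923     0.917     0.928
auc          0.959     0.956     0.961
auprc        0.970     0.968     0.971
```

Reading this: the 200 labeled events yield 468 usable columns (774 minus
the 306 Fourier indices beyond the one-sided spectrum of a 60-sample hour);
the ridge route keeps 22 features; and the gradient-boosted model separates
planted-prodrome cases from controls at AUROC ≈ 0.96 twelve hours before
onset, with the CI taken across the 20 balanced-subsample CV iterations.
With `effect_size=0` (no planted physiology) the same pipeline falls to
chance (AUROC ≈ 0.5) — the recovery is signal, not leakage.

The `examples/` directory has one narrative script per stage
(simulation, labeling, extraction, selection, benchmarking, full pipeline),
and a CLI mirrors them:

```bash
sepsiskit simulate --n-cases 20 --n-controls 20 --seed 1 --out data/
sepsiskit run-all --config config.yaml --seed 1 --out run/
```

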