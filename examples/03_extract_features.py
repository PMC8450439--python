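"""Extract the 774-column feature matrix from labeled events.

Each event contributes a 3-h observation window ending 12 h before its
anchor, split into hourly sub-windows.  Per channel and hour: 8 summary
statistics, 25 FFT coefficient magnitudes (indices 0,4,...,96) and 10
Ricker-wavelet coefficients (widths 2,4,...,20).  Columns that are null for
every row — Fourier indices beyond the one-sided spectrum of a 60-sample
hour — are dropped and logged.
"""

from sepsiskit import SimulationConfig, WindowConfig, build_feature_matrix, label_cohort, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_cases=8, n_controls=8, seed=5))
labels = label_cohort(cohort.vitals, cohort.events, cohort.labs, seed=5)
fm = build_feature_matrix(labels.labels, cohort.vitals, WindowConfig())

print("columns before null removal:", WindowConfig().n_features)
print("columns after null removal: ", fm.X.shape[1])
print("all-null columns dropped:   ", len(fm.dropped_columns))
print("\nexample feature values for the first case:")
cols = ["rr__stat__mean__h0", "hr__stat__std__h0", "sbp__stat__length__h0",
        "rr__fft__4__h0", "rr__cwt__10__h0"]
print(fm.X.loc[fm.y].iloc[0][cols].round(3).to_string())
# rr__stat__mean__h0 is the mean respiratory rate in the first hour of the
# window; sbp__stat__length__h0 counts observed (pre-imputation) cuff
# samples in that hour.
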