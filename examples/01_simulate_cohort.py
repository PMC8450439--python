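"""Generate a small synthetic ICU cohort and inspect its structure.

The simulator emits four tables: minute-resolution vitals (with realistic
cuff-pressure missingness), clinical events (admission, discharge, culture
orders, antibiotic starts), hourly SOFA-input labs, and the ground truth
(which patients carry a planted sepsis prodrome and when it culminates).
"""

from sepsiskit import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_cases=5, n_controls=5, seed=42))

print("patients:", cohort.truth.shape[0])
print("true sepsis onsets:", cohort.truth["true_onset_time"].notna().sum())
print("\nvitals head:")
print(cohort.vitals.head(3).to_string(index=False))
print("\nper-channel observed fraction (cuff pressures are hourly):")
print(cohort.vitals[["hr", "rr", "spo2", "sbp", "dbp", "map"]].notna().mean().round(3))
# Expect hr/spo2 near 1.0 and sbp/dbp/map near 0.02 (~1 sample/hour on a
# 1-minute grid): the non-invasive pressures are cuff measurements.
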