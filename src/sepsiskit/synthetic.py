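"""Seeded synthetic ICU cohort generator.

Real continuous bedside-monitor data are IRB-restricted, so the pipeline is
developed and validated against a simulator that reproduces the statistical
structure the analysis assumes: minute-by-minute HR / RR / SpO2 streams,
intermittently sampled non-invasive blood pressures (SBP / DBP / MAP),
hourly labs feeding SOFA scoring, culture/antibiotic event pairs, and a
sepsis prodrome planted in the vital signs — reduced heart-rate variability,
a rising respiratory rate, and increased blood-pressure dynamics — ramping
linearly over the 18 h before the true onset.

Every draw is keyed by ``(seed, patient index, channel)`` through
:class:`numpy.random.SeedSequence`, so outputs are bit-reproducible and
adding patients to a cohort never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.signal import lfilter

CHANNELS = ("hr", "rr", "spo2", "sbp", "dbp", "map")

#: channels that carry a planted pre-onset effect in sepsis profiles
EFFECT_CHANNELS = ("hr", "rr", "sbp", "map")

EPOCH = pd.Timestamp("2024-01-01 00:00:00", tz="UTC")

# Baseline autoregressive kernels, per minute.  (mean, between-patient SD of
# the mean, AR coefficient, innovation SD, circadian amplitude).  Innovation
# SDs give stationary SDs of roughly 5 bpm HR, 2 breaths/min RR, 1% SpO2 and
# 4-6 mmHg for pressures — typical monitored-ICU variability.
_KERNELS = {
    "hr": dict(mu=78.0, mu_sd=7.0, phi=0.97, eps_sd=1.20, circ=3.0),
    "rr": dict(mu=17.5, mu_sd=1.5, phi=0.95, eps_sd=0.60, circ=1.0),
    "spo2": dict(mu=97.0, mu_sd=0.8, phi=0.95, eps_sd=0.30, circ=0.3),
    "dbp": dict(mu=62.0, mu_sd=6.0, phi=0.97, eps_sd=1.00, circ=2.0),
    # pulse pressure: SBP = DBP + PP, MAP = DBP + PP/3
    "pp": dict(mu=52.0, mu_sd=8.0, phi=0.97, eps_sd=1.00, circ=2.0),
}

#: hours of linear ramp-up of the planted effects before onset
RAMP_HOURS = 18.0

_LAB_BASELINES = {
    "platelets": (250.0, 40.0),   # 1e3/uL
    "bilirubin": (0.8, 0.2),      # mg/dL
    "creatinine": (0.9, 0.12),    # mg/dL
    "gcs": (15.0, 0.0),
    "pao2_fio2": (460.0, 25.0),
}
# values the labs step to at onset; drops total SOFA rise of >= 2 points
_LAB_SEPTIC = {"platelets": 90.0, "creatinine": 2.2}


@dataclass(frozen=True)
class MissingnessProfile:
    """Per-channel observation model applied after simulation.

    HR / RR / SpO2 are near-complete with small independent dropout rates.
    NIBP channels are reduced to one retained sample per ``nibp_interval_min``
    (cuff cycling), densified to ``deterioration_interval_min`` during the
    planted pre-onset window, mirroring more frequent cuff measurements when
    deterioration is suspected.  ``map_extra_rate`` drops retained MAP
    samples; wherever MAP is missing, DBP is additionally set missing with
    probability ``coupling``.
    """

    hr_rate: float = 0.006
    rr_rate: float = 0.027
    spo2_rate: float = 0.001
    nibp_interval_min: int | None = 60
    deterioration_interval_min: int = 15
    map_extra_rate: float = 0.12
    coupling: float = 1.0

    @classmethod
    def none(cls) -> "MissingnessProfile":
        """A profile under which :func:`apply_missingness` is the identity."""
        return cls(
            hr_rate=0.0,
            rr_rate=0.0,
            spo2_rate=0.0,
            nibp_interval_min=None,
            map_extra_rate=0.0,
            coupling=0.0,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated cohort.

    ``effect_size`` scales every planted pre-onset shift; ``effect_size = 0``
    makes the case and control generating laws identical (events and labs
    still mark the cases, so labeling works but vitals carry no signal).
    """

    n_cases: int
    n_controls: int
    cohort_tag: str = "general"
    duration_h: float = 48.0
    sample_interval_min: int = 1
    effect_size: float = 1.0
    hrv_reduction: float = 0.5
    rr_drift: float = 0.5           # breaths/min per hour of ramp
    bp_instability: float = 2.0     # mmHg added innovation SD at full ramp
    missingness: MissingnessProfile = field(default_factory=MissingnessProfile)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("n_cases and n_controls must be non-negative")
        if self.cohort_tag not in ("general", "transplant"):
            raise ValueError(f"unknown cohort_tag {self.cohort_tag!r}")
        if self.n_cases > 0 and self.duration_h < 27:
            raise ValueError(
                "duration_h must be >= 27 when cases are generated "
                "(24-h availability filter plus window headroom)"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.hrv_reduction <= 1:
            raise ValueError("hrv_reduction must lie in [0, 1]")
        if self.sample_interval_min < 1:
            raise ValueError("sample_interval_min must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    patient_id: str
    true_onset_time: pd.Timestamp | None
    planted_effect_channels: tuple[str, ...]
    cohort_tag: str


@dataclass
class SimulatedCohort:
    """Container for one simulated cohort's four tables."""

    vitals: pd.DataFrame
    events: pd.DataFrame
    labs: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.vitals.to_csv(out / "vitals.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.labs.to_csv(out / "labs.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _channel_rng(seed: int, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index, stream]))


def _ar1(mu: float, phi: float, eps: np.ndarray, x0: float) -> np.ndarray:
    """Mean-reverting AR(1) driven by the (possibly heteroscedastic) eps."""
    # x_t - mu = phi (x_{t-1} - mu) + eps_t, solved by linear filtering
    z = lfilter([1.0], [1.0, -phi], eps, zi=[phi * (x0 - mu)])[0]
    return mu + z


def _ramp(minutes: np.ndarray, onset_min: float) -> np.ndarray:
    """Linear 0->1 ramp over the RAMP_HOURS before onset, held at 1 after."""
    r = (minutes - (onset_min - RAMP_HOURS * 60.0)) / (RAMP_HOURS * 60.0)
    return np.clip(r, 0.0, 1.0)


def simulate_patient_stream(
    profile: str,
    config: SimulationConfig,
    onset: pd.Timestamp | None,
    patient_index: int = 0,
    admission: pd.Timestamp = EPOCH,
) -> pd.DataFrame:
    """Simulate one patient's complete (pre-missingness) vitals table.

    ``profile`` is ``"control"`` or ``"sepsis"``; a sepsis profile requires
    ``onset`` and ramps the planted effects linearly over the 18 h before it:
    the HR innovation SD is scaled by ``1 - hrv_reduction * effect_size``,
    the RR mean drifts upward by ``rr_drift`` breaths/min per ramp hour, and
    the SBP/MAP innovation SD gains ``bp_instability * effect_size`` mmHg.

    Returns a tidy frame with columns ``timestamp`` plus the six channels.
    """
    if profile not in ("control", "sepsis"):
        raise ValueError(f"unknown profile {profile!r}")
    if (onset is not None) != (profile == "sepsis"):
        raise ValueError("onset must be given iff profile == 'sepsis'")

    step = config.sample_interval_min
    n = int(round(config.duration_h * 60 / step))
    minutes = np.arange(n, dtype=float) * step
    timestamps = admission + pd.to_timedelta(minutes, unit="m")

    if onset is not None:
        onset_min = (onset - admission).total_seconds() / 60.0
        if not 0 <= onset_min <= config.duration_h * 60:
            raise ValueError("onset lies outside the simulated stay")
        ramp = _ramp(minutes, onset_min)
    else:
        ramp = np.zeros(n)

    e = config.effect_size
    circ_phase = 2 * np.pi * minutes / (24.0 * 60.0)

    raw: dict[str, np.ndarray] = {}
    for stream_idx, name in enumerate(("hr", "rr", "spo2", "dbp", "pp")):
        k = _KERNELS[name]
        rng = _channel_rng(config.seed, patient_index, stream_idx)
        mu = rng.normal(k["mu"], k["mu_sd"])
        phase = rng.uniform(0, 2 * np.pi)
        eps_sd = np.full(n, k["eps_sd"])
        if name == "hr":
            eps_sd = eps_sd * np.clip(1.0 - config.hrv_reduction * e * ramp, 0.05, None)
        elif name in ("dbp", "pp"):
            # raises SBP and MAP innovation variance during the prodrome
            eps_sd = eps_sd + config.bp_instability * e * ramp * 0.5
        eps = rng.normal(0.0, 1.0, n) * eps_sd
        x = _ar1(mu, k["phi"], eps, x0=mu)
        x = x + k["circ"] * np.sin(circ_phase + phase)
        if name == "rr":
            # ramp * RAMP_HOURS = hours elapsed since the prodrome began
            x = x + config.rr_drift * e * ramp * RAMP_HOURS
        raw[name] = x

    dbp = raw["dbp"]
    pp = np.clip(raw["pp"], 5.0, None)  # pulse pressure stays positive
    out = pd.DataFrame(
        {
            "timestamp": timestamps,
            "hr": np.clip(raw["hr"], 20.0, 220.0),
            "rr": np.clip(raw["rr"], 4.0, 60.0),
            "spo2": np.clip(raw["spo2"], 0.0, 100.0),
            "sbp": dbp + pp,
            "dbp": dbp,
            "map": dbp + pp / 3.0,
        }
    )
    return out


def apply_missingness(
    series: pd.DataFrame,
    profile: MissingnessProfile,
    onset: pd.Timestamp | None = None,
    patient_index: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Apply the observation model to a complete vitals table.

    NIBP channels are thinned to the cuff-cycling grid (denser during the
    pre-onset deterioration window when ``onset`` is given); continuous
    channels get independent dropout.  DBP is forced missing wherever MAP is
    missing with probability ``profile.coupling``, reproducing the observed
    MAP<->DBP coupled missingness of cuff measurements.
    """
    out = series.copy()
    n = len(out)
    rng = _channel_rng(seed, patient_index, 17)

    for ch, rate in (("hr", profile.hr_rate), ("rr", profile.rr_rate), ("spo2", profile.spo2_rate)):
        if rate > 0:
            drop = rng.random(n) < rate
            out.loc[drop, ch] = np.nan

    if profile.nibp_interval_min is not None:
        minutes = (
            (out["timestamp"] - out["timestamp"].iloc[0]).dt.total_seconds() / 60.0
        ).to_numpy()
        offset = int(rng.integers(0, profile.nibp_interval_min))
        keep = (minutes.astype(int) - offset) % profile.nibp_interval_min == 0
        if onset is not None:
            # clinicians cycle the cuff more often as deterioration becomes
            # apparent: extra samples arrive stochastically, with an expected
            # inter-sample interval shrinking toward deterioration_interval_min
            # as the prodrome ramps up — informative, but overlapping with the
            # control sampling law rather than a deterministic case marker
            onset_min = (onset - out["timestamp"].iloc[0]).total_seconds() / 60.0
            ramp = _ramp(minutes, onset_min)
            ramp[minutes > onset_min] = 1.0
            extra_per_min = (60.0 / profile.deterioration_interval_min - 1.0) / 60.0
            extra = rng.random(n) < extra_per_min * ramp
            keep = keep | extra
        for ch in ("sbp", "dbp", "map"):
            out.loc[~keep, ch] = np.nan

    if profile.map_extra_rate > 0:
        retained = out["map"].notna().to_numpy()
        drop = retained & (rng.random(n) < profile.map_extra_rate)
        out.loc[drop, "map"] = np.nan

    if profile.coupling > 0:
        map_missing = out["map"].isna().to_numpy()
        couple = rng.random(n) < profile.coupling
        out.loc[map_missing & couple, "dbp"] = np.nan

    return out


def _simulate_labs(
    patient_id: str,
    admission: pd.Timestamp,
    duration_h: float,
    onset: pd.Timestamp | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Hourly SOFA-input labs; septic patients step at onset to values that
    raise total SOFA by >= 2 points within the suspicion window."""
    hours = np.arange(int(np.floor(duration_h)) + 1)
    timestamps = admission + pd.to_timedelta(hours, unit="h")
    rows = []
    for analyte, (mu, sd) in _LAB_BASELINES.items():
        base = rng.normal(mu, sd) if sd > 0 else mu
        vals = base + (rng.normal(0.0, sd * 0.1, len(hours)) if sd > 0 else 0.0)
        if onset is not None and analyte in _LAB_SEPTIC:
            septic = timestamps >= onset
            vals = np.where(septic, _LAB_SEPTIC[analyte] + rng.normal(0, 2.0, len(hours)), vals)
        if analyte == "gcs":
            vals = np.clip(np.round(vals), 3, 15)
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id,
                    "timestamp": timestamps,
                    "analyte": analyte,
                    "value": np.asarray(vals, dtype=float),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full cohort: vitals, events, labs and ground truth.

    Cases receive a true onset drawn uniformly in
    ``[24 h, duration - 1 h]`` after admission (so the 24-h availability
    filter and the observation window are satisfiable), a culture order 1 h
    and an antibiotic start 2 h after onset, and the lab step planting the
    SOFA rise.  Controls get neither.  Identical ``(config, seed)`` give
    byte-identical serialized outputs.
    """
    config.validate()
    n_total = config.n_cases + config.n_controls
    prefix = "G" if config.cohort_tag == "general" else "T"

    vitals_parts, labs_parts, event_rows, truth_rows = [], [], [], []
    for i in range(n_total):
        is_case = i < config.n_cases
        patient_id = f"{prefix}{i:04d}"
        admission = EPOCH
        discharge = admission + pd.Timedelta(hours=config.duration_h)
        meta_rng = _channel_rng(config.seed, i, 23)

        onset = None
        if is_case:
            onset_h = meta_rng.uniform(24.0, config.duration_h - 1.0)
            onset = admission + pd.Timedelta(minutes=round(onset_h * 60))

        stream = simulate_patient_stream(
            "sepsis" if is_case else "control",
            config,
            onset,
            patient_index=i,
            admission=admission,
        )
        # densified NIBP sampling is part of the planted deterioration: with
        # effect_size 0 there is no prodrome, so cases and controls share one
        # observation law and the labels carry no signal
        stream = apply_missingness(
            stream,
            config.missingness,
            onset=onset if config.effect_size > 0 else None,
            patient_index=i,
            seed=config.seed,
        )
        stream.insert(0, "patient_id", patient_id)
        vitals_parts.append(stream)

        labs_parts.append(
            _simulate_labs(patient_id, admission, config.duration_h, onset, meta_rng)
        )

        event_rows.append((patient_id, "admission", admission))
        if config.cohort_tag == "transplant":
            event_rows.append((patient_id, "transplant", admission))
        if is_case:
            event_rows.append((patient_id, "culture", onset + pd.Timedelta(hours=1)))
            event_rows.append((patient_id, "antibiotic", onset + pd.Timedelta(hours=2)))
        event_rows.append((patient_id, "discharge", discharge))

        truth_rows.append(
            (
                patient_id,
                onset,
                ";".join(EFFECT_CHANNELS) if is_case else "",
                config.cohort_tag,
            )
        )

    vitals = (
        pd.concat(vitals_parts, ignore_index=True)
        if vitals_parts
        else pd.DataFrame(columns=["patient_id", "timestamp", *CHANNELS])
    )
    events = pd.DataFrame(event_rows, columns=["patient_id", "event_type", "timestamp"])
    labs = (
        pd.concat(labs_parts, ignore_index=True)
        if labs_parts
        else pd.DataFrame(columns=["patient_id", "timestamp", "analyte", "value"])
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "true_onset_time", "planted_effect_channels", "cohort_tag"],
    )
    return SimulatedCohort(vitals=vitals, events=events, labs=labs, truth=truth, config=config)


def load_cohort_tables(
    directory: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read vitals/events/labs CSVs written by :meth:`SimulatedCohort.write`."""
    d = Path(directory)
    vitals = pd.read_csv(d / "vitals.csv", parse_dates=["timestamp"])
    events = pd.read_csv(d / "events.csv", parse_dates=["timestamp"])
    labs = pd.read_csv(d / "labs.csv", parse_dates=["timestamp"])
    return vitals, events, labs
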