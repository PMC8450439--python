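"""Serial Sepsis-3 onset labeling and anchor-time assignment.

A patient is a case when a suspicion of infection (a culture/antibiotic pair
in the standard pairing windows) co-occurs with an acute rise of >= 2 points
in the total SOFA score relative to the patient's rolling 24-h minimum,
evaluated serially over suspicion times.  The first qualifying hour is the
onset ``t_sepsis`` and every stream is later aligned to it.  Controls — who
never meet the criteria — receive a seeded random anchor between admission
and discharge, subject to the same 24-h data-availability filter applied to
cases.

Conventions: all intervals are left-closed / right-open, timestamps UTC;
SOFA is piecewise-constant between lab updates (last observation carried
forward up to a staleness limit, after which a subscore falls back to 0).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: analytes understood by the SOFA scorer
SOFA_ANALYTES = frozenset(
    {
        "pao2_fio2",
        "platelets",
        "bilirubin",
        "gcs",
        "creatinine",
        "dopamine",
        "dobutamine",
        "norepinephrine",
        "epinephrine",
    }
)

_VASOPRESSORS = ("dopamine", "dobutamine", "norepinephrine", "epinephrine")

SOFA_SUBSYSTEMS = (
    "respiration",
    "coagulation",
    "liver",
    "cardiovascular",
    "cns",
    "renal",
)


@dataclass
class SofaTrajectory:
    """Hourly six-subsystem SOFA subscores and total for one patient."""

    patient_id: str
    frame: pd.DataFrame  # columns: timestamp, six subscores, total

    def __post_init__(self) -> None:
        sub = self.frame[list(SOFA_SUBSYSTEMS)]
        if not (self.frame["total"] == sub.sum(axis=1)).all():
            raise ValueError("total must equal the sum of subscores")


@dataclass(frozen=True)
class EventLabel:
    patient_id: str
    t_event: pd.Timestamp
    is_case: bool
    t_suspicion: pd.Timestamp | None = None


def _score_respiration(pf: float) -> int:
    if pf >= 400:
        return 0
    if pf >= 300:
        return 1
    if pf >= 200:
        return 2
    if pf >= 100:
        return 3
    return 4


def _score_coagulation(plt: float) -> int:
    if plt >= 150:
        return 0
    if plt >= 100:
        return 1
    if plt >= 50:
        return 2
    if plt >= 20:
        return 3
    return 4


def _score_liver(bili: float) -> int:
    if bili < 1.2:
        return 0
    if bili < 2.0:
        return 1
    if bili < 6.0:
        return 2
    if bili < 12.0:
        return 3
    return 4


def _score_cns(gcs: float) -> int:
    if gcs >= 15:
        return 0
    if gcs >= 13:
        return 1
    if gcs >= 10:
        return 2
    if gcs >= 6:
        return 3
    return 4


def _score_renal(creat: float) -> int:
    if creat < 1.2:
        return 0
    if creat < 2.0:
        return 1
    if creat < 3.5:
        return 2
    if creat < 5.0:
        return 3
    return 4


def _score_cardiovascular(
    map_mmhg: float, dopa: float, dobu: float, norepi: float, epi: float
) -> int:
    # vasopressor doses in ug/kg/min; NaN means not running
    dopa = 0.0 if np.isnan(dopa) else dopa
    dobu = 0.0 if np.isnan(dobu) else dobu
    norepi = 0.0 if np.isnan(norepi) else norepi
    epi = 0.0 if np.isnan(epi) else epi
    if dopa > 15 or norepi > 0.1 or epi > 0.1:
        return 4
    if dopa > 5 or (0 < norepi <= 0.1) or (0 < epi <= 0.1):
        return 3
    if dopa > 0 or dobu > 0:
        return 2
    if not np.isnan(map_mmhg) and map_mmhg < 70:
        return 1
    return 0


def compute_sofa_series(
    labs: pd.DataFrame,
    vitals: pd.DataFrame,
    patient_id: str,
    staleness_limit_h: float = 24.0,
) -> SofaTrajectory:
    """Hourly SOFA trajectory over the span of a patient's records.

    Missing analytes carry forward up to ``staleness_limit_h`` hours; beyond
    that (or before the first measurement) the affected subscore is 0, the
    conservative floor.  MAP for the cardiovascular score is the hourly mean
    of the monitored MAP channel, carried forward under the same limit.
    The result is deterministic and invariant to input row order.
    """
    plabs = labs[labs["patient_id"] == patient_id]
    pvit = vitals[vitals["patient_id"] == patient_id]
    if plabs.empty and pvit.empty:
        raise ValueError(f"no records for patient {patient_id!r}")

    unknown = set(plabs["analyte"].unique()) - SOFA_ANALYTES
    if unknown:
        raise ValueError(f"unknown analyte(s): {sorted(unknown)}")

    parts = [s for s in (plabs["timestamp"], pvit["timestamp"]) if len(s)]
    stamps = pd.concat(parts, ignore_index=True)
    start = stamps.min().floor("h")
    end = stamps.max().floor("h")
    grid = pd.date_range(start, end, freq="h")
    if len(grid) < 1:
        raise ValueError("trajectory shorter than 1 h")
    limit = pd.Timedelta(hours=staleness_limit_h)

    # hourly LOCF per analyte with staleness cutoff
    analyte_vals: dict[str, np.ndarray] = {}
    for analyte in SOFA_ANALYTES:
        sub = plabs[plabs["analyte"] == analyte].sort_values("timestamp")
        if sub.empty:
            analyte_vals[analyte] = np.full(len(grid), np.nan)
            continue
        s = pd.Series(sub["value"].to_numpy(), index=sub["timestamp"])
        s = s[~s.index.duplicated(keep="last")]
        aligned = s.reindex(s.index.union(grid)).ffill(limit=None)
        # enforce staleness: blank out grid points further than limit from
        # the most recent observation
        last_obs = pd.Series(s.index, index=s.index).reindex(
            s.index.union(grid)
        ).ffill()
        stale = (aligned.index - last_obs) > limit
        aligned[stale.fillna(True)] = np.nan
        analyte_vals[analyte] = aligned.reindex(grid).to_numpy(dtype=float)

    if not pvit.empty and "map" in pvit.columns:
        m = pvit.dropna(subset=["map"]).sort_values("timestamp")
        if not m.empty:
            hourly = (
                m.set_index("timestamp")["map"].resample("1h").mean()
            )
            aligned = hourly.reindex(grid)
            aligned = aligned.ffill(limit=int(staleness_limit_h))
            map_vals = aligned.to_numpy(dtype=float)
        else:
            map_vals = np.full(len(grid), np.nan)
    else:
        map_vals = np.full(len(grid), np.nan)

    def _safe(scorer, vals):
        return np.array(
            [0 if np.isnan(v) else scorer(v) for v in vals], dtype=int
        )

    resp = _safe(_score_respiration, analyte_vals["pao2_fio2"])
    coag = _safe(_score_coagulation, analyte_vals["platelets"])
    liver = _safe(_score_liver, analyte_vals["bilirubin"])
    cns = _safe(_score_cns, analyte_vals["gcs"])
    renal = _safe(_score_renal, analyte_vals["creatinine"])
    cardio = np.array(
        [
            _score_cardiovascular(
                map_vals[i],
                analyte_vals["dopamine"][i],
                analyte_vals["dobutamine"][i],
                analyte_vals["norepinephrine"][i],
                analyte_vals["epinephrine"][i],
            )
            for i in range(len(grid))
        ],
        dtype=int,
    )

    frame = pd.DataFrame(
        {
            "timestamp": grid,
            "respiration": resp,
            "coagulation": coag,
            "liver": liver,
            "cardiovascular": cardio,
            "cns": cns,
            "renal": renal,
        }
    )
    frame["total"] = frame[list(SOFA_SUBSYSTEMS)].sum(axis=1)
    return SofaTrajectory(patient_id=patient_id, frame=frame)


def detect_suspicion_times(
    events: pd.DataFrame,
    patient_id: str,
    abx_after_culture_h: float = 72.0,
    culture_after_abx_h: float = 24.0,
) -> list[pd.Timestamp]:
    """Suspicion-of-infection times from culture/antibiotic pairing.

    A qualifying pair is an antibiotic started within ``abx_after_culture_h``
    hours after a culture order, or a culture drawn within
    ``culture_after_abx_h`` hours after an antibiotic start; the suspicion
    time is the earlier member of the pair.  Returns sorted unique times.
    """
    pe = events[events["patient_id"] == patient_id]
    cultures = pe.loc[pe["event_type"] == "culture", "timestamp"]
    abx = pe.loc[pe["event_type"] == "antibiotic", "timestamp"]
    found: set[pd.Timestamp] = set()
    for c in cultures:
        for a in abx:
            if pd.Timedelta(0) <= a - c <= pd.Timedelta(hours=abx_after_culture_h):
                found.add(c)
            elif pd.Timedelta(0) <= c - a <= pd.Timedelta(hours=culture_after_abx_h):
                found.add(a)
    return sorted(found)


def detect_sepsis_onset(
    sofa: SofaTrajectory,
    suspicions: list[pd.Timestamp],
    window_before_h: float = 48.0,
    window_after_h: float = 24.0,
    rise_points: int = 2,
    baseline_window_h: float = 24.0,
) -> pd.Timestamp | None:
    """First hour meeting Sepsis-3 criteria, or None.

    For each suspicion time (serially, in order), hours inside
    ``[t_susp - window_before, t_susp + window_after]`` are scanned for a
    total SOFA at least ``rise_points`` above the patient's minimum over the
    preceding ``baseline_window_h`` hours.  The rolling-minimum baseline
    tolerates patients admitted with already-elevated scores (e.g. fresh
    post-transplant admissions).
    """
    frame = sofa.frame
    if len(frame) < 1:
        raise ValueError("trajectory shorter than 1 h")
    ts = frame["timestamp"]
    total = frame["total"].to_numpy()
    for t_susp in suspicions:
        lo = t_susp - pd.Timedelta(hours=window_before_h)
        hi = t_susp + pd.Timedelta(hours=window_after_h)
        for i in range(len(frame)):
            t = ts.iloc[i]
            if t < lo or t > hi:
                continue
            base_mask = (
                (ts < t) & (ts >= t - pd.Timedelta(hours=baseline_window_h))
            ).to_numpy()
            baseline = total[base_mask].min() if base_mask.any() else total[i]
            if total[i] - baseline >= rise_points:
                return t
    return None


def check_data_availability(
    vitals: pd.DataFrame,
    t_event: pd.Timestamp,
    lookback_h: float = 24.0,
    min_coverage: dict[str, float] | None = None,
    bp_channel: str = "sbp",
    bp_samples_per_block: int = 1,
    bp_block_h: float = 4.0,
) -> bool:
    """24-h data-availability filter.

    True iff, over ``[t_event - lookback, t_event)``, every channel in
    ``min_coverage`` meets its non-missing fraction (>= semantics, relative
    to the minute grid) and the blood-pressure channel has at least
    ``bp_samples_per_block`` samples in each ``bp_block_h``-hour block.
    ``vitals`` is a single patient's table.
    """
    if min_coverage is None:
        min_coverage = {"hr": 0.5, "rr": 0.5, "spo2": 0.5}
    start = t_event - pd.Timedelta(hours=lookback_h)
    if vitals.empty or vitals["timestamp"].min() > start:
        return False
    win = vitals[(vitals["timestamp"] >= start) & (vitals["timestamp"] < t_event)]
    n_slots = int(lookback_h * 60)
    for ch, frac in min_coverage.items():
        if win[ch].notna().sum() / n_slots < frac:
            return False
    if bp_channel is not None and bp_samples_per_block > 0:
        n_blocks = int(np.ceil(lookback_h / bp_block_h))
        for b in range(n_blocks):
            b_lo = start + pd.Timedelta(hours=b * bp_block_h)
            b_hi = min(start + pd.Timedelta(hours=(b + 1) * bp_block_h), t_event)
            blk = win[(win["timestamp"] >= b_lo) & (win["timestamp"] < b_hi)]
            if blk[bp_channel].notna().sum() < bp_samples_per_block:
                return False
    return True


def sample_control_event_time(
    admission: pd.Timestamp,
    discharge: pd.Timestamp,
    availability_check,
    seed: int,
    min_offset_h: float = 24.0,
    max_tries: int = 100,
) -> pd.Timestamp | None:
    """Seeded uniform anchor for a control patient.

    Draws minute-aligned timestamps uniformly from
    ``[admission + min_offset_h, discharge]`` until ``availability_check``
    accepts one; None when the feasible set is empty or the retry cap is hit.
    """
    if admission >= discharge:
        raise ValueError("admission must precede discharge")
    lo = admission + pd.Timedelta(hours=min_offset_h)
    if lo > discharge:
        return None
    rng = np.random.default_rng(seed)
    span_min = int((discharge - lo).total_seconds() // 60)
    for _ in range(max_tries):
        t = lo + pd.Timedelta(minutes=int(rng.integers(0, span_min + 1)))
        if availability_check(t):
            return t
    return None


@dataclass
class LabelingResult:
    """Cohort labels plus bookkeeping from the labeling pass."""

    labels: pd.DataFrame  # patient_id, t_event, is_case, t_suspicion
    excluded: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)


def label_cohort(
    vitals: pd.DataFrame,
    events: pd.DataFrame,
    labs: pd.DataFrame,
    seed: int = 0,
    availability_kwargs: dict | None = None,
) -> LabelingResult:
    """Label every patient in a cohort as case (with t_sepsis) or control.

    Cases failing the 24-h availability filter at onset are excluded, as are
    controls for which no feasible anchor exists.  Control anchors are drawn
    with a per-patient sub-seed so labeling is order-independent.
    """
    availability_kwargs = availability_kwargs or {}
    rows, excluded = [], []
    patient_ids = sorted(
        set(vitals["patient_id"]) | set(events["patient_id"])
    )
    for pid in patient_ids:
        pvit = vitals[vitals["patient_id"] == pid]
        pev = events[events["patient_id"] == pid]
        suspicions = detect_suspicion_times(events, pid)
        onset = None
        t_susp = None
        if suspicions:
            sofa = compute_sofa_series(labs, vitals, pid)
            onset = detect_sepsis_onset(sofa, suspicions)
            if onset is not None:
                t_susp = next(
                    (
                        s
                        for s in suspicions
                        if s - pd.Timedelta(hours=48) <= onset <= s + pd.Timedelta(hours=24)
                    ),
                    suspicions[0],
                )
        if onset is not None:
            if check_data_availability(pvit, onset, **availability_kwargs):
                rows.append((pid, onset, True, t_susp))
            else:
                excluded.append(pid)
        else:
            adm = pev.loc[pev["event_type"] == "admission", "timestamp"]
            dis = pev.loc[pev["event_type"] == "discharge", "timestamp"]
            if adm.empty or dis.empty:
                adm_t, dis_t = pvit["timestamp"].min(), pvit["timestamp"].max()
            else:
                adm_t, dis_t = adm.iloc[0], dis.iloc[0]
            # crc32 gives a stable per-patient sub-seed (str hash is salted)
            sub_seed = int(
                np.random.SeedSequence(
                    [seed, zlib.crc32(pid.encode())]
                ).generate_state(1)[0] % (2**31)
            )
            t = sample_control_event_time(
                adm_t,
                dis_t,
                lambda t: check_data_availability(pvit, t, **availability_kwargs),
                seed=sub_seed,
            )
            if t is None:
                excluded.append(pid)
            else:
                rows.append((pid, t, False, None))
    labels = pd.DataFrame(
        rows, columns=["patient_id", "t_event", "is_case", "t_suspicion"]
    )
    counts = {
        "patients_in": len(patient_ids),
        "excluded": len(excluded),
        "labeled": len(labels),
        "cases": int(labels["is_case"].sum()) if len(labels) else 0,
        "controls": int((~labels["is_case"]).sum()) if len(labels) else 0,
    }
    return LabelingResult(labels=labels, excluded=excluded, counts=counts)
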