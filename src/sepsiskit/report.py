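"""Missing-data QC: per-channel window missingness and the conditional
missingness matrix (e.g. the MAP<->DBP coupling of cuff measurements)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import WindowConfig, extract_window


def missingness_report(
    vitals: pd.DataFrame,
    labels: pd.DataFrame,
    cfg: WindowConfig | None = None,
) -> dict:
    """Quantify missingness inside each labeled event's observation window.

    Returns ``fractions`` — per channel, the fraction of patient windows
    with at least one missing value — and ``conditional`` — the slot-level
    matrix P(channel A missing | channel B missing), NaN where channel B is
    never missing (flagged undefined).
    """
    cfg = cfg or WindowConfig()
    if len(labels) == 0:
        raise ValueError("no labeled windows to report on")
    channels = list(cfg.channels)
    any_missing = pd.DataFrame(False, index=labels["patient_id"], columns=channels)
    slot_missing = []
    for i, (_, ev) in enumerate(labels.iterrows()):
        pvit = vitals[vitals["patient_id"] == ev["patient_id"]]
        arrays = extract_window(pvit, ev["t_event"], cfg)
        miss = np.column_stack([np.isnan(arrays[ch].ravel()) for ch in channels])
        slot_missing.append(miss)
        any_missing.iloc[i] = miss.any(axis=0)
    fractions = any_missing.mean(axis=0)
    allm = np.vstack(slot_missing)  # slots x channels
    cond = pd.DataFrame(np.nan, index=channels, columns=channels)
    for b, chb in enumerate(channels):
        denom = allm[:, b].sum()
        if denom == 0:
            continue  # undefined: channel never missing
        for a, cha in enumerate(channels):
            cond.loc[cha, chb] = allm[allm[:, b], a].sum() / denom
    return {"fractions": fractions, "conditional": cond}


def write_missingness_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["fractions"].rename("fraction_windows_with_missing").to_csv(
        out / "missingness_fractions.csv"
    )
    report["conditional"].to_csv(out / "missingness_conditional.csv")
    payload = {
        "fractions": {k: round(float(v), 10) for k, v in report["fractions"].items()},
        "conditional": {
            a: {
                b: (None if pd.isna(v) else round(float(v), 10))
                for b, v in row.items()
            }
            for a, row in report["conditional"].iterrows()
        },
    }
    (out / "missingness.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
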