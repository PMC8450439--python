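"""Horizon-anchored windowing and per-hour feature extraction.

Each labeled event contributes one 3-hour observation window ending at the
prediction horizon (default 12 h) before the anchor time, split into hourly
sub-windows on the minute grid.  Per channel and sub-window, the extractor
computes eight summary statistics (mean, sum, minimum, maximum, observed
length, standard deviation, variance, excess kurtosis), the magnitudes of
25 discrete-Fourier coefficients (indices 0, 4, ..., 96), and 10 Ricker
continuous-wavelet coefficients (widths 2, 4, ..., 20) — 43 values, hence
6 channels x 3 sub-windows x 43 = 774 columns at the defaults.

Missing samples are imputed last-observation-carried-forward inside the
window; leading gaps take the per-channel population median fitted on
training rows only.  Columns that are null for every row (e.g. Fourier
indices beyond the one-sided spectrum of a 60-sample hour) are dropped and
logged by name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CHANNELS

STAT_NAMES = (
    "mean",
    "sum",
    "minimum",
    "maximum",
    "length",
    "std",
    "variance",
    "kurtosis",
)


@dataclass(frozen=True)
class WindowConfig:
    """Geometry and extractor grids for one observation window."""

    horizon_h: float = 12.0
    window_h: float = 3.0
    subwindow_h: float = 1.0
    channels: tuple[str, ...] = CHANNELS
    fft_params: tuple[int, ...] = tuple(range(0, 97, 4))
    cwt_widths: tuple[int, ...] = tuple(range(2, 21, 2))
    sample_interval_min: int = 1

    def validate(self) -> None:
        if self.window_h % self.subwindow_h != 0:
            raise ValueError("window_h must be divisible by subwindow_h")
        for name, grid in (("fft_params", self.fft_params), ("cwt_widths", self.cwt_widths)):
            if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be non-empty and strictly increasing")
        if any(w < 1 for w in self.cwt_widths):
            raise ValueError("cwt widths must be >= 1 (width 0 is degenerate)")

    @property
    def n_subwindows(self) -> int:
        return int(self.window_h / self.subwindow_h)

    @property
    def slots_per_subwindow(self) -> int:
        return int(self.subwindow_h * 60 / self.sample_interval_min)

    @property
    def n_features(self) -> int:
        per_cell = len(STAT_NAMES) + len(self.fft_params) + len(self.cwt_widths)
        return len(self.channels) * self.n_subwindows * per_cell

    def column_names(self) -> list[str]:
        names = []
        for ch in self.channels:
            for h in range(self.n_subwindows):
                for s in STAT_NAMES:
                    names.append(f"{ch}__stat__{s}__h{h}")
                for k in self.fft_params:
                    names.append(f"{ch}__fft__{k}__h{h}")
                for w in self.cwt_widths:
                    names.append(f"{ch}__cwt__{w}__h{h}")
        return names

    def hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def extract_window(
    series: pd.DataFrame,
    t_event: pd.Timestamp,
    cfg: WindowConfig,
    admission: pd.Timestamp | None = None,
) -> dict[str, np.ndarray]:
    """Per-channel sample arrays for one event's observation window.

    Returns, for each channel, a ``(n_subwindows, slots)`` array on the
    minute grid covering ``[t_event - horizon - window, t_event - horizon)``
    (left-closed, right-open), with missing slots as NaN.
    """
    cfg.validate()
    start = t_event - pd.Timedelta(hours=cfg.horizon_h + cfg.window_h)
    end = t_event - pd.Timedelta(hours=cfg.horizon_h)
    adm = admission if admission is not None else series["timestamp"].min()
    if start < adm:
        pid = series["patient_id"].iloc[0] if "patient_id" in series.columns else "?"
        raise ValueError(
            f"window for patient {pid} at {t_event} extends before admission"
        )
    grid = pd.date_range(
        start, end, freq=f"{cfg.sample_interval_min}min", inclusive="left"
    )
    idx = series.set_index("timestamp")
    out: dict[str, np.ndarray] = {}
    for ch in cfg.channels:
        vals = idx[ch].reindex(grid).to_numpy(dtype=float)
        out[ch] = vals.reshape(cfg.n_subwindows, cfg.slots_per_subwindow)
    return out


def impute_stream(values: np.ndarray, population_median: float) -> np.ndarray:
    """LOCF within the window; leading gaps take the population median."""
    if not np.isfinite(population_median):
        raise ValueError("population_median must be finite")
    x = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(x)
    if not isnan.any():
        return x
    # vectorized forward fill
    idx = np.where(~isnan, np.arange(len(x)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, x[np.clip(idx, 0, None)], population_median)
    return filled


def statistical_features(x: np.ndarray, n_observed: int | None = None) -> dict[str, float]:
    """Eight summary statistics of a complete (post-imputation) sub-window.

    ``length`` counts the originally observed samples (pre-imputation) —
    the measurement frequency — not the imputed grid length.  Variance and
    SD use the n-1 convention; kurtosis is excess (Fisher) without bias
    correction and is null for constant input.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n_observed is None:
        n_observed = n
    if n == 0:
        return {s: (0.0 if s == "length" else np.nan) for s in STAT_NAMES}
    var = float(np.var(x, ddof=1)) if n > 1 else 0.0
    if np.ptp(x) == 0:
        kurt = np.nan
    else:
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return {
        "mean": float(np.mean(x)),
        "sum": float(np.sum(x)),
        "minimum": float(np.min(x)),
        "maximum": float(np.max(x)),
        "length": float(n_observed),
        "std": float(np.sqrt(var)),
        "variance": var,
        "kurtosis": kurt,
    }


def fft_features(x: np.ndarray, params: Sequence[int]) -> dict[int, float]:
    """Magnitude of the k-th discrete Fourier coefficient for each k.

    Indices beyond the one-sided spectrum (k > n // 2) are null: a 60-sample
    hour resolves coefficients 0..30 only.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    spec = np.abs(np.fft.fft(x))
    return {
        int(k): (float(spec[k]) if k <= n // 2 else np.nan) for k in params
    }


def ricker_kernel(points: int, width: float) -> np.ndarray:
    """Sampled Ricker (Mexican-hat) wavelet, classic normalization
    A = 2 / (sqrt(3*width) * pi**0.25)."""
    if width < 1:
        raise ValueError("width must be >= 1")
    a = float(width)
    amp = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    t = np.arange(points) - (points - 1.0) / 2.0
    tsq = t**2
    return amp * (1.0 - tsq / a**2) * np.exp(-tsq / (2.0 * a**2))


def cwt_features(x: np.ndarray, widths: Sequence[int]) -> dict[int, float]:
    """Ricker continuous-wavelet coefficient at the window's central time.

    For each width the signal is convolved ('same' mode) with a kernel of
    ``min(10 * width, n)`` points and the coefficient at index ``n // 2`` is
    returned — one scalar per width.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    out: dict[int, float] = {}
    for w in widths:
        if w < 1:
            raise ValueError("width must be >= 1")
        kernel = ricker_kernel(min(10 * int(w), n), w)
        conv = np.convolve(x, kernel, mode="same")
        out[int(w)] = float(conv[n // 2]) if n else np.nan
    return out


def fit_population_medians(
    vitals: pd.DataFrame,
    labels: pd.DataFrame,
    cfg: WindowConfig,
    train_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Per-channel median of observed window samples over training rows."""
    pools: dict[str, list[np.ndarray]] = {ch: [] for ch in cfg.channels}
    rows = labels if train_mask is None else labels[np.asarray(train_mask, bool)]
    for _, row in rows.iterrows():
        pvit = vitals[vitals["patient_id"] == row["patient_id"]]
        arrays = extract_window(pvit, row["t_event"], cfg)
        for ch, arr in arrays.items():
            pools[ch].append(arr.ravel())
    medians = {}
    for ch, parts in pools.items():
        allv = np.concatenate(parts) if parts else np.array([np.nan])
        med = np.nanmedian(allv)
        medians[ch] = float(med) if np.isfinite(med) else 0.0
    return medians


@dataclass
class FeatureMatrix:
    """One row per labeled event; columns named
    ``{channel}__{extractor}__{param}__h{subwindow}``."""

    X: pd.DataFrame
    y: pd.Series
    dropped_columns: list[str] = field(default_factory=list)
    medians: dict[str, float] = field(default_factory=dict)
    config_hash: str = ""
    seed: int | None = None


def _event_features(
    arrays: Mapping[str, np.ndarray], cfg: WindowConfig, medians: Mapping[str, float]
) -> list[float]:
    row: list[float] = []
    for ch in cfg.channels:
        arr = arrays[ch]
        for h in range(cfg.n_subwindows):
            raw = arr[h]
            n_obs = int(np.sum(~np.isnan(raw)))
            filled = impute_stream(raw, medians[ch])
            st = statistical_features(filled, n_observed=n_obs)
            row.extend(st[s] for s in STAT_NAMES)
            ff = fft_features(filled, cfg.fft_params)
            row.extend(ff[k] for k in cfg.fft_params)
            cw = cwt_features(filled, cfg.cwt_widths)
            row.extend(cw[w] for w in cfg.cwt_widths)
    return row


def build_feature_matrix(
    labels: pd.DataFrame,
    vitals: pd.DataFrame,
    cfg: WindowConfig | None = None,
    medians: dict[str, float] | None = None,
    train_mask: np.ndarray | None = None,
    drop_null_columns: bool = True,
    fill_residual_nan: bool = True,
) -> FeatureMatrix:
    """Assemble the event-by-feature matrix for a labeled cohort.

    ``medians`` (or the rows selected by ``train_mask``) must come from the
    training split only, so no information leaks from held-out rows.  After
    all-null columns are dropped, residual per-row nulls (e.g. kurtosis of a
    constant hour) are filled with training-row column medians so downstream
    estimators see a complete matrix.
    """
    cfg = cfg or WindowConfig()
    cfg.validate()
    if len(labels) == 0:
        raise ValueError("no labeled events to featurize")
    if medians is None:
        medians = fit_population_medians(vitals, labels, cfg, train_mask)

    rows = []
    for _, ev in labels.iterrows():
        pvit = vitals[vitals["patient_id"] == ev["patient_id"]]
        arrays = extract_window(pvit, ev["t_event"], cfg)
        rows.append(_event_features(arrays, cfg, medians))

    index = pd.MultiIndex.from_frame(
        labels[["patient_id", "t_event"]], names=["patient_id", "t_event"]
    )
    X = pd.DataFrame(rows, columns=cfg.column_names(), index=index)
    y = pd.Series(
        labels["is_case"].to_numpy(dtype=bool), index=index, name="is_case"
    )

    dropped: list[str] = []
    if drop_null_columns:
        all_null = X.columns[X.isna().all(axis=0)]
        dropped = list(all_null)
        X = X.drop(columns=all_null)
    if fill_residual_nan and X.isna().any().any():
        train_rows = X if train_mask is None else X[np.asarray(train_mask, bool)]
        fill = train_rows.median(axis=0).fillna(0.0)
        X = X.fillna(fill)
    return FeatureMatrix(
        X=X, y=y, dropped_columns=dropped, medians=dict(medians), config_hash=cfg.hash()
    )
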