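"""End-to-end orchestration: simulate/load -> label -> extract -> select ->
train -> validate -> report, with seeded determinism and a structured log
of patient/feature counts at every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import WindowConfig, build_feature_matrix
from .labeling import label_cohort
from .modeling import ModelSpec, MetricsSummary, run_cv_iterations, validate_on_holdout
from .report import missingness_report, write_missingness_report
from .selection import SelectionConfig, select_features
from .synthetic import MissingnessProfile, SimulationConfig, simulate_cohort


@dataclass
class PipelineConfig:
    """Fully resolved configuration for one pipeline run.

    Either ``simulation`` is given (the cohort is generated) or the three
    table paths must exist.  ``holdout_simulation`` optionally generates an
    independent cohort (e.g. the transplant stream) for external validation.
    """

    seed: int
    out_dir: str = "run"
    simulation: SimulationConfig | None = None
    holdout_simulation: SimulationConfig | None = None
    vitals_path: str | None = None
    events_path: str | None = None
    labs_path: str | None = None
    window: WindowConfig = field(default_factory=WindowConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    n_iterations: int = 100
    n_folds: int = 5
    resubsample_each_iteration: bool = True

    def validate(self) -> None:
        if self.simulation is None:
            for p in (self.vitals_path, self.events_path, self.labs_path):
                if p is None:
                    raise ValueError(
                        "vitals/events/labs paths are required when simulation "
                        "is disabled"
                    )
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")

    def resolved(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def hash(self) -> str:
        # output location is provenance, not a parameter of the analysis
        payload = {k: v for k, v in self.resolved().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)

        def build(block_cls, key, **extra):
            block = raw.pop(key, None)
            if block is None:
                return None
            if "missingness" in block and isinstance(block["missingness"], dict):
                block = dict(block)
                block["missingness"] = MissingnessProfile(**block["missingness"])
            for tup_key in ("channels", "fft_params", "cwt_widths"):
                if tup_key in block:
                    block = dict(block)
                    block[tup_key] = tuple(block[tup_key])
            return block_cls(**{**block, **extra})

        sim = build(SimulationConfig, "simulation")
        holdout = build(SimulationConfig, "holdout_simulation")
        window = build(WindowConfig, "window") or WindowConfig()
        selection = build(SelectionConfig, "selection") or SelectionConfig()
        model = build(ModelSpec, "model") or ModelSpec()
        return cls(
            simulation=sim,
            holdout_simulation=holdout,
            window=window,
            selection=selection,
            model=model,
            **raw,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    out_dir: Path
    labels: pd.DataFrame
    feature_matrix: object
    selections: dict
    summary: MetricsSummary
    holdout_summary: MetricsSummary | None
    counts: dict


def _json_dumps(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full pipeline and serialize every artifact.

    Reruns with an identical (config, seed) produce byte-identical
    ``metrics.json``.  On a stage failure, partial outputs stay in the run
    directory next to a ``failed_<stage>.json`` marker naming the cause.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True)
    )
    log_path = out / "log.jsonl"
    log_fh = open(log_path, "w")
    counts: dict = {"config_hash": cfg_hash, "seed": config.seed}

    def log(stage: str, **kw):
        counts.update(kw)
        log_fh.write(json.dumps({"stage": stage, **kw}, sort_keys=True, default=str) + "\n")
        log_fh.flush()

    stage = "simulate"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate_cohort(sim)
            cohort.write(out / "data")
            vitals, events, labs = cohort.vitals, cohort.events, cohort.labs
            cohort.truth.to_csv(out / "truth.csv", index=False)
        else:
            vitals = pd.read_csv(config.vitals_path, parse_dates=["timestamp"])
            events = pd.read_csv(config.events_path, parse_dates=["timestamp"])
            labs = pd.read_csv(config.labs_path, parse_dates=["timestamp"])
        log(stage, patients_in=int(vitals["patient_id"].nunique()))

        stage = "label"
        lab_res = label_cohort(vitals, events, labs, seed=config.seed)
        lab_res.labels.to_csv(out / "labels.csv", index=False)
        log(stage, **lab_res.counts)

        stage = "extract"
        fm = build_feature_matrix(lab_res.labels, vitals, config.window)
        fm.X.assign(is_case=fm.y).to_csv(out / "features.csv")
        log(
            stage,
            features_pre_removal=config.window.n_features,
            features_post_removal=fm.X.shape[1],
            null_columns_dropped=len(fm.dropped_columns),
        )

        stage = "select"
        selections = select_features(fm, config.selection)
        sel_payload = {
            name: {
                "features": r.features,
                "scores": {k: round(float(v), 10) for k, v in r.scores.items()},
            }
            for name, r in selections.items()
        }
        (out / "selections.json").write_text(_json_dumps(sel_payload))
        chosen = selections[config.selection.method].features
        if not chosen:
            chosen = list(fm.X.columns)
            log(stage, warning="selection empty; falling back to all features")
        log(stage, **{f"selected_{k}": len(v.features) for k, v in selections.items()})

        stage = "train"
        sub_fm = (fm.X[chosen], fm.y.to_numpy(dtype=int))
        summary, folds = run_cv_iterations(
            sub_fm,
            config.model,
            n_iterations=config.n_iterations,
            n_folds=config.n_folds,
            seed=config.seed,
            resubsample_each_iteration=config.resubsample_each_iteration,
        )
        folds.to_csv(out / "fold_records.csv", index=False)
        log(stage, n_fold_records=len(folds))

        stage = "validate"
        holdout_summary = None
        if config.holdout_simulation is not None:
            ho_sim = dataclasses.replace(
                config.holdout_simulation, seed=config.seed + 1
            )
            ho = simulate_cohort(ho_sim)
            ho_labels = label_cohort(ho.vitals, ho.events, ho.labs, seed=config.seed + 1)
            # training medians only: no holdout information flows backward
            ho_fm = build_feature_matrix(
                ho_labels.labels,
                ho.vitals,
                config.window,
                medians=fm.medians,
                drop_null_columns=False,
            )
            ho_X = ho_fm.X[chosen].fillna(0.0)
            holdout_summary = validate_on_holdout(
                (fm.X[chosen], fm.y.to_numpy(dtype=int)),
                (ho_X, ho_fm.y.to_numpy(dtype=int)),
                config.model,
                seed=config.seed,
            )
            log(stage, holdout_patients=len(ho_labels.labels))

        stage = "report"
        qc = missingness_report(vitals, lab_res.labels, config.window)
        write_missingness_report(qc, out)
        metrics_payload = {
            "config_hash": cfg_hash,
            "seed": config.seed,
            "training": summary.to_dict(),
        }
        if holdout_summary is not None:
            metrics_payload["holdout"] = holdout_summary.to_dict()
        (out / "metrics.json").write_text(_json_dumps(metrics_payload))
        log(stage, done=True)
    except Exception as exc:
        (out / f"failed_{stage}.json").write_text(
            _json_dumps({"stage": stage, "error": repr(exc)})
        )
        log_fh.close()
        raise
    log_fh.close()
    return RunResult(
        out_dir=out,
        labels=lab_res.labels,
        feature_matrix=fm,
        selections=selections,
        summary=summary,
        holdout_summary=holdout_summary,
        counts=counts,
    )
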