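"""Experiment orchestration: cross-validation, frozen-model testing, reports.

The workflow mirrors the standard multicentric evaluation design: a single
cohort is split into three event-stratified cross-validation folds used to
train three fold models; the frozen fold models are then applied to each
independent test cohort, their predictions averaged pointwise into one
model-averaged prediction per patient, summarised as a bootstrap median
with 83% interval, and used for risk stratification with a threshold
derived from the validation folds only.  Patient-id leakage between the
cross-validation cohort and any test cohort aborts the run.

All randomness is funnelled through one experiment seed expanded into named
sub-seeds (fold split, weight initialisation, augmentation/training,
bootstrap), making the metric outputs byte-identical across runs on one
machine.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold

from . import evaluation
from .models import (ArchitectureConfig, ClinicalDataset, ConvBlock,
                     ImageDataset, TrainConfig, build_ann, build_cnn,
                     build_fusion, predict, train)
from .preprocessing import AugmentConfig, PreprocessConfig
from .survival import DiscreteTimeGrid, assemble_curve, encode_targets, \
    risk_at_horizon
from .synthetic import PatientRecord

__all__ = ["ExperimentConfig", "CVResult", "run_cv", "run_test",
           "full_experiment", "load_experiment_config"]

_FAMILIES = ("cnn2d", "cnn3d", "ann", "cnn2d_clinical", "cnn3d_clinical")


@dataclass(frozen=True)
class ExperimentConfig:
    task: str = "time_to_event"  # "binary" | "time_to_event"
    model_family: str = "cnn3d"
    input_mode: str = "standard"  # "standard" | "binary"
    cv_folds: int = 3
    horizon_years: float = 3.0
    n_bootstrap: int = 1000
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ann_hidden: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_family not in _FAMILIES:
            raise ValueError(f"model_family must be one of {_FAMILIES}")
        if self.task not in ("binary", "time_to_event"):
            raise ValueError("task must be binary or time_to_event")

    @property
    def grid(self) -> DiscreteTimeGrid:
        return DiscreteTimeGrid(self.arch.n_intervals, 0.5)

    @property
    def dimensionality(self) -> str:
        return "2D" if "2d" in self.model_family else "3D"

    @property
    def uses_images(self) -> bool:
        return self.model_family != "ann"

    @property
    def uses_clinical(self) -> bool:
        return self.model_family == "ann" or self.model_family.endswith("_clinical")

    def sub_seed(self, name: str) -> int:
        """Stable named sub-seed derived from the experiment seed."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a (possibly partial) YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    nested = {
        "preprocess": PreprocessConfig, "augment": AugmentConfig,
        "arch": ArchitectureConfig, "train": TrainConfig,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            if key == "arch" and "conv_blocks" in value:
                value["conv_blocks"] = tuple(
                    ConvBlock(*b) if isinstance(b, (list, tuple)) else ConvBlock(**b)
                    for b in value["conv_blocks"])
            for tup in ("hu_window", "rescale_range", "fc_sizes"):
                if tup in value:
                    value[tup] = tuple(value[tup])
            kwargs[key] = nested[key](**value)
        else:
            kwargs[key] = value
    return ExperimentConfig(**kwargs)


# ---------------------------------------------------------------------------

def _make_dataset(config: ExperimentConfig, records: list[PatientRecord]):
    if not config.uses_images:
        return ClinicalDataset(records)
    pre = replace(config.preprocess, input_mode=config.input_mode)
    return ImageDataset(records, pre, config.augment,
                        dimensionality=config.dimensionality,
                        with_clinical=config.uses_clinical)


def _build_model(config: ExperimentConfig, seed: int):
    arch = replace(config.arch,
                   dimensionality=config.dimensionality,
                   head=config.task,
                   crop_extent=config.preprocess.crop_extent)
    if config.model_family == "ann":
        return build_ann(head=config.task, n_intervals=arch.n_intervals,
                         hidden=config.ann_hidden,
                         dropout_rate=arch.dropout_rate, seed=seed)
    if config.uses_clinical:
        return build_fusion(arch, seed=seed)
    return build_cnn(arch, seed=seed)


def _risks_from_predictions(config: ExperimentConfig, pred: np.ndarray) -> np.ndarray:
    """Scalar risk per patient: sigmoid score (binary) or 1 - S(horizon)."""
    if config.task == "binary":
        return pred[:, 0]
    return risk_at_horizon(assemble_curve(pred), config.grid, config.horizon_years)


@dataclass
class CVResult:
    fold_models: list
    fold_metrics: list[float]
    fold_val_risks: list[np.ndarray]
    fold_val_events: list[np.ndarray]
    histories: list
    patient_ids: list[str]
    config_hash: str


def run_cv(config: ExperimentConfig, records: list[PatientRecord]) -> CVResult:
    """Event-stratified 3-fold cross-validation; one best-checkpoint model,
    its validation metric and its validation risks per fold."""
    events = np.array([r.event for r in records])
    times = np.array([r.time_years for r in records])
    if len(np.unique(events)) < 2:
        raise ValueError("cross-validation cohort contains a single outcome class")

    splitter = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                               random_state=config.sub_seed("split"))
    grid = config.grid
    fold_models, fold_metrics, histories = [], [], []
    fold_val_risks, fold_val_events = [], []
    for fold, (tr_idx, va_idx) in enumerate(splitter.split(np.zeros(len(records)), events)):
        if len(np.unique(events[va_idx])) < 2:
            raise ValueError(f"fold {fold}: validation set has a single outcome class")
        tr_records = [records[i] for i in tr_idx]
        va_records = [records[i] for i in va_idx]
        tr_data = _make_dataset(config, tr_records)
        va_data = _make_dataset(config, va_records)
        model = _build_model(config, seed=config.sub_seed(f"init{fold}"))
        tcfg = replace(config.train, seed=config.sub_seed(f"train{fold}"))
        if config.task == "time_to_event":
            history = train(
                model, tr_data, (times[tr_idx], events[tr_idx]),
                va_data, (times[va_idx], events[va_idx]), tcfg,
                task="time_to_event", grid=grid,
                targets=encode_targets(events[tr_idx], times[tr_idx], grid))
        else:
            history = train(model, tr_data, events[tr_idx], va_data,
                            events[va_idx], tcfg, task="binary")
        val_pred = predict(model, va_data)
        fold_models.append(model)
        fold_metrics.append(history.best_metric)
        histories.append(history)
        fold_val_risks.append(_risks_from_predictions(config, val_pred))
        fold_val_events.append(events[va_idx])
    return CVResult(fold_models=fold_models, fold_metrics=fold_metrics,
                    fold_val_risks=fold_val_risks,
                    fold_val_events=fold_val_events, histories=histories,
                    patient_ids=[r.patient_id for r in records],
                    config_hash=config.config_hash())


def run_test(config: ExperimentConfig, cv_result: CVResult,
             test_records: list[PatientRecord], cohort_name: str = "test") -> dict:
    """Frozen fold models -> ensemble -> bootstrap summary + stratification.

    Preprocessing is deterministic (central crop, no augmentation); the
    stratification threshold is computed from validation-fold risks only, so
    no test information can influence it.  Any patient id shared with the
    cross-validation cohort aborts the run.
    """
    test_ids = [r.patient_id for r in test_records]
    shared = set(test_ids) & set(cv_result.patient_ids)
    if shared:
        raise ValueError(
            f"cohort {cohort_name!r} shares patients with the CV cohort: {sorted(shared)[:5]}")

    data = _make_dataset(config, test_records)
    per_fold = [predict(m, data) for m in cv_result.fold_models]
    ensemble = evaluation.average_ensemble(per_fold, patient_ids=[test_ids] * len(per_fold))
    risks = _risks_from_predictions(config, ensemble.values)
    times = np.array([r.time_years for r in test_records])
    events = np.array([r.event for r in test_records])

    if config.task == "binary":
        summary = evaluation.bootstrap_metric(
            risks, events, metric="AUC", n_bootstrap=config.n_bootstrap,
            seed=config.sub_seed("bootstrap"))
    else:
        summary = evaluation.bootstrap_metric(
            risks, (times, events), metric="HCI",
            n_bootstrap=config.n_bootstrap, seed=config.sub_seed("bootstrap"))
    threshold = evaluation.find_threshold(cv_result.fold_val_risks,
                                          cv_result.fold_val_events)
    strat = evaluation.stratify_and_test(risks, times, events, threshold.threshold)

    report = {
        "cohort": cohort_name,
        "config_hash": cv_result.config_hash,
        "n_patients": len(test_records),
        "metric": summary.metric_name,
        "median": summary.median,
        "lo83": summary.lo83,
        "hi83": summary.hi83,
        "threshold": threshold.threshold,
        "fold_thresholds": list(threshold.fold_thresholds),
        "n_high_risk": int(strat.labels.sum()),
        "n_low_risk": int((~strat.labels).sum()),
        "logrank_statistic": strat.logrank_statistic,
        "logrank_p": strat.p_value,
        "stratification_note": strat.note,
    }
    if config.task == "time_to_event":
        report["survival_curves"] = {
            pid: assemble_curve(ensemble.values[i]).tolist()
            for i, pid in enumerate(test_ids)
        }
    report["_km_tables"] = strat.km_tables
    return report


def full_experiment(config: ExperimentConfig,
                    cv_records: list[PatientRecord],
                    test_cohorts: dict[str, list[PatientRecord]],
                    out_dir: str | Path | None = None) -> dict:
    """Cross-validate, then test on every independent cohort.

    Returns one consolidated report (per-cohort bootstrap summaries,
    stratification p-values and, for the time-to-event task, per-patient
    survival curves); optionally writes JSON/CSV outputs and Kaplan-Meier
    plots to ``out_dir``.
    """
    cv_result = run_cv(config, cv_records)
    report = {
        "config_hash": cv_result.config_hash,
        "task": config.task,
        "model_family": config.model_family,
        "input_mode": config.input_mode,
        "cv_metrics": list(cv_result.fold_metrics),
        "cohorts": {},
    }
    for name, records in test_cohorts.items():
        report["cohorts"][name] = run_test(config, cv_result, records, cohort_name=name)

    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    serializable = {
        k: v for k, v in report.items() if k != "cohorts"
    }
    serializable["cohorts"] = {}
    for name, cohort in report["cohorts"].items():
        entry = {k: v for k, v in cohort.items() if not k.startswith("_")}
        serializable["cohorts"][name] = entry
        for group, table in cohort.get("_km_tables", {}).items():
            table.to_csv(out_dir / f"km_{name}_{group}.csv", index=False)
        if cohort.get("_km_tables"):
            fig, ax = plt.subplots(figsize=(5, 4))
            for group, table in cohort["_km_tables"].items():
                ax.step(table["time"], table["survival"], where="post", label=group)
            ax.set_xlabel("years")
            ax.set_ylabel("event-free probability")
            p = cohort.get("logrank_p")
            ax.set_title(f"{name} (log-rank p = {p:.3g})" if p is not None else name)
            ax.legend()
            fig.savefig(out_dir / f"km_{name}.png", dpi=120)
            plt.close(fig)
    (out_dir / "report.json").write_text(json.dumps(serializable, indent=2))
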