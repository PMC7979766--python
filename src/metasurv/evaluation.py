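"""Metrics and statistical procedures.

Discrimination is measured with the area under the ROC curve (binary task)
or Harrell's concordance index evaluated on a fixed-horizon risk (one minus
the 3-year event-free probability) for the time-to-event task.  Cohort-level
uncertainty uses bootstrap resampling of patients: the median metric with an
83% percentile interval, chosen because two non-overlapping 83% intervals
correspond to a two-sample difference at significance level ~0.05.
Risk stratification derives a threshold from validation folds only (mean of
the per-fold midpoints between the average risk of event and non-event
patients) and is assessed on held-out patients with Kaplan-Meier curves and
the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from sklearn.metrics import roc_auc_score

__all__ = [
    "concordance_index", "auc", "EnsemblePrediction", "average_ensemble",
    "BootstrapSummary", "bootstrap_metric", "bootstrap_median_interval",
    "ci83_different", "ci83_calibration", "StratificationThreshold",
    "find_threshold", "StratificationResult", "stratify_and_test",
]


def concordance_index(risks, times, events) -> float:
    """Harrell's concordance between predicted risk and observed event time.

    Permissible pairs follow the standard Harrell rules (both events, or one
    event preceding the other patient's censoring time); a pair is
    concordant when the higher risk belongs to the shorter event time, and
    tied risks receive half credit.  Raises ``ValueError`` when no
    permissible pair exists.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not (len(risks) == len(times) == len(events)):
        raise ValueError("risks, times and events must have equal length")
    try:
        # lifelines scores higher prediction <-> longer survival; negate risk
        return float(_lifelines_cindex(times, -risks, events))
    except ZeroDivisionError as err:
        raise ValueError("no permissible pairs for concordance") from err


def auc(scores, labels) -> float:
    """Rank-statistic ROC AUC (ties credited 0.5); needs both classes."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class EnsemblePrediction:
    """Pointwise mean of per-fold predictions (curves or scores)."""

    values: np.ndarray
    provenance: tuple[int, ...]


def average_ensemble(per_fold_predictions, patient_ids=None) -> EnsemblePrediction:
    """Average the cross-validation fold models' predictions pointwise.

    All folds must predict the same patients in the same order; when
    ``patient_ids`` (one list per fold) is given this is verified.
    """
    arrays = [np.asarray(p, dtype=float) for p in per_fold_predictions]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"fold predictions disagree in shape: {shapes}")
    if patient_ids is not None:
        first = list(patient_ids[0])
        for k, ids in enumerate(patient_ids[1:], start=1):
            if list(ids) != first:
                raise ValueError(f"fold {k} predicts different patients than fold 0")
    return EnsemblePrediction(values=np.mean(arrays, axis=0),
                              provenance=tuple(range(len(arrays))))


@dataclass(frozen=True)
class BootstrapSummary:
    metric_name: str
    median: float
    lo83: float
    hi83: float
    n_bootstrap: int
    seed: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if not self.lo83 <= self.median <= self.hi83:
            raise ValueError("interval must bracket the median")


_PCT_LO, _PCT_HI = 8.5, 91.5  # 83% central percentile interval


def bootstrap_metric(values, outcomes, metric: str = "HCI",
                     n_bootstrap: int = 1000, seed: int = 0) -> BootstrapSummary:
    """Median metric with 83% percentile interval over patient resamples.

    ``values`` holds per-patient risks (HCI) or scores (AUC); ``outcomes``
    is ``(times, events)`` for HCI and a label vector for AUC.  Replicates
    on which the metric is undefined (single class, no permissible pairs)
    are redrawn so the number of replicates stays fixed; more than 50%
    undefined draws raise.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if metric == "HCI":
        times = np.asarray(outcomes[0], dtype=float)
        events = np.asarray(outcomes[1])
        compute = lambda idx: concordance_index(values[idx], times[idx], events[idx])
    elif metric == "AUC":
        labels = np.asarray(outcomes)
        compute = lambda idx: auc(values[idx], labels[idx])
    else:
        raise ValueError(f"unknown metric {metric!r}")

    rng = np.random.default_rng(seed)
    replicates = np.empty(n_bootstrap)
    redrawn = 0
    max_attempts = 2 * n_bootstrap
    i = attempts = 0
    while i < n_bootstrap:
        if attempts >= max_attempts:
            raise ValueError("metric undefined in more than 50% of bootstrap replicates")
        idx = rng.integers(0, n, size=n)
        attempts += 1
        try:
            replicates[i] = compute(idx)
        except ValueError:
            redrawn += 1
            continue
        i += 1
    lo, hi = np.percentile(replicates, [_PCT_LO, _PCT_HI])
    return BootstrapSummary(metric_name=metric,
                            median=float(np.median(replicates)),
                            lo83=float(lo), hi83=float(hi),
                            n_bootstrap=n_bootstrap, seed=seed,
                            n_redrawn=redrawn)


def bootstrap_median_interval(sample: np.ndarray, n_bootstrap: int,
                              rng: np.random.Generator) -> tuple[float, float]:
    """83% percentile interval for the median of one sample (vectorised)."""
    sample = np.asarray(sample, dtype=float)
    idx = rng.integers(0, len(sample), size=(n_bootstrap, len(sample)))
    medians = np.median(sample[idx], axis=1)
    lo, hi = np.percentile(medians, [_PCT_LO, _PCT_HI])
    return float(lo), float(hi)


def ci83_different(a: BootstrapSummary, b: BootstrapSummary) -> bool:
    """Significance-at-0.05 surrogate: disjoint 83% intervals.

    Touching endpoints count as overlap (conservative), so identical
    summaries are never declared different.
    """
    if a.metric_name != b.metric_name:
        raise ValueError("summaries measure different metrics")
    return a.hi83 < b.lo83 or b.hi83 < a.lo83


def ci83_calibration(n_outer: int = 1000, n_sample: int = 100,
                     n_bootstrap: int = 1000, seed: int = 0) -> float:
    """Type-I error of the interval-overlap rule under the null.

    Repeatedly draws two independent Gaussian samples from the same
    distribution, bootstraps each median's 83% interval and records how
    often the intervals are disjoint.  For a well-calibrated rule the
    returned rate is close to 0.05.
    """
    rng = np.random.default_rng(seed)
    disjoint = 0
    for _ in range(n_outer):
        x = rng.standard_normal(n_sample)
        y = rng.standard_normal(n_sample)
        lo_x, hi_x = bootstrap_median_interval(x, n_bootstrap, rng)
        lo_y, hi_y = bootstrap_median_interval(y, n_bootstrap, rng)
        if hi_x < lo_y or hi_y < lo_x:
            disjoint += 1
    return disjoint / n_outer


@dataclass(frozen=True)
class StratificationThreshold:
    """Model-averaged risk threshold from the validation folds."""

    threshold: float
    fold_thresholds: tuple[float, ...]


def find_threshold(validation_risks, validation_events) -> StratificationThreshold:
    """Per fold, the midpoint between the mean risk of event and non-event
    validation patients; the final threshold is the mean over folds."""
    fold_values = []
    for k, (risks, events) in enumerate(zip(validation_risks, validation_events)):
        risks = np.asarray(risks, dtype=float)
        events = np.asarray(events).astype(bool)
        if events.all() or not events.any():
            raise ValueError(f"fold {k}: validation set contains a single outcome class")
        fold_values.append(0.5 * (risks[events].mean() + risks[~events].mean()))
    return StratificationThreshold(threshold=float(np.mean(fold_values)),
                                   fold_thresholds=tuple(fold_values))


@dataclass
class StratificationResult:
    labels: np.ndarray  # True = high risk
    km_tables: dict = field(default_factory=dict)
    logrank_statistic: float | None = None
    p_value: float | None = None
    note: str = ""


def stratify_and_test(test_risks, test_times, test_events,
                      threshold: float) -> StratificationResult:
    """Split by risk threshold, fit Kaplan-Meier per group, run log-rank.

    High-risk is strict ``risk > threshold``.  If either group is empty the
    result reports the fact and carries no test.
    """
    risks = np.asarray(test_risks, dtype=float)
    times = np.asarray(test_times, dtype=float)
    events = np.asarray(test_events)
    high = risks > threshold
    result = StratificationResult(labels=high)
    if high.all() or not high.any():
        result.note = "one risk group is empty; log-rank test not performed"
        return result
    for name, sel in (("low", ~high), ("high", high)):
        kmf = KaplanMeierFitter(label=name)
        kmf.fit(times[sel], events[sel])
        table = kmf.survival_function_.reset_index()
        table.columns = ["time", "survival"]
        table["at_risk"] = [
            int((times[sel] >= t).sum()) for t in table["time"]
        ]
        result.km_tables[name] = table
    lr = logrank_test(times[high], times[~high], events[high], events[~high])
    result.logrank_statistic = float(lr.test_statistic)
    result.p_value = float(lr.p_value)
    return result
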