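"""Discrete-time survival machinery.

The follow-up axis is cut into ``n_intervals`` equal intervals (default ten
half-year intervals covering five years).  A time-to-event network outputs,
per interval, the conditional probability ``p[j]`` of remaining event-free
through interval ``j`` given the patient was event-free at its start.  The
survival curve is the running product of those conditional probabilities,
and the scalar "risk" used for concordance and stratification is one minus
the survival probability at a fixed horizon (three years by default).

Supervision uses the standard discrete-time censoring-aware encoding: an
uncensored patient contributes a "survived" indicator for every interval
fully lived through and an "event" indicator for the interval containing the
event; a censored patient contributes survived indicators for every interval
whose midpoint precedes the censoring time (half-interval credit) and no
event indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscreteTimeGrid",
    "SurvivalTarget",
    "encode_target",
    "encode_targets",
    "survival_loss",
    "survival_loss_grad",
    "assemble_curve",
    "risk_at_horizon",
    "PROB_EPS",
]

#: conditional probabilities are clamped to [PROB_EPS, 1 - PROB_EPS] in the loss
PROB_EPS = 1e-7


@dataclass(frozen=True)
class DiscreteTimeGrid:
    """Lattice of equal-width follow-up intervals.

    Parameters
    ----------
    n_intervals
        Number of intervals (default 10).
    width_years
        Width of each interval in years (default 0.5).
    """

    n_intervals: int = 10
    width_years: float = 0.5

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.width_years <= 0:
            raise ValueError("width_years must be > 0")

    @property
    def edges(self) -> np.ndarray:
        """Interval boundaries ``[0, w, 2w, ..., n*w]`` in years."""
        return np.arange(self.n_intervals + 1) * self.width_years

    @property
    def midpoints(self) -> np.ndarray:
        """Interval midpoints in years."""
        return (np.arange(self.n_intervals) + 0.5) * self.width_years

    @property
    def span_years(self) -> float:
        return self.n_intervals * self.width_years


@dataclass(frozen=True)
class SurvivalTarget:
    """Per-interval censoring-aware supervision for one patient.

    ``survived[j] = 1`` marks interval ``j`` as fully survived (or credited
    for a censored patient); ``event_at[j] = 1`` marks the interval in which
    the event occurred.  At most one ``event_at`` entry is set, and no index
    carries both indicators.
    """

    survived: np.ndarray = field(repr=False)
    event_at: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.survived, dtype=float)
        e = np.asarray(self.event_at, dtype=float)
        if s.shape != e.shape:
            raise ValueError("survived and event_at must share shape")
        if e.sum() > 1:
            raise ValueError("at most one event interval allowed")
        if np.any((s > 0) & (e > 0)):
            raise ValueError("an interval cannot be both survived and event")
        object.__setattr__(self, "survived", s)
        object.__setattr__(self, "event_at", e)

    def as_array(self) -> np.ndarray:
        """Stacked ``[survived, event_at]`` of shape ``(2 * n_intervals,)``."""
        return np.concatenate([self.survived, self.event_at])


def encode_target(event: int, time_years: float, grid: DiscreteTimeGrid) -> SurvivalTarget:
    """Encode one outcome into per-interval supervision indicators.

    For an observed event at time ``t``, every interval ending at or before
    ``t`` is marked survived and the interval containing ``t`` is marked as
    the event interval.  A censored patient receives survived credit for
    every interval whose midpoint lies at or before the censoring time
    (half-interval credit); events or censoring beyond the grid span are
    treated as survivors of all intervals.
    """
    if time_years <= 0:
        raise ValueError(f"time_years must be positive, got {time_years}")
    n = grid.n_intervals
    upper = grid.edges[1:]
    survived = np.zeros(n)
    event_at = np.zeros(n)
    if event:
        survived[:] = (time_years >= upper).astype(float)
        inside = np.nonzero(time_years < upper)[0]
        if inside.size:  # beyond the grid: survivor of all intervals
            event_at[inside[0]] = 1.0
    else:
        survived[:] = (time_years >= grid.midpoints).astype(float)
    return SurvivalTarget(survived=survived, event_at=event_at)


def encode_targets(
    events: np.ndarray, times: np.ndarray, grid: DiscreteTimeGrid
) -> np.ndarray:
    """Vectorised :func:`encode_target` → array ``(n_patients, 2 * n_intervals)``."""
    events = np.asarray(events)
    times = np.asarray(times, dtype=float)
    return np.stack(
        [encode_target(int(e), float(t), grid).as_array() for e, t in zip(events, times)]
    )


def _split_targets(targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = targets.shape[1] // 2
    return targets[:, :n], targets[:, n:]


def survival_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-likelihood of the discrete-time survival model.

    ``predictions`` holds per-patient conditional event-free probabilities
    (shape ``(n_patients, n_intervals)``); ``targets`` the stacked
    ``[survived, event_at]`` encoding.  Per patient the contribution is
    ``-sum_j survived[j] * log p[j] + event_at[j] * log(1 - p[j])`` and the
    batch loss is the mean over patients.
    """
    p = np.clip(np.atleast_2d(np.asarray(predictions, dtype=float)), PROB_EPS, 1 - PROB_EPS)
    survived, event_at = _split_targets(targets)
    if p.shape != survived.shape:
        raise ValueError(f"prediction shape {p.shape} does not match target shape {survived.shape}")
    per_patient = -(survived * np.log(p) + event_at * np.log1p(-p)).sum(axis=1)
    return float(per_patient.mean())


def survival_loss_grad(predictions: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Gradient of :func:`survival_loss` with respect to the predictions.

    Entries clamped by the numeric guard receive zero gradient.
    """
    raw = np.atleast_2d(np.asarray(predictions, dtype=float))
    p = np.clip(raw, PROB_EPS, 1 - PROB_EPS)
    survived, event_at = _split_targets(targets)
    grad = -(survived / p - event_at / (1.0 - p)) / p.shape[0]
    grad[(raw < PROB_EPS) | (raw > 1 - PROB_EPS)] = 0.0
    return grad


def assemble_curve(p: np.ndarray) -> np.ndarray:
    """Cumulative product of conditional probabilities → survival curve.

    ``S[j] = prod_{k <= j} p[k]``; accepts a single curve or a batch with
    intervals on the last axis.
    """
    p = np.asarray(p, dtype=float)
    return np.cumprod(p, axis=-1)


def risk_at_horizon(
    curve: np.ndarray, grid: DiscreteTimeGrid, horizon_years: float = 3.0
) -> np.ndarray | float:
    """Event risk ``1 - S(horizon)`` read off the survival curve.

    The horizon must coincide with or exceed the end of at least one
    interval and lie within the grid span; the survival value of the last
    interval ending at or before the horizon is used (interval index 5 for
    a three-year horizon on the default ten-by-half-year grid).
    """
    curve = np.asarray(curve, dtype=float)
    if horizon_years > grid.span_years + 1e-9:
        raise ValueError(
            f"horizon {horizon_years} y exceeds grid span {grid.span_years} y"
        )
    n_complete = int(np.floor(horizon_years / grid.width_years + 1e-9))
    if n_complete < 1:
        raise ValueError("horizon shorter than the first interval")
    risk = 1.0 - curve[..., n_complete - 1]
    return float(risk) if risk.ndim == 0 else risk
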