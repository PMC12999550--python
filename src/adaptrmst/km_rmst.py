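"""Kaplan-Meier estimation and restricted mean survival time (RMST).

Handles right-censored data that may additionally be left-truncated
(delayed entry), as needed for the second-stage data of a two-stage
adaptive trial: patients recruited before the interim analysis enter the
stage-2 risk sets only after their time under observation at interim.

The RMST up to a horizon ``tau`` is the area under the survival curve on
``[0, tau]``; its standard error is the Greenwood-type integrated-area
estimator (the convention of the R ``survival`` package): for each event
time ``t_i <= tau``,

    var(mu_hat) = sum_i  A_i^2 * d_i / (Y_i * (Y_i - d_i)),

where ``A_i`` is the remaining area under the curve on ``(t_i, tau]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObservedRecord",
    "KMCurve",
    "RMSTEstimate",
    "km_fit",
    "rmst",
    "rmst_difference",
]


@dataclass(frozen=True)
class ObservedRecord:
    """One subject's observed follow-up.

    ``followup_time`` is min(event time, dropout time, tau) in years,
    ``event`` is 1 for an observed event and 0 for censoring, and
    ``truncation_time`` is the delayed-entry time (0 when the subject is
    under observation from time origin). ``arm`` is "I" or "C".
    """

    followup_time: float
    event: int
    truncation_time: float = 0.0
    arm: str = "C"

    def __post_init__(self) -> None:
        if self.followup_time < 0:
            raise ValueError("followup_time must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.truncation_time > 0 and self.followup_time <= self.truncation_time:
            raise ValueError("invalid truncation: need followup_time > truncation_time")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value of the curve at time ``t`` (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class RMSTEstimate:
    tau: float
    mu_hat: float
    se: float
    n_used: int
    no_events: bool = field(default=False)


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coerce records to (time, event, entry) float/int arrays.

    Accepts a sequence of :class:`ObservedRecord`, a ``(time, event)`` or
    ``(time, event, entry)`` tuple of array-likes, or an object exposing
    ``time``, ``event`` and ``entry`` attributes.
    """
    if hasattr(records, "time") and hasattr(records, "event"):
        time = np.asarray(records.time, dtype=float)
        event = np.asarray(records.event)
        entry = getattr(records, "entry", None)
        entry = np.zeros_like(time) if entry is None else np.asarray(entry, dtype=float)
        return time, event.astype(np.int8), entry
    if isinstance(records, tuple) and len(records) in (2, 3):
        time = np.asarray(records[0], dtype=float)
        event = np.asarray(records[1]).astype(np.int8)
        entry = (
            np.asarray(records[2], dtype=float)
            if len(records) == 3
            else np.zeros_like(time)
        )
        return time, event, entry
    recs = list(records)
    time = np.array([r.followup_time for r in recs], dtype=float)
    event = np.array([r.event for r in recs], dtype=np.int8)
    entry = np.array([r.truncation_time for r in recs], dtype=float)
    return time, event, entry


def km_fit(records) -> KMCurve:
    """Fit the product-limit estimator, honouring delayed entry.

    The risk set at time ``t`` is ``#{j : entry_j < t <= time_j}``;
    with all entry times zero this is the ordinary right-censored
    Kaplan-Meier estimator.
    """
    time, event, entry = _as_arrays(records)
    if time.size == 0:
        raise ValueError("no records")
    if np.any((entry > 0) & (time <= entry)):
        raise ValueError("invalid truncation: followup_time must exceed truncation_time")

    event_mask = event == 1
    if not np.any(event_mask):
        empty = np.empty(0)
        return KMCurve(empty, empty, np.empty(0, dtype=int), np.empty(0, dtype=int), time.size)

    t, d = np.unique(time[event_mask], return_counts=True)
    time_sorted = np.sort(time)
    n_exited = np.searchsorted(time_sorted, t, side="left")  # #{time < t}
    if np.any(entry > 0):
        entry_sorted = np.sort(entry)
        n_entered = np.searchsorted(entry_sorted, t, side="left")  # #{entry < t}
    else:
        n_entered = np.full(t.shape, time.size)
    at_risk = n_entered - n_exited
    survival = np.cumprod(1.0 - d / at_risk)
    return KMCurve(t, survival, at_risk.astype(int), d.astype(int), time.size)


def rmst(curve: KMCurve, tau: float) -> RMSTEstimate:
    """Area under the step curve on ``[0, tau]`` with Greenwood-type SE.

    If the curve has no event before ``tau`` the estimate is ``tau`` and
    the standard error is reported as 0 with ``no_events`` flagged.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    keep = curve.event_times <= tau
    t = curve.event_times[keep]
    if t.size == 0:
        return RMSTEstimate(tau, float(tau), 0.0, curve.n, no_events=True)
    s = curve.survival[keep]
    d = curve.events[keep].astype(float)
    y = curve.at_risk[keep].astype(float)

    grid = np.concatenate(([0.0], t, [tau]))
    step_vals = np.concatenate(([1.0], s))  # value on [grid_i, grid_{i+1})
    seg_areas = step_vals * np.diff(grid)
    mu = float(seg_areas.sum())
    # A_i = area on (t_i, tau] = sum of segment areas strictly after event i
    tail = np.cumsum(seg_areas[::-1])[::-1][1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = tail**2 * d / (y * (y - d))
    terms[~np.isfinite(terms)] = 0.0  # curve hit zero: remaining area is zero
    return RMSTEstimate(tau, mu, float(np.sqrt(terms.sum())), curve.n)


def rmst_difference(data_I, data_C, tau: float) -> tuple[float, float]:
    """RMST difference (intervention minus control) and its scaled SD.

    Returns ``(delta_hat, sigma_hat)`` with
    ``sigma_hat = sqrt(n * (se_I^2 + se_C^2))`` and ``n`` the total number
    of subjects supplied, so that ``sqrt(n) * delta_hat / sigma_hat`` is
    the standardized test statistic: under 1:1 allocation
    ``se_arm^2 ~ v_arm / (n/2)``, hence ``sigma_hat^2 ~ 2*(v_I + v_C) =
    n * Var(delta_hat)``.
    """
    est_I = rmst(km_fit(data_I), tau)
    est_C = rmst(km_fit(data_C), tau)
    if est_I.no_events or est_C.no_events:
        warnings.warn(
            "an arm has no event before tau; variance uses the other arm only",
            RuntimeWarning,
            stacklevel=2,
        )
    n = est_I.n_used + est_C.n_used
    sigma = np.sqrt(n * (est_I.se**2 + est_C.se**2))
    return est_I.mu_hat - est_C.mu_hat, float(sigma)
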