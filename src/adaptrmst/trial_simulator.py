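"""Simulation of delayed-treatment-effect trials and stage-wise data assembly.

The data-generating model is the canonical delayed-effect pattern: both arms
share a constant hazard ``lambda0`` up to a change-point ``t0``; afterwards
the hazards are constant but arm-specific (``lambdaI`` for intervention,
``lambdaC`` for control). Entry (calendar) times are uniform over the accrual
window, time to loss of follow-up is exponential with rate ``dropout_rate``,
and — apart from dropout — every patient is followed for exactly ``tau``
years.

The two analysis stages of the adaptive design are assembled here:

* stage 1 (interim) data: follow-up administratively censored at the
  interim calendar time ``t_int``;
* stage 2 data: the *post-interim* follow-up of stage-1 patients still
  under observation at interim (left-truncated at their time under
  observation) together with all newly recruited patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HazardScenario",
    "Subjects",
    "StageData",
    "simulate_subjects",
    "observe_full",
    "interim_snapshot",
    "stage_two_assemble",
    "pooled_full_data",
    "censoring_probability",
    "read_subjects",
    "write_subjects",
]


def two_piece_rmst(t0: float, lambda0: float, lam: float, tau: float) -> float:
    """Closed-form RMST on [0, tau] for the two-piece exponential hazard."""
    if t0 >= tau:
        raise ValueError("t0 must be smaller than tau")
    early = (1.0 - np.exp(-lambda0 * t0)) / lambda0
    late = np.exp(-lambda0 * t0) * (1.0 - np.exp(-lam * (tau - t0))) / lam
    return float(early + late)


def two_piece_survival(t, t0: float, lambda0: float, lam: float):
    """Survival function of the two-piece exponential hazard."""
    t = np.asarray(t, dtype=float)
    return np.where(
        t <= t0, np.exp(-lambda0 * t), np.exp(-lambda0 * t0 - lam * (t - t0))
    )


@dataclass(frozen=True)
class HazardScenario:
    """Data-generating parameters of one trial configuration.

    Rates are per year; ``dropout_rate`` is the exponential rate of the
    time to loss of follow-up (0 disables dropout); ``tE`` is the accrual
    duration.
    """

    t0: float
    lambda0: float
    lambdaC: float
    lambdaI: float
    dropout_rate: float
    tau: float
    tE: float

    def __post_init__(self) -> None:
        if min(self.lambda0, self.lambdaC, self.lambdaI) <= 0:
            raise ValueError("hazard rates must be positive")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be non-negative")
        if not 0 < self.t0 < self.tau:
            raise ValueError("need 0 < t0 < tau")

    @property
    def delta(self) -> float:
        """True RMST difference implied by the hazard parameters."""
        return two_piece_rmst(
            self.t0, self.lambda0, self.lambdaI, self.tau
        ) - two_piece_rmst(self.t0, self.lambda0, self.lambdaC, self.tau)

    def with_rates(self, **kwargs) -> "HazardScenario":
        return replace(self, **kwargs)


@dataclass
class Subjects:
    """Latent per-subject draws: calendar entry, event and dropout times."""

    entry: np.ndarray
    event_time: np.ndarray
    dropout_time: np.ndarray
    arm_I: np.ndarray  # boolean, True for intervention

    @property
    def n(self) -> int:
        return self.entry.size


@dataclass
class StageData:
    """Observed records for one analysis stage.

    ``entry`` holds the left-truncation times (0 for subjects under
    observation from their time origin). For interim-stage data,
    ``admin_censor`` stores the administrative censoring times
    ``t_int - E`` needed for interim nuisance estimation, and
    ``calendar_entry`` the calendar entry times.
    """

    stage: str  # interim | stage2 | all
    time: np.ndarray
    event: np.ndarray
    entry: np.ndarray
    arm_I: np.ndarray
    n1: int = 0
    n2: int = 0
    n_pipeline: int = 0
    tau: float = np.nan
    admin_censor: np.ndarray | None = field(default=None, repr=False)
    calendar_entry: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.time.size

    def arm(self, label: str):
        """Records of one arm as a ``(time, event, entry)`` triple."""
        mask = self.arm_I if label == "I" else ~self.arm_I
        return self.time[mask], self.event[mask], self.entry[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "entry_time": (
                    self.calendar_entry
                    if self.calendar_entry is not None
                    else np.zeros(self.n)
                ),
                "followup_time": self.time,
                "event": self.event.astype(int),
                "truncation_time": self.entry,
                "arm": np.where(self.arm_I, "I", "C"),
            }
        )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_subjects(
    scenario: HazardScenario,
    n: int,
    accrual_window: tuple[float, float] | None = None,
    seed=None,
) -> Subjects:
    """Draw ``n`` subjects (1:1 allocation, alternating within entry order).

    Event times follow the two-piece exponential by inversion: an
    exponential(lambda0) draw is kept if it falls before ``t0``, otherwise
    the residual beyond ``t0`` is redrawn from the arm-specific late
    hazard (memorylessness of the piecewise-constant model).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n % 2:
        raise ValueError("n must be even for 1:1 allocation")
    rng = _rng(seed)
    lo, hi = accrual_window if accrual_window is not None else (0.0, scenario.tE)
    entry = np.sort(rng.uniform(lo, hi, n))
    arm_I = np.zeros(n, dtype=bool)
    arm_I[::2] = True  # alternate I, C in entry order

    early = rng.exponential(1.0 / scenario.lambda0, n)
    late_rate = np.where(arm_I, scenario.lambdaI, scenario.lambdaC)
    residual = rng.exponential(1.0, n) / late_rate
    event_time = np.where(early <= scenario.t0, early, scenario.t0 + residual)
    if scenario.dropout_rate > 0:
        dropout = rng.exponential(1.0 / scenario.dropout_rate, n)
    else:
        dropout = np.full(n, np.inf)
    return Subjects(entry, event_time, dropout, arm_I)


def observe_full(subjects: Subjects, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Final-analysis follow-up time and event indicator per subject."""
    time = np.minimum(np.minimum(subjects.event_time, subjects.dropout_time), tau)
    event = subjects.event_time <= np.minimum(subjects.dropout_time, tau)
    return time, event


def interim_snapshot(subjects: Subjects, t_int: float, tau: float) -> StageData:
    """Stage-1 data: follow-up administratively censored at ``t_int``."""
    if np.any(subjects.entry >= t_int):
        raise ValueError("stage-1 subjects must have entered before t_int")
    admin = t_int - subjects.entry
    time_full, event_full = observe_full(subjects, tau)
    time = np.minimum(time_full, admin)
    event = event_full & (time_full <= admin)
    # still under observation at interim: administratively censored before
    # both the event/dropout time and the tau-year completion
    pipeline = (~event) & (admin < time_full) & (admin < tau)
    return StageData(
        stage="interim",
        time=time,
        event=event,
        entry=np.zeros_like(time),
        arm_I=subjects.arm_I,
        n1=subjects.n,
        n_pipeline=int(pipeline.sum()),
        tau=tau,
        admin_censor=admin,
        calendar_entry=subjects.entry,
    )


def stage_two_assemble(
    subjects: Subjects,
    t_int: float,
    new_subjects: Subjects | None,
    tau: float,
) -> StageData:
    """Stage-2 data: post-interim follow-up plus newly recruited patients.

    Stage-1 patients enter left-truncated at their time under observation
    at interim (``t_int - E``); a patient whose follow-up had already
    ended at interim contributes nothing to stage 2.
    """
    admin = t_int - subjects.entry
    time_full, event_full = observe_full(subjects, tau)
    pipe = time_full > admin  # follow-up continued past the interim look
    times = [time_full[pipe]]
    events = [event_full[pipe]]
    entries = [admin[pipe]]
    arms = [subjects.arm_I[pipe]]
    calendar = [subjects.entry[pipe]]
    n2 = 0
    if new_subjects is not None and new_subjects.n > 0:
        t_new, e_new = observe_full(new_subjects, tau)
        times.append(t_new)
        events.append(e_new)
        entries.append(np.zeros(new_subjects.n))
        arms.append(new_subjects.arm_I)
        calendar.append(new_subjects.entry)
        n2 = new_subjects.n
    return StageData(
        stage="stage2",
        time=np.concatenate(times),
        event=np.concatenate(events),
        entry=np.concatenate(entries),
        arm_I=np.concatenate(arms),
        n1=subjects.n,
        n2=n2,
        n_pipeline=int(pipe.sum()),
        tau=tau,
        calendar_entry=np.concatenate(calendar),
    )


def pooled_full_data(
    subjects: Subjects, new_subjects: Subjects | None, tau: float
) -> StageData:
    """Full-follow-up data of all patients (used by the pooled statistic)."""
    if new_subjects is not None and new_subjects.n > 0:
        entry = np.concatenate((subjects.entry, new_subjects.entry))
        merged = Subjects(
            entry,
            np.concatenate((subjects.event_time, new_subjects.event_time)),
            np.concatenate((subjects.dropout_time, new_subjects.dropout_time)),
            np.concatenate((subjects.arm_I, new_subjects.arm_I)),
        )
        n2 = new_subjects.n
    else:
        merged, n2 = subjects, 0
    time, event = observe_full(merged, tau)
    return StageData(
        stage="all",
        time=time,
        event=event,
        entry=np.zeros_like(time),
        arm_I=merged.arm_I,
        n1=subjects.n,
        n2=n2,
        tau=tau,
        calendar_entry=merged.entry,
    )


def censoring_probability(
    scenario: HazardScenario, arm: str = "C", horizon: float | None = None
) -> float:
    """P(dropout before min(event, horizon)) by numeric integration."""
    from scipy.integrate import quad

    lam_late = scenario.lambdaI if arm == "I" else scenario.lambdaC
    c = scenario.dropout_rate
    if c == 0:
        return 0.0
    horizon = scenario.tau if horizon is None else horizon

    def integrand(t):
        s_event = two_piece_survival(t, scenario.t0, scenario.lambda0, lam_late)
        return c * np.exp(-c * t) * s_event

    val, _ = quad(integrand, 0.0, horizon, points=[scenario.t0], limit=200)
    return float(val)


_COLUMNS = ["id", "entry_time", "followup_time", "event", "truncation_time", "arm"]


def write_subjects(data: StageData, path) -> None:
    """Write stage data as delimited text (CSV) in the standard layout."""
    data.to_frame().to_csv(path, index=False)


def read_subjects(path, stage: str = "all", tau: float = np.nan) -> StageData:
    """Read subject-level delimited text into a :class:`StageData`."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    time = df["followup_time"].to_numpy(dtype=float)
    entry = df["truncation_time"].to_numpy(dtype=float)
    if np.any(time < 0):
        raise ValueError("followup_time must be non-negative")
    if np.any((entry > 0) & (time <= entry)):
        raise ValueError("invalid truncation: followup_time must exceed truncation_time")
    event = df["event"].to_numpy()
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event must be 0 or 1")
    arm = df["arm"].astype(str).to_numpy()
    if not np.isin(arm, ["I", "C"]).all():
        raise ValueError("arm must be 'I' or 'C'")
    return StageData(
        stage=stage,
        time=time,
        event=event.astype(bool),
        entry=entry,
        arm_I=arm == "I",
        n1=len(df),
        n_pipeline=int((entry > 0).sum()),
        tau=tau,
        calendar_entry=df["entry_time"].to_numpy(dtype=float),
    )
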