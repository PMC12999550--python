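"""Pre-trial planning computations for the adaptive RMST design.

Planning proceeds in the following steps, all exposed individually:

1. solve the late intervention hazard ``lambdaI`` so that the two-piece
   exponential model implies the target RMST difference ``delta0``;
2. estimate the asymptotic standard deviations ``sigma1`` (interim-data
   estimator), ``sigma1_star`` (full-follow-up estimator) and ``sigma21``
   (pipeline-follow-up contribution) by simulation;
3. convert the target power into a maximum information level and an
   initial sample size (with a group-sequential inflation factor), derive
   the first-stage size from the accrual fraction, and fix the
   combination-test weights.

``sigma21`` is not estimable directly from pipeline data alone (such an
estimator behaves very poorly); it is derived from the information
decomposition ``n1/sigma1*^2 = n1/sigma1^2 + nbar1/sigma21^2`` that holds
when no new patients are recruited, giving

    sigma21^2 = (nbar1/n1) / (1/sigma1*^2 - 1/sigma1^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri

from . import _fastkm
from .trial_simulator import HazardScenario, two_piece_rmst

__all__ = [
    "DesignPlan",
    "NuisanceEstimates",
    "rmst_diff_closed_form",
    "solve_lambda_I",
    "estimate_sigmas",
    "max_information",
    "fixed_sample_size",
    "stage_one_size",
    "combination_weights",
    "inflation_factor",
    "make_plan",
]


@dataclass(frozen=True)
class NuisanceEstimates:
    """Simulation-based asymptotic standard deviations.

    ``sigma1`` scales the interim-data RMST difference, ``sigma1_star``
    the full-follow-up one (the limit of the pooled estimator), and
    ``sigma21`` the contribution of post-interim follow-up of pipeline
    patients. ``pipeline_frac`` is the expected fraction of stage-1
    patients still under observation at interim.
    """

    sigma1: float
    sigma21: float
    sigma1_star: float
    pipeline_frac: float
    L_sims: int
    sim_n: int


@dataclass(frozen=True)
class DesignPlan:
    """All pre-specified constants of the two-stage adaptive design."""

    alpha: float
    beta: float
    beta_cond: float
    delta0: float
    tau: float
    tE: float
    t_int: float
    gamma: float
    I_max: float
    n_total: int
    n1: int
    n_max: int
    n_fix_guess: int
    cp_min: float
    w1: float
    w2: float
    nuisance: NuisanceEstimates | None = None
    scenario_guess: HazardScenario | None = field(default=None, repr=False)

    @property
    def t_final(self) -> float:
        return self.tE + self.tau

    @property
    def planned_n2(self) -> int:
        return self.n_total - self.n1

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "alpha", "beta", "beta_cond", "delta0", "tau", "tE", "t_int",
                "gamma", "I_max", "n_total", "n1", "n_max", "n_fix_guess",
                "cp_min", "w1", "w2",
            )
        }
        d["t_final"] = self.t_final
        d["planned_n2"] = self.planned_n2
        if self.nuisance is not None:
            d.update(
                sigma1=self.nuisance.sigma1,
                sigma21=self.nuisance.sigma21,
                sigma1_star=self.nuisance.sigma1_star,
                pipeline_frac=self.nuisance.pipeline_frac,
                L_sims=self.nuisance.L_sims,
                sim_n=self.nuisance.sim_n,
            )
        if self.scenario_guess is not None:
            g = self.scenario_guess
            d.update(
                t0=g.t0, lambda0_guess=g.lambda0, lambdaC_guess=g.lambdaC,
                lambdaI_guess=g.lambdaI, dropout_guess=g.dropout_rate,
            )
        return d


def rmst_diff_closed_form(
    t0: float, lambda0: float, lambdaI: float, lambdaC: float, tau: float
) -> float:
    """Exact RMST difference of the two-piece exponential model.

    Because the early hazard is shared, the early areas cancel:
    ``delta = exp(-lambda0*t0) * [(1-exp(-lambdaI*(tau-t0)))/lambdaI
    - (1-exp(-lambdaC*(tau-t0)))/lambdaC]``.
    """
    return two_piece_rmst(t0, lambda0, lambdaI, tau) - two_piece_rmst(
        t0, lambda0, lambdaC, tau
    )


def solve_lambda_I(
    t0: float, lambda0: float, lambdaC: float, tau: float, delta0: float
) -> float:
    """Late intervention hazard implying RMST difference ``delta0``.

    The difference is strictly decreasing in ``lambdaI``; for
    ``delta0 >= 0`` the root lies in ``(0, lambdaC]``.
    """
    if delta0 == 0:
        return lambdaC
    upper = np.exp(-lambda0 * t0) * (
        (tau - t0) - (1.0 - np.exp(-lambdaC * (tau - t0))) / lambdaC
    )
    if not 0 <= delta0 < upper:
        raise ValueError(
            f"delta0={delta0} not attainable; must lie in [0, {upper:.6g})"
        )
    f = lambda lam: rmst_diff_closed_form(t0, lambda0, lam, lambdaC, tau) - delta0
    return float(brentq(f, 1e-12, lambdaC, xtol=1e-14, rtol=8.9e-16))


def estimate_sigmas(
    scenario: HazardScenario,
    t_int: float,
    L_sims: int = 100,
    sim_n: int = 10_000,
    seed=None,
) -> NuisanceEstimates:
    """Estimate (sigma1, sigma21, sigma1_star) by trial simulation.

    Simulates ``L_sims`` cohorts of ``sim_n`` stage-1 subjects (entry
    uniform on ``[0, t_int]``), computes the scaled standard error of the
    RMST difference from the interim snapshot (-> sigma1) and from the
    full tau-year follow-up (-> sigma1_star) of each cohort, and averages.
    ``sigma21`` follows from the information decomposition using the
    average pipeline fraction.
    """
    if L_sims < 1 or sim_n < 2:
        raise ValueError("need L_sims >= 1 and sim_n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = sim_n // 2
    tau = scenario.tau

    # one batched draw per arm; (L_sims, m) matrices
    out = {}
    for label, lam_late in (("I", scenario.lambdaI), ("C", scenario.lambdaC)):
        entry = rng.uniform(0.0, t_int, (L_sims, m))
        early = rng.exponential(1.0 / scenario.lambda0, (L_sims, m))
        resid = rng.exponential(1.0 / lam_late, (L_sims, m))
        t_event = np.where(early <= scenario.t0, early, scenario.t0 + resid)
        if scenario.dropout_rate > 0:
            drop = rng.exponential(1.0 / scenario.dropout_rate, (L_sims, m))
        else:
            drop = np.inf
        time_full = np.minimum(np.minimum(t_event, drop), tau)
        ev_full = t_event <= np.minimum(drop, tau)
        admin = t_int - entry
        time_1 = np.minimum(time_full, admin)
        ev_1 = ev_full & (time_full <= admin)
        out[label] = (time_full, ev_full, time_1, ev_1)

    tf_i, ef_i, t1_i, e1_i = out["I"]
    tf_c, ef_c, t1_c, e1_c = out["C"]
    _, var_fi = _fastkm.batched_rmst(tf_i, ef_i, tau)
    _, var_fc = _fastkm.batched_rmst(tf_c, ef_c, tau)
    _, var_1i = _fastkm.batched_rmst(t1_i, e1_i, tau)
    _, var_1c = _fastkm.batched_rmst(t1_c, e1_c, tau)
    n = 2 * m
    sig_all = np.sqrt(n * (var_fi + var_fc))
    sig1 = np.sqrt(n * (var_1i + var_1c))
    pipe = ((t1_i < tf_i).sum(axis=1) + (t1_c < tf_c).sum(axis=1)) / n

    sigma1 = float(sig1.mean())
    sigma1_star = float(sig_all.mean())
    inv_gap = 1.0 / sigma1_star**2 - 1.0 / sigma1**2
    if inv_gap <= 0:
        raise RuntimeError(
            "interim information exceeded full-follow-up information; "
            "cannot derive sigma21 (increase L_sims/sim_n)"
        )
    sigma21 = float(np.sqrt(pipe.mean() / inv_gap))
    return NuisanceEstimates(
        sigma1, sigma21, sigma1_star, float(pipe.mean()), L_sims, sim_n
    )


def max_information(alpha: float, beta: float, delta0: float, gamma: float = 1.0) -> float:
    """Planned maximum information: gamma * (z_alpha + z_beta)^2 / delta0^2."""
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must be in (0, 1)")
    if delta0 == 0:
        raise ValueError("delta0 must be non-zero")
    return gamma * (ndtri(1 - alpha) + ndtri(1 - beta)) ** 2 / delta0**2


def _even_ceil(x: float) -> int:
    return int(2 * np.ceil(x / 2.0 - 1e-12))


def _even_round(x: float) -> int:
    # nearest even integer, ties rounded up
    return int(2 * np.floor(x / 2.0 + 0.5))


def fixed_sample_size(
    alpha: float, beta: float, delta0: float, sigma1_star: float, gamma: float = 1.0
) -> int:
    """Total sample size (both groups), rounded up to an even integer."""
    raw = max_information(alpha, beta, delta0, gamma) * sigma1_star**2
    return _even_ceil(raw)


def stage_one_size(n: int, t_int: float, tE: float) -> int:
    """First-stage size under constant accrual: n * t_int / tE, rounded up
    to an even integer (both groups accrue together)."""
    if not 0 < t_int <= tE:
        raise ValueError("need 0 < t_int <= tE")
    return _even_ceil(n * t_int / tE)


def combination_weights(
    n1: int, sigma1: float, n: int, sigma1_star: float
) -> tuple[float, float]:
    """Pre-specified inverse-normal weights from expected information fractions.

    ``w1^2`` is the expected fraction of maximum information available at
    interim, ``(n1/sigma1^2) / (n/sigma1_star^2)``.
    """
    w1sq = (n1 / sigma1**2) / (n / sigma1_star**2)
    if not 0 < w1sq <= 1:
        raise ValueError(
            f"inconsistent inputs: w1^2 = {w1sq:.4f} outside (0, 1]"
        )
    w1 = float(np.sqrt(w1sq))
    return w1, float(np.sqrt(1.0 - w1sq))


def inflation_factor(
    alpha: float = 0.025,
    beta: float = 0.2,
    info_fraction: float = 0.6,
    interim_efficacy: bool = True,
) -> float:
    """Information inflation required by a two-look O'Brien-Fleming design.

    Solves the two-stage power equation for the factor ``gamma`` by which
    the maximum information must exceed the fixed-design information so
    that the design, spending alpha with the O'Brien-Fleming-type
    spending function at the given interim information fraction, attains
    power ``1 - beta``. With no interim efficacy look the factor is 1.
    """
    from .sequential_testing import critical_values  # local import: avoids cycle

    if not interim_efficacy:
        return 1.0
    f = info_fraction
    w1 = float(np.sqrt(f))
    i_fix = (ndtri(1 - alpha) + ndtri(1 - beta)) ** 2  # delta0 = sigma = 1

    from .sequential_testing import _bvn_upper
    from scipy.special import ndtr

    def power(gamma: float) -> float:
        i_max = gamma * i_fix
        cv = critical_values(f * i_max, i_max, alpha, w1)
        d1 = np.sqrt(f * i_max)  # drift of Z1 under the alternative
        df = np.sqrt(i_max)  # drift of Z_final
        p_interim = ndtr(d1 - cv.c1)
        # P(Zf >= cf, Z1 < c1) = P(Zf >= cf) - P(Zf >= cf, Z1 >= c1)
        p_joint = ndtr(df - cv.c_final) - _bvn_upper(
            cv.c1 - d1, cv.c_final - df, w1
        )
        return float(p_interim + p_joint)

    return float(brentq(lambda g: power(g) - (1 - beta), 0.999, 1.5, xtol=1e-10))


def make_plan(
    scenario_guess: HazardScenario,
    delta0: float,
    t_int: float,
    alpha: float = 0.025,
    beta: float = 0.2,
    beta_cond: float = 0.2,
    cp_min: float = 0.2,
    gamma: float = 1.01,
    n_max_factor: float = 1.5,
    L_sims: int = 100,
    sim_n: int = 10_000,
    seed=None,
) -> DesignPlan:
    """Full planning pipeline at the guessed nuisance parameters.

    ``n_fix_guess`` is the fixed-design size (no inflation); the adaptive
    design starts from ``n = even_ceil(gamma * n_fix_guess)`` with
    ``n1 = n * t_int / tE`` first-stage patients, and caps the total at
    ``n_max_factor * n_fix_guess``.
    """
    nuis = estimate_sigmas(scenario_guess, t_int, L_sims, sim_n, seed)
    n_fix_guess = fixed_sample_size(alpha, beta, delta0, nuis.sigma1_star, gamma=1.0)
    n_total = _even_ceil(gamma * n_fix_guess)
    n1 = stage_one_size(n_total, t_int, scenario_guess.tE)
    n_max = int(2 * np.floor(n_max_factor * n_fix_guess / 2.0 + 1e-12))
    w1, w2 = combination_weights(n1, nuis.sigma1, n_total, nuis.sigma1_star)
    return DesignPlan(
        alpha=alpha,
        beta=beta,
        beta_cond=beta_cond,
        delta0=delta0,
        tau=scenario_guess.tau,
        tE=scenario_guess.tE,
        t_int=t_int,
        gamma=gamma,
        I_max=max_information(alpha, beta, delta0, gamma),
        n_total=n_total,
        n1=n1,
        n_max=n_max,
        n_fix_guess=n_fix_guess,
        cp_min=cp_min,
        w1=w1,
        w2=w2,
        nuisance=nuis,
        scenario_guess=scenario_guess,
    )
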