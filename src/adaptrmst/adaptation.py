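"""Interim decision logic: stopping, nuisance updating, sample-size recalculation.

At the interim look the design (i) stops for efficacy when the stage-1
statistic crosses the spending boundary, (ii) otherwise re-estimates the
nuisance rates of the piecewise-exponential working model from the interim
data by constrained maximum likelihood — the effect size is *not*
re-estimated; the late intervention hazard is pinned by the design
alternative ``delta0`` — and (iii) evaluates the conditional power

    CP(delta0, z1) = 1 - Phi( (c_final - w1*z1)/w2
                              - delta0*sqrt(nbar1/sigma21^2 + n2/sigma1*^2) ),

stopping (non-bindingly) for futility when the conditional power at the
initially planned stage-2 size falls below ``cp_min``, and otherwise
choosing the smallest even number of newly recruited patients that lifts
the conditional power to the target, capped at ``n_max - n1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .design_planning import (
    DesignPlan,
    NuisanceEstimates,
    estimate_sigmas,
    solve_lambda_I,
)
from .sequential_testing import CriticalValues, critical_values, stage_statistic
from .trial_simulator import HazardScenario, StageData

__all__ = [
    "InterimDecision",
    "conditional_power",
    "interim_rates_mle",
    "interim_nuisance_update",
    "recalculate_n2",
    "interim_decide",
]


@dataclass(frozen=True)
class InterimDecision:
    """Outcome of the interim analysis."""

    action: str  # stop_efficacy | stop_futility | continue
    z1: float
    c1: float
    c_final: float
    info_1: float
    n_pipeline: int
    cp_planned_n2: float
    n2_new: int
    cp_achieved: float
    nuisance: NuisanceEstimates | None
    scenario_updated: HazardScenario | None = None

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "action", "z1", "c1", "c_final", "info_1", "n_pipeline",
                "cp_planned_n2", "n2_new", "cp_achieved",
            )
        }
        if self.nuisance is not None:
            d.update(
                sigma1=self.nuisance.sigma1,
                sigma21=self.nuisance.sigma21,
                sigma1_star=self.nuisance.sigma1_star,
            )
        if self.scenario_updated is not None:
            s = self.scenario_updated
            d.update(
                lambda0_hat=s.lambda0, lambdaC_hat=s.lambdaC,
                lambdaI_constrained=s.lambdaI, dropout_hat=s.dropout_rate,
            )
        return d


def conditional_power(
    delta0: float,
    z1: float,
    c_final: float,
    w1: float,
    w2: float,
    n_pipeline: int,
    n2: float,
    sigma21: float,
    sigma1_star: float,
) -> float:
    """Probability of final rejection given z1, under effect ``delta0``.

    The stage-2 information is decomposed into the pipeline contribution
    ``nbar1/sigma21^2`` and the new-recruit contribution ``n2/sigma1*^2``.
    """
    if np.isinf(c_final):
        return 0.0
    drift = delta0 * np.sqrt(n_pipeline / sigma21**2 + n2 / sigma1_star**2)
    return float(1.0 - ndtr((c_final - w1 * z1) / w2 - drift))


def interim_rates_mle(
    interim_data: StageData, t0: float, tau: float
) -> tuple[float, float, float, float]:
    """Occurrence/exposure rate estimates from interim right-censored data.

    Returns ``(lambda0_hat, lambdaC_hat, lambdaI_hat, dropout_hat)``; each
    is ``nan`` when its window holds no events or no exposure. The early
    hazard pools both arms (they share ``lambda0`` by assumption); dropout
    is identified as censoring strictly before both the administrative
    interim cut and the tau-year completion.
    """
    if interim_data.admin_censor is None:
        raise ValueError("interim data must carry administrative censoring times")
    time = interim_data.time
    event = interim_data.event.astype(bool)

    def occ_exp(t_arr, e_arr, lo, hi):
        exposure = np.clip(t_arr, lo, hi) - lo
        events = float((e_arr & (t_arr > lo) & (t_arr <= hi)).sum())
        total = float(exposure.sum())
        return events / total if (total > 0 and events > 0) else np.nan

    lam0 = occ_exp(time, event, 0.0, t0)
    t_c, e_c, _ = interim_data.arm("C")
    lamC = occ_exp(t_c, e_c.astype(bool), t0, tau)
    t_i, e_i, _ = interim_data.arm("I")
    lamI = occ_exp(t_i, e_i.astype(bool), t0, tau)

    eps = 1e-9
    dropouts = (~event) & (time < interim_data.admin_censor - eps) & (time < tau - eps)
    total_exposure = float(time.sum())
    chat = float(dropouts.sum()) / total_exposure if total_exposure > 0 else np.nan
    return lam0, lamC, lamI, chat


def interim_nuisance_update(
    interim_data: StageData,
    t0: float,
    delta0: float,
    tau: float,
    t_int: float,
    scenario_guess: HazardScenario,
    L_sims: int = 100,
    sim_n: int = 10_000,
    seed=None,
) -> tuple[HazardScenario, NuisanceEstimates]:
    """Constrained re-estimation of nuisance parameters at interim.

    Event and dropout rates are re-estimated from the interim data; the
    late intervention hazard is then *imposed* by the constraint that the
    model RMST difference equals ``delta0`` (the design alternative is
    kept, only nuisance values are updated). The asymptotic standard
    deviations are re-estimated by simulation at the updated rates. Any
    rate that cannot be estimated (no events/exposure in its window, or a
    ``delta0`` unattainable at the estimated rates) falls back to the
    planning guess with a warning.
    """
    lam0, lamC, _, chat = interim_rates_mle(interim_data, t0, tau)
    fallbacks = []
    if not np.isfinite(lam0):
        lam0, fallbacks = scenario_guess.lambda0, fallbacks + ["lambda0"]
    if not np.isfinite(lamC):
        lamC, fallbacks = scenario_guess.lambdaC, fallbacks + ["lambdaC"]
    if not np.isfinite(chat):
        chat, fallbacks = scenario_guess.dropout_rate, fallbacks + ["dropout"]
    try:
        lamI = solve_lambda_I(t0, lam0, lamC, tau, delta0)
    except ValueError:
        lam0, lamC = scenario_guess.lambda0, scenario_guess.lambdaC
        lamI = solve_lambda_I(t0, lam0, lamC, tau, delta0)
        fallbacks.append("lambdaI-constraint")
    if fallbacks:
        warnings.warn(
            f"interim nuisance update fell back to planning guesses for: {fallbacks}",
            RuntimeWarning,
            stacklevel=2,
        )
    updated = HazardScenario(
        t0=t0, lambda0=lam0, lambdaC=lamC, lambdaI=lamI,
        dropout_rate=chat, tau=tau, tE=scenario_guess.tE,
    )
    nuis = estimate_sigmas(updated, t_int, L_sims=L_sims, sim_n=sim_n, seed=seed)
    return updated, nuis


def recalculate_n2(
    z1: float,
    c_final: float,
    plan: DesignPlan,
    nuisance: NuisanceEstimates,
    n_pipeline: int,
) -> int:
    """Smallest (even) stage-2 recruitment meeting the conditional-power target.

    Closed-form inversion of the conditional-power equation, clamped to
    ``[0, n_max - n1]``: 0 when pipeline data alone already deliver the
    target, the cap when even the maximal feasible size falls short.
    """
    cap = plan.n_max - plan.n1
    if np.isinf(c_final):
        return cap
    q = (c_final - plan.w1 * z1) / plan.w2
    need = (q + ndtri(1.0 - plan.beta_cond)) / plan.delta0
    if need <= 0:
        return 0
    n2_raw = nuisance.sigma1_star**2 * (
        need**2 - n_pipeline / nuisance.sigma21**2
    )
    if n2_raw <= 0:
        return 0
    n2 = int(2 * np.ceil(n2_raw / 2.0 - 1e-12))
    return int(min(n2, cap))


def interim_decide(
    interim_data: StageData,
    plan: DesignPlan,
    planned_n2: int | None = None,
    L_sims: int = 100,
    sim_n: int = 10_000,
    seed=None,
) -> InterimDecision:
    """Apply the three-way interim rule: efficacy / futility / continue.

    Futility is assessed *before* recalculation, at the initially planned
    stage-2 size; it is non-binding but always followed here.
    """
    if plan.scenario_guess is None:
        raise ValueError("plan must carry the guessed scenario for nuisance updating")
    planned_n2 = plan.planned_n2 if planned_n2 is None else planned_n2
    stats1 = stage_statistic(interim_data, plan.tau)
    cv: CriticalValues = critical_values(stats1.info, plan.I_max, plan.alpha, plan.w1)
    nbar1 = interim_data.n_pipeline

    if stats1.z >= cv.c1:
        return InterimDecision(
            "stop_efficacy", stats1.z, cv.c1, cv.c_final, stats1.info,
            nbar1, np.nan, 0, np.nan, None,
        )

    scen_upd, nuis = interim_nuisance_update(
        interim_data, plan.scenario_guess.t0, plan.delta0, plan.tau,
        plan.t_int, plan.scenario_guess, L_sims=L_sims, sim_n=sim_n, seed=seed,
    )
    cp_args = dict(
        delta0=plan.delta0, z1=stats1.z, c_final=cv.c_final,
        w1=plan.w1, w2=plan.w2, n_pipeline=nbar1,
        sigma21=nuis.sigma21, sigma1_star=nuis.sigma1_star,
    )
    cp_planned = conditional_power(n2=planned_n2, **cp_args)
    if cp_planned < plan.cp_min:
        return InterimDecision(
            "stop_futility", stats1.z, cv.c1, cv.c_final, stats1.info,
            nbar1, cp_planned, 0, np.nan, nuis, scen_upd,
        )
    n2_new = recalculate_n2(stats1.z, cv.c_final, plan, nuis, nbar1)
    cp_achieved = conditional_power(n2=n2_new, **cp_args)
    return InterimDecision(
        "continue", stats1.z, cv.c1, cv.c_final, stats1.info,
        nbar1, cp_planned, n2_new, cp_achieved, nuis, scen_upd,
    )
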