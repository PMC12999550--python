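"""Monte-Carlo engine for the operating characteristics of the adaptive design.

Runs complete trials — planning at guessed rates, interim analysis with
efficacy/futility stopping and sample-size recalculation, stage-2 accrual
and the final combination test — over many replicates, and summarizes
power (or type-I error), expected sample sizes, stopping probabilities and
conditional power. The ten benchmark configurations S1-S10 share the
delayed-effect truth (t0 = 0.8, lambda0 = 0.4, lambdaC = 0.7, dropout
0.095, tau = 1.5, accrual over 3 years) and vary the true effect, the
interim timing and the quality of the planning guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .adaptation import interim_decide
from .design_planning import (
    DesignPlan,
    estimate_sigmas,
    fixed_sample_size,
    make_plan,
    solve_lambda_I,
)
from .sequential_testing import (
    VARIANTS,
    logrank_stat,
    stage_statistic,
    tau_year_stat,
)
from .trial_simulator import (
    HazardScenario,
    interim_snapshot,
    pooled_full_data,
    simulate_subjects,
    stage_two_assemble,
)

__all__ = [
    "ScenarioConfig",
    "TrialOutcome",
    "OperatingCharacteristics",
    "scenario_fixtures",
    "run_trial_once",
    "run_scenario",
]

TESTS = ("rmst", "logrank", "tau_year")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation-study configuration.

    Guessed rates are obtained from the true ones via the multipliers
    ``g0`` and ``gC``; the planning target effect is ``delta0`` (equal to
    the true effect except under the null, where the reference-scenario
    value is kept).
    """

    name: str
    delta_true: float
    delta0: float
    t_int: float = 1.8
    g0: float = 1.0
    gC: float = 1.0
    t0: float = 0.8
    lambda0_true: float = 0.4
    lambdaC_true: float = 0.7
    r_cens_true: float = 0.095
    r_cens_guess: float = 0.090
    tau: float = 1.5
    tE: float = 3.0
    alpha: float = 0.025
    beta: float = 0.2
    cp_target: float = 0.8
    cp_min: float = 0.2
    n_max_factor: float = 1.5
    gamma: float = 1.01
    n_mc: int = 10_000
    L_sims: int = 100
    sim_n: int = 10_000

    @property
    def lambda0_guess(self) -> float:
        return self.g0 * self.lambda0_true

    @property
    def lambdaC_guess(self) -> float:
        return self.gC * self.lambdaC_true

    def scenario_true(self) -> HazardScenario:
        """Data-generating truth; lambdaI implied by the true effect."""
        lam_i = solve_lambda_I(
            self.t0, self.lambda0_true, self.lambdaC_true, self.tau, self.delta_true
        )
        return HazardScenario(
            self.t0, self.lambda0_true, self.lambdaC_true, lam_i,
            self.r_cens_true, self.tau, self.tE,
        )

    def scenario_true_alt(self) -> HazardScenario:
        """True nuisance rates with lambdaI pinned by the design alternative.

        Used for the 'fixed design at true parameters' benchmark, which is
        powered for ``delta0`` also under null configurations.
        """
        lam_i = solve_lambda_I(
            self.t0, self.lambda0_true, self.lambdaC_true, self.tau, self.delta0
        )
        return HazardScenario(
            self.t0, self.lambda0_true, self.lambdaC_true, lam_i,
            self.r_cens_true, self.tau, self.tE,
        )

    def scenario_guess(self) -> HazardScenario:
        lam_i = solve_lambda_I(
            self.t0, self.lambda0_guess, self.lambdaC_guess, self.tau, self.delta0
        )
        return HazardScenario(
            self.t0, self.lambda0_guess, self.lambdaC_guess, lam_i,
            self.r_cens_guess, self.tau, self.tE,
        )


def scenario_fixtures() -> dict[str, ScenarioConfig]:
    """The ten benchmark configurations S1-S10."""
    guess0 = dict(g0=0.8, gC=1.1)
    s1 = ScenarioConfig("S1", delta_true=0.075, delta0=0.075, t_int=1.8, **guess0)
    fixtures = {
        "S1": s1,
        "S2": replace(s1, name="S2", delta_true=0.0),
        "S3": replace(s1, name="S3", delta_true=0.0, g0=1.0, gC=1.0),
        "S4": replace(s1, name="S4", delta_true=0.05, delta0=0.05),
        "S5": replace(s1, name="S5", delta_true=0.1, delta0=0.1),
        "S6": replace(s1, name="S6", t_int=2.0),
        "S7": replace(s1, name="S7", t_int=2.2),
        "S8": replace(s1, name="S8", g0=1.0, gC=1.0),
        "S9": replace(s1, name="S9", g0=0.5, gC=0.8),
        "S10": replace(
            s1, name="S10", lambda0_true=0.2, lambdaC_true=0.56, g0=2.0, gC=1.25
        ),
    }
    return fixtures


@dataclass
class TrialOutcome:
    """Everything recorded from one simulated trial."""

    action: str
    z1: float
    n_pipeline: int
    n2: int
    n_total: int
    cp_planned: float
    cp_achieved: float
    rejected: dict  # (test, variant) -> bool
    rejected_fixed: bool


def _comparator_variants(z1, i1, z2, i2, z_all, i_all):
    """Three stage-2 statistics from (z, information) stage summaries."""
    out = {"truncated": z2}
    if i_all > i1:
        incr = np.sqrt(i_all - i1)
        out["desseaux_porcher"] = (z_all * np.sqrt(i_all) - z1 * np.sqrt(i1)) / incr
        out["combined"] = z2 * incr / np.sqrt(i2) if i2 > 0 else np.nan
    else:
        out["desseaux_porcher"] = np.nan
        out["combined"] = np.nan
    return out


def run_trial_once(
    config: ScenarioConfig, plan: DesignPlan, seed, n_fix_guess_sim: int | None = None
) -> TrialOutcome:
    """Simulate one complete adaptive trial under ``config``'s truth.

    ``plan`` is the (shared) design computed from the guessed rates.
    A parallel fixed-size trial of ``n_fix_guess_sim`` patients is run on
    independent draws for the fixed-design power benchmark.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = config.scenario_true()
    tau, t_int = config.tau, config.t_int

    subjects1 = simulate_subjects(truth, plan.n1, (0.0, t_int), rng)
    interim = interim_snapshot(subjects1, t_int, tau)
    decision = interim_decide(
        interim, plan, L_sims=config.L_sims, sim_n=config.sim_n, seed=rng
    )
    z1 = {"rmst": decision.z1}
    i1 = {"rmst": decision.info_1}
    for test, fn in (("logrank", logrank_stat), ("tau_year", lambda d: tau_year_stat(d, tau))):
        try:
            z1[test], i1[test] = fn(interim)
        except ValueError:
            z1[test], i1[test] = np.nan, np.nan

    # fixed-design benchmark on independent data
    rejected_fixed = False
    if n_fix_guess_sim:
        subj_fix = simulate_subjects(truth, n_fix_guess_sim, (0.0, config.tE), rng)
        stats_fix = stage_statistic(pooled_full_data(subj_fix, None, tau), tau)
        rejected_fixed = bool(stats_fix.z >= ndtri(1.0 - config.alpha))

    interim_reject = {t: bool(z1[t] >= decision.c1) for t in TESTS}
    rejected = {(t, v): interim_reject[t] for t in TESTS for v in VARIANTS}

    if decision.action != "continue":
        n_total = plan.n1
        return TrialOutcome(
            decision.action, decision.z1, decision.n_pipeline, 0, n_total,
            decision.cp_planned_n2, decision.cp_achieved, rejected, rejected_fixed,
        )

    n2 = decision.n2_new
    new_subjects = (
        simulate_subjects(truth, n2, (t_int, config.tE), rng) if n2 > 0 else None
    )
    stage2 = stage_two_assemble(subjects1, t_int, new_subjects, tau)
    all_data = pooled_full_data(subjects1, new_subjects, tau)

    stats2 = stage_statistic(stage2, tau)
    stats_all = stage_statistic(all_data, tau)
    z2 = {"rmst": _comparator_variants(
        decision.z1, decision.info_1, stats2.z, stats2.info, stats_all.z, stats_all.info
    )}
    # the 'combined' RMST variant uses the truncated-data effect estimate
    if stats_all.info > decision.info_1:
        z2["rmst"]["combined"] = stats2.delta_hat * np.sqrt(
            stats_all.info - decision.info_1
        )
    for test, fn in (("logrank", logrank_stat), ("tau_year", lambda d: tau_year_stat(d, tau))):
        try:
            z2s, i2s = fn(stage2)
            zas, ias = fn(all_data)
            z2[test] = _comparator_variants(z1[test], i1[test], z2s, i2s, zas, ias)
        except ValueError:
            z2[test] = {v: np.nan for v in VARIANTS}

    for t in TESTS:
        for v in VARIANTS:
            zf = plan.w1 * z1[t] + plan.w2 * z2[t][v]
            final_reject = bool(np.isfinite(zf) and zf >= decision.c_final)
            rejected[(t, v)] = interim_reject[t] or final_reject

    return TrialOutcome(
        "continue", decision.z1, decision.n_pipeline, n2, plan.n1 + n2,
        decision.cp_planned_n2, decision.cp_achieved, rejected, rejected_fixed,
    )


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo summary of one scenario (sample sizes are both arms)."""

    name: str
    n_mc: int
    n_fix_true: int
    n_fix_guess: int
    n1: int
    n_max: int
    power: dict  # (test, variant) -> % rejection
    power_fixed: float
    e_n_pipeline: float
    e_n2_cont: float
    q_n2_cont: tuple
    e_ntotal_cont: float
    q_ntotal_cont: tuple
    e_ntotal: float
    q_ntotal: tuple
    e_cp_cont: float
    q_cp_cont: tuple
    e_cp_all: float
    p_eff: float
    p_fut: float
    p_at_n1: float
    p_at_nmax: float
    total_sample_sizes: np.ndarray = field(repr=False, default=None)
    plan: DesignPlan = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        rows = {
            "scenario": self.name,
            "n_mc": self.n_mc,
            "n_fix_true": self.n_fix_true,
            "n_fix_guess": self.n_fix_guess,
            "n1": self.n1,
            "n_max": self.n_max,
            "E_n_pipeline": self.e_n_pipeline,
            "E_n2_cont": self.e_n2_cont,
            "Q1_n2_cont": self.q_n2_cont[0],
            "Q3_n2_cont": self.q_n2_cont[1],
            "E_ntotal_cont": self.e_ntotal_cont,
            "Q1_ntotal_cont": self.q_ntotal_cont[0],
            "Q3_ntotal_cont": self.q_ntotal_cont[1],
            "E_ntotal": self.e_ntotal,
            "Q1_ntotal": self.q_ntotal[0],
            "Q3_ntotal": self.q_ntotal[1],
            "E_CP_cont_pct": self.e_cp_cont,
            "Q1_CP_cont_pct": self.q_cp_cont[0],
            "Q3_CP_cont_pct": self.q_cp_cont[1],
            "E_CP_all_pct": self.e_cp_all,
            "P_eff_pct": self.p_eff,
            "P_fut_pct": self.p_fut,
            "P_ntotal_eq_n1_pct": self.p_at_n1,
            "P_ntotal_eq_nmax_pct": self.p_at_nmax,
            "power_fixed_pct": self.power_fixed,
        }
        for (t, v), p in self.power.items():
            rows[f"power_{t}_{v}_pct"] = p
        return pd.DataFrame([rows])


def run_scenario(
    config: ScenarioConfig,
    seed: int = 0,
    n_mc: int | None = None,
    out_dir=None,
    progress: bool = False,
) -> OperatingCharacteristics:
    """Monte-Carlo evaluation of one scenario.

    Planning (at guessed rates) and the fixed-design benchmark size (at
    true rates) are computed once; replicates then receive independent
    child seeds from a single seed sequence, so results do not depend on
    execution order.
    """
    n_mc = config.n_mc if n_mc is None else n_mc
    ss = np.random.SeedSequence(seed)
    plan_seed, true_seed, *rep_seeds = ss.spawn(n_mc + 2)

    plan = make_plan(
        config.scenario_guess(),
        delta0=config.delta0,
        t_int=config.t_int,
        alpha=config.alpha,
        beta=config.beta,
        beta_cond=1.0 - config.cp_target,
        cp_min=config.cp_min,
        gamma=config.gamma,
        n_max_factor=config.n_max_factor,
        L_sims=config.L_sims,
        sim_n=config.sim_n,
        seed=np.random.default_rng(plan_seed),
    )
    nuis_true = estimate_sigmas(
        config.scenario_true_alt(), config.t_int, config.L_sims, config.sim_n,
        seed=np.random.default_rng(true_seed),
    )
    n_fix_true = fixed_sample_size(
        config.alpha, config.beta, config.delta0, nuis_true.sigma1_star, gamma=1.0
    )

    outcomes = []
    iterator = enumerate(rep_seeds)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc=config.name)
    for _, child in iterator:
        outcomes.append(
            run_trial_once(
                config, plan, np.random.default_rng(child),
                n_fix_guess_sim=plan.n_fix_guess,
            )
        )

    actions = np.array([o.action for o in outcomes])
    cont = actions == "continue"
    ntot = np.array([o.n_total for o in outcomes], dtype=float)
    n2 = np.array([o.n2 for o in outcomes], dtype=float)
    cp_ach = np.array([o.cp_achieved for o in outcomes])
    cp_pl = np.array([o.cp_planned for o in outcomes])
    cp_all = np.where(cont, cp_ach, cp_pl)  # futility stops keep planned-n2 CP

    def q13(x):
        return (float(np.percentile(x, 25)), float(np.percentile(x, 75))) if x.size else (np.nan, np.nan)

    power = {
        key: 100.0 * float(np.mean([o.rejected[key] for o in outcomes]))
        for key in outcomes[0].rejected
    }
    oc = OperatingCharacteristics(
        name=config.name,
        n_mc=n_mc,
        n_fix_true=n_fix_true,
        n_fix_guess=plan.n_fix_guess,
        n1=plan.n1,
        n_max=plan.n_max,
        power=power,
        power_fixed=100.0 * float(np.mean([o.rejected_fixed for o in outcomes])),
        e_n_pipeline=float(np.mean([o.n_pipeline for o in outcomes])),
        e_n2_cont=float(n2[cont].mean()) if cont.any() else np.nan,
        q_n2_cont=q13(n2[cont]),
        e_ntotal_cont=float(ntot[cont].mean()) if cont.any() else np.nan,
        q_ntotal_cont=q13(ntot[cont]),
        e_ntotal=float(ntot.mean()),
        q_ntotal=q13(ntot),
        e_cp_cont=100.0 * float(np.nanmean(cp_ach[cont])) if cont.any() else np.nan,
        q_cp_cont=tuple(100.0 * v for v in q13(cp_ach[cont])),
        e_cp_all=100.0 * float(np.nanmean(cp_all[np.isfinite(cp_all)])),
        p_eff=100.0 * float(np.mean(actions == "stop_efficacy")),
        p_fut=100.0 * float(np.mean(actions == "stop_futility")),
        p_at_n1=100.0 * float(np.mean(ntot == plan.n1)),
        p_at_nmax=100.0 * float(np.mean(ntot == plan.n_max)),
        total_sample_sizes=ntot,
        plan=plan,
    )
    if out_dir is not None:
        _write_outputs(oc, outcomes, out_dir, seed)
    return oc


def _write_outputs(oc: OperatingCharacteristics, outcomes, out_dir, seed) -> None:
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, o in enumerate(outcomes):
        row = {
            "replicate": i,
            "seed": seed,
            "action": o.action,
            "z1": o.z1,
            "n_pipeline": o.n_pipeline,
            "n2": o.n2,
            "n_total": o.n_total,
            "cp_planned": o.cp_planned,
            "cp_achieved": o.cp_achieved,
            "rejected_fixed": o.rejected_fixed,
        }
        row.update({f"reject_{t}_{v}": o.rejected[(t, v)] for t, v in o.rejected})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / f"{oc.name}_replicates.csv", index=False)
    oc.summary_frame().to_csv(out / f"{oc.name}_summary.csv", index=False)
    vals, counts = np.unique(oc.total_sample_sizes, return_counts=True)
    pd.DataFrame(
        {"n_total": vals, "count": counts, "frequency": counts / counts.sum()}
    ).to_csv(out / f"{oc.name}_histogram.csv", index=False)
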