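"""Stage-wise statistics, combination tests and alpha-spending boundaries.

The final decision statistic is the inverse-normal combination
``Z_final = w1*Z1 + w2*Z2`` with pre-specified weights (w1^2 + w2^2 = 1).
Three versions of the stage-2 statistic are supported:

* ``truncated`` — Z2 computed from the left-truncated stage-2 data
  directly: ``Z2 = sqrt(n2 + nbar1) * delta_hat(X2) / sigma_hat_2``;
* ``desseaux_porcher`` — reconstructs the stage-2 increment from the
  pooled full-data statistic:
  ``Z2' = (Z_all*sqrt(I_all) - Z1*sqrt(I_1)) / sqrt(I_all - I_1)``;
* ``combined`` — truncated-data effect estimate with the pooled
  information increment: ``Z2'' = delta_hat(X2) * sqrt(I_all - I_1)``.

Boundaries use the O'Brien-Fleming-type alpha-spending function. The
final critical value solves P(Z_final >= c, Z1 < c1) = alpha - spent,
where (Z1, Z_final) is standard bivariate normal with correlation w1
(independent stage increments).

Comparator tests (log-rank and tau-year survival difference) are provided
as drop-in stage statistics using the same combination machinery; the
stage-2 log-rank uses delayed-entry risk sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .km_rmst import km_fit, rmst, rmst_difference
from .trial_simulator import StageData

__all__ = [
    "StageStatistic",
    "CriticalValues",
    "obf_spending",
    "critical_values",
    "stage_statistic",
    "stage_two_z",
    "combine",
    "logrank_stat",
    "logrank_z",
    "tau_year_stat",
    "tau_year_z",
]

VARIANTS = ("truncated", "desseaux_porcher", "combined")

# Gauss-Legendre nodes for the bivariate normal quadrature
_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)


def _bvn_upper(h: float, k: float, rho: float) -> float:
    """P(X >= h, Y >= k) for standard bivariate normal with correlation rho.

    Drezner-Wesolowsky identity: the upper orthant probability equals the
    independent product plus an integral over the correlation path,
    evaluated here by fixed Gauss-Legendre quadrature (accurate to ~1e-14
    for |rho| <= 0.95, ample for combination-test weights).
    """
    if np.isinf(h) or np.isinf(k):
        if h == np.inf or k == np.inf:
            return 0.0
        return float(ndtr(-k)) if h == -np.inf else float(ndtr(-h))
    if rho == 0.0:
        return float(ndtr(-h) * ndtr(-k))
    a = np.arcsin(rho)
    theta = 0.5 * a * (_GL_X + 1.0)
    sin_t = np.sin(theta)
    cos2 = 1.0 - sin_t**2
    integrand = np.exp(-(h * h - 2.0 * h * k * sin_t + k * k) / (2.0 * cos2))
    integral = 0.5 * a * float(np.dot(_GL_W, integrand))
    return float(ndtr(-h) * ndtr(-k) + integral / (2.0 * np.pi))


@dataclass(frozen=True)
class CriticalValues:
    c1: float
    c_final: float
    alpha_spent_interim: float
    alpha: float


@dataclass(frozen=True)
class StageStatistic:
    """Standardized statistic and information for one analysis stage."""

    z: float
    delta_hat: float
    sigma_hat: float
    info: float
    n: int
    stage: str


def obf_spending(info: float, i_max: float, alpha: float) -> float:
    """O'Brien-Fleming-type alpha-spending at the observed information.

    ``2 * (1 - Phi(z_{alpha/2} / sqrt(info / i_max)))``, capped at
    ``alpha`` once the observed information reaches the planned maximum.
    """
    if info <= 0 or i_max <= 0:
        raise ValueError("information levels must be positive")
    if info >= i_max:
        return alpha
    return float(2.0 * (1.0 - ndtr(ndtri(1.0 - alpha / 2.0) / np.sqrt(info / i_max))))


def critical_values(
    info_1: float, i_max: float, alpha: float, w1: float
) -> CriticalValues:
    """Interim and final rejection boundaries for the combination test.

    ``c1`` spends ``alpha_tilde(I_1)`` at interim; ``c_final`` allocates
    the remainder through the joint law of ``(Z1, Z_final)`` (bivariate
    normal, correlation ``w1``). If the interim look already spends the
    whole alpha, the final boundary is ``+inf``.
    """
    if not 0 < w1 < 1:
        raise ValueError("w1 must be in (0, 1)")
    spent = obf_spending(info_1, i_max, alpha)
    if spent >= alpha:
        return CriticalValues(float(ndtri(1.0 - alpha)), np.inf, alpha, alpha)
    if spent <= 0.0:  # spending underflowed: effectively a fixed design
        return CriticalValues(np.inf, float(ndtri(1.0 - alpha)), 0.0, alpha)
    c1 = float(ndtri(1.0 - spent))
    target = alpha - spent

    def excess(c: float) -> float:
        # P(Zf >= c, Z1 < c1) = P(Zf >= c) - P(Zf >= c, Z1 >= c1)
        return ndtr(-c) - _bvn_upper(c1, c, w1) - target

    lo = ndtri(1.0 - alpha) - 1.0
    c_final = float(brentq(excess, lo, 8.0, xtol=1e-10))
    return CriticalValues(c1, c_final, spent, alpha)


def stage_statistic(data: StageData, tau: float | None = None) -> StageStatistic:
    """Standardized RMST-difference statistic for one stage's data.

    The scaling count is the number of records supplied: ``n1`` at
    interim, ``n2 + nbar1`` for stage-2 data, ``n`` for the pooled data.
    """
    tau = data.tau if tau is None else tau
    delta, sigma = rmst_difference(data.arm("I"), data.arm("C"), tau)
    n = data.n
    z = float(np.sqrt(n) * delta / sigma) if sigma > 0 else 0.0
    return StageStatistic(z, delta, sigma, n / sigma**2 if sigma > 0 else np.inf, n, data.stage)


def stage_two_z(
    variant: str,
    stats2: StageStatistic | None = None,
    stats1: StageStatistic | None = None,
    stats_all: StageStatistic | None = None,
) -> float:
    """Stage-2 statistic under one of the three combination variants."""
    if variant == "truncated":
        return stats2.z
    if stats_all.info <= stats1.info:
        raise ValueError("non-increasing information: I_all <= I_1")
    incr = np.sqrt(stats_all.info - stats1.info)
    if variant == "desseaux_porcher":
        return float(
            (stats_all.z * np.sqrt(stats_all.info) - stats1.z * np.sqrt(stats1.info))
            / incr
        )
    if variant == "combined":
        return float(stats2.delta_hat * incr)
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


def combine(z1: float, z2: float, w1: float, w2: float) -> float:
    """Inverse-normal combination ``w1*z1 + w2*z2`` (weights pre-specified)."""
    if abs(w1**2 + w2**2 - 1.0) > 1e-8:
        raise ValueError("weights must satisfy w1^2 + w2^2 = 1")
    return float(w1 * z1 + w2 * z2)


def _group_counts(values: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """#{values < t} for each t (values need not be sorted)."""
    return np.searchsorted(np.sort(values), ts, side="left")


def logrank_stat(data: StageData) -> tuple[float, float]:
    """One-sided log-rank statistic with delayed-entry risk sets.

    Returns ``(z, info)`` where ``info`` is the hypergeometric variance of
    the score. ``z`` is oriented so that fewer events in the intervention
    arm than expected gives a positive value.
    """
    if not (np.any(data.arm_I) and np.any(~data.arm_I)):
        raise ValueError("both arms required")
    ev = data.event.astype(bool)
    t, counts = np.unique(data.time[ev], return_counts=True)
    t_i, e_i, l_i = data.arm(("I"))
    t_c, e_c, l_c = data.arm(("C"))
    d_i = np.zeros_like(t)
    ti_ev = t_i[e_i.astype(bool)]
    if ti_ev.size:
        pos = np.searchsorted(t, ti_ev)
        np.add.at(d_i, pos, 1.0)
    y_i = _group_counts(l_i, t) - _group_counts(t_i, t)
    y_c = _group_counts(l_c, t) - _group_counts(t_c, t)
    y = (y_i + y_c).astype(float)
    d = counts.astype(float)
    keep = y > 1
    y, d, d_i, y_i = y[keep], d[keep], d_i[keep], y_i[keep].astype(float)
    score = float((d_i - y_i * d / y).sum())
    var = float((d * (y_i / y) * (1.0 - y_i / y) * (y - d) / (y - 1.0)).sum())
    if var <= 0:
        raise ValueError("log-rank variance is zero (no comparable events)")
    return -score / np.sqrt(var), var


def logrank_z(data: StageData) -> float:
    return logrank_stat(data)[0]


def tau_year_stat(data: StageData, tau: float) -> tuple[float, float]:
    """Difference in Kaplan-Meier tau-year survival over its Greenwood SE.

    Returns ``(z, info)`` with ``info = 1/se^2`` of the difference.
    """
    ses = {}
    surv = {}
    for label in ("I", "C"):
        curve = km_fit(data.arm(label))
        keep = curve.event_times <= tau
        if curve.event_times.size and curve.event_times[keep].size:
            s_tau = float(curve.survival[keep][-1])
        else:
            s_tau = 1.0
        d = curve.events[keep].astype(float)
        y = curve.at_risk[keep].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            gw = (d / (y * (y - d)))
        gw[~np.isfinite(gw)] = 0.0
        var = s_tau**2 * float(gw.sum())
        if s_tau <= 0.0:
            raise ValueError(f"S(tau) reached zero in arm {label}; statistic undefined")
        if var == 0.0:
            warnings.warn(
                f"no events before tau in arm {label}; its variance contribution is 0",
                RuntimeWarning,
                stacklevel=2,
            )
        surv[label], ses[label] = s_tau, var
    var = ses["I"] + ses["C"]
    if var <= 0:
        raise ValueError("tau-year variance is zero")
    z = (surv["I"] - surv["C"]) / np.sqrt(var)
    return float(z), 1.0 / var


def tau_year_z(data: StageData, tau: float) -> float:
    return tau_year_stat(data, tau)[0]
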