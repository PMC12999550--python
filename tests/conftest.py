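import numpy as np
import pytest

from adaptrmst import HazardScenario, solve_lambda_I

# reference trial configuration used across tests: delayed effect with
# change-point 0.8y, shared early hazard 0.4, control late hazard 0.7,
# horizon 1.5y, accrual over 3y, interim at 1.8y
REF = dict(t0=0.8, lambda0=0.4, lambdaC=0.7, tau=1.5, tE=3.0, t_int=1.8)


@pytest.fixture(scope="session")
def ref_scenario() -> HazardScenario:
    """Truth of the reference scenario: RMST difference 0.075, dropout 0.095."""
    lam_i = solve_lambda_I(REF["t0"], REF["lambda0"], REF["lambdaC"], REF["tau"], 0.075)
    return HazardScenario(
        REF["t0"], REF["lambda0"], REF["lambdaC"], lam_i, 0.095, REF["tau"], REF["tE"]
    )


@pytest.fixture(scope="session")
def null_scenario() -> HazardScenario:
    """Same nuisance rates with no treatment effect."""
    return HazardScenario(
        REF["t0"], REF["lambda0"], REF["lambdaC"], REF["lambdaC"], 0.095,
        REF["tau"], REF["tE"],
    )


def brute_force_km(time, event, entry):
    """Reference product-limit computation by explicit risk-set counting.

    Independent of the package implementation: enumerates candidate event
    times and counts risk sets subject by subject.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    entry = np.asarray(entry, float)
    ts = sorted(set(time[event]))
    surv = []
    s = 1.0
    out = []
    for t in ts:
        at_risk = sum(1 for l, x in zip(entry, time) if l < t <= x)
        d = sum(1 for x, e in zip(time, event) if e and x == t)
        s *= 1.0 - d / at_risk
        out.append((t, at_risk, d, s))
    return out
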