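"""Spending function, boundaries, combination variants, comparator tests."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import multivariate_normal

from adaptrmst import (
    combine,
    critical_values,
    interim_snapshot,
    obf_spending,
    pooled_full_data,
    simulate_subjects,
    stage_statistic,
    stage_two_assemble,
    stage_two_z,
)
from adaptrmst.sequential_testing import (
    _bvn_upper,
    logrank_stat,
    logrank_z,
    tau_year_stat,
    tau_year_z,
)


class TestObfSpending:
    def test_full_information_spends_alpha(self):
        assert obf_spending(7.92, 7.92, 0.025) == 0.025
        assert obf_spending(10.0, 7.92, 0.025) == 0.025  # over-run capped

    def test_half_information_value(self):
        # 2*(1 - Phi(2.241403 / sqrt(0.5)))
        assert obf_spending(0.5, 1.0, 0.025) == pytest.approx(0.001525, abs=2e-6)

    def test_strictly_increasing(self):
        vals = [obf_spending(f, 1.0, 0.025) for f in np.linspace(0.1, 1.0, 15)]
        assert np.all(np.diff(vals) > 0)


class TestBvn:
    @pytest.mark.parametrize(
        "h,k,rho",
        [(0.5, 1.2, 0.664), (2.0, 2.2, 0.775), (-1.0, 0.3, -0.5), (1.5, 1.5, 0.9)],
    )
    def test_against_scipy(self, h, k, rho):
        ours = _bvn_upper(h, k, rho)
        theirs = multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf([-h, -k])
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestCriticalValues:
    def test_alpha_conservation_monte_carlo(self):
        """Interim spending plus final rejection mass totals alpha."""
        alpha, w1 = 0.025, 0.664
        cv = critical_values(0.6 * 7.92, 7.92, alpha, w1)
        rng = np.random.default_rng(17)
        n = 2_000_000
        z1 = rng.standard_normal(n)
        zf = w1 * z1 + np.sqrt(1 - w1**2) * rng.standard_normal(n)
        total = np.mean(z1 >= cv.c1) + np.mean((zf >= cv.c_final) & (z1 < cv.c1))
        mc_se = np.sqrt(alpha * (1 - alpha) / n)
        assert abs(total - alpha) < 3 * mc_se

    def test_fixed_design_limit(self):
        # almost no alpha spent at interim -> c_final ~ z_{1-alpha}
        cv = critical_values(1e-4 * 7.92, 7.92, 0.025, 0.664)
        assert cv.c1 > 6
        assert cv.c_final == pytest.approx(ndtri(0.975), abs=1e-4)

    def test_overrun_spends_everything(self):
        cv = critical_values(9.0, 7.92, 0.025, 0.664)
        assert cv.alpha_spent_interim == 0.025
        assert np.isinf(cv.c_final)

    def test_group_sequential_limit(self):
        """With w1 = sqrt(information fraction) the boundary matches a direct
        two-look group-sequential computation (error-spending)."""
        alpha, frac = 0.025, 0.6
        w1 = np.sqrt(frac)
        cv = critical_values(frac, 1.0, alpha, w1)
        # direct computation: P(Z_f >= c, Z_1 < c1) with corr sqrt(frac)
        rng = np.random.default_rng(23)
        n = 4_000_000
        z1 = rng.standard_normal(n)
        zf = w1 * z1 + np.sqrt(1 - frac) * rng.standard_normal(n)
        spent = obf_spending(frac, 1.0, alpha)
        joint = np.mean((zf >= cv.c_final) & (z1 < cv.c1))
        assert joint == pytest.approx(alpha - spent, abs=3 * np.sqrt(alpha / n))


class TestCombine:
    def test_linear_arithmetic(self):
        assert combine(0.0, 0.0, 0.664, np.sqrt(1 - 0.664**2)) == 0.0
        w2 = float(np.sqrt(1 - 0.664**2))
        assert combine(1.0, 1.0, 0.664, w2) == pytest.approx(1.412, abs=1e-3)
        with pytest.raises(ValueError, match="weights"):
            combine(1.0, 1.0, 0.9, 0.9)

    def test_variant_asymptotic_equivalence(self, ref_scenario):
        """|z2 - z2'| and |z2 - z2''| shrink relative to |z2| as n grows
        (in mean over replicates; single trials are noise-dominated)."""
        rel = {}
        for n1 in (2_000, 20_000):
            vals = []
            for seed in range(12):
                rng = np.random.default_rng(300 + seed)
                subj = simulate_subjects(ref_scenario, n1, (0.0, 1.8), rng)
                new = simulate_subjects(ref_scenario, int(n1 * 0.7), (1.8, 3.0), rng)
                s1 = stage_statistic(interim_snapshot(subj, 1.8, 1.5), 1.5)
                s2 = stage_statistic(stage_two_assemble(subj, 1.8, new, 1.5), 1.5)
                sa = stage_statistic(pooled_full_data(subj, new, 1.5), 1.5)
                z2p = stage_two_z("desseaux_porcher", s2, s1, sa)
                z2pp = stage_two_z("combined", s2, s1, sa)
                vals.append(max(abs(s2.z - z2p), abs(s2.z - z2pp)) / abs(s2.z))
            rel[n1] = np.mean(vals)
        assert rel[20_000] < rel[2_000]
        assert rel[20_000] < 0.10

    def test_non_increasing_information_rejected(self, ref_scenario):
        rng = np.random.default_rng(33)
        subj = simulate_subjects(ref_scenario, 200, (0.0, 1.8), rng)
        s1 = stage_statistic(interim_snapshot(subj, 1.8, 1.5), 1.5)
        s2 = stage_statistic(stage_two_assemble(subj, 1.8, None, 1.5), 1.5)
        fake_all = stage_statistic(interim_snapshot(subj, 1.8, 1.5), 1.5)
        with pytest.raises(ValueError, match="information"):
            stage_two_z("desseaux_porcher", s2, s1, fake_all)


class TestComparators:
    def test_null_type_one_error(self, null_scenario):
        """One-sided rejection rate ~ alpha for both comparators under the null."""
        alpha = 0.05
        crit = ndtri(1 - alpha)
        rej_lr = rej_ty = 0
        reps = 2000
        for b in range(reps):
            rng = np.random.default_rng(40_000 + b)
            subj = simulate_subjects(null_scenario, 300, (0.0, 3.0), rng)
            data = pooled_full_data(subj, None, 1.5)
            rej_lr += logrank_z(data) >= crit
            rej_ty += tau_year_z(data, 1.5) >= crit
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert rej_lr / reps == pytest.approx(alpha, abs=3.5 * se)
        assert rej_ty / reps == pytest.approx(alpha, abs=3.5 * se)

    def test_logrank_schoenfeld_approximation(self):
        """Under proportional hazards, E[z] ~ sqrt(d/4) * log HR."""
        rng = np.random.default_rng(55)
        n, hr = 40_000, 1.25
        t_i = rng.exponential(1 / 0.4, n // 2)
        t_c = rng.exponential(1 / (0.4 * hr), n // 2)
        time = np.concatenate([np.minimum(t_i, 1.5), np.minimum(t_c, 1.5)])
        event = np.concatenate([t_i <= 1.5, t_c <= 1.5])
        from adaptrmst.trial_simulator import StageData

        data = StageData(
            "all", time, event, np.zeros(n),
            np.arange(n) < n // 2, tau=1.5,
        )
        z, _ = logrank_stat(data)
        expected = np.sqrt(event.sum() / 4) * np.log(hr)
        assert z == pytest.approx(expected, rel=0.10)

    def test_logrank_matches_lifelines_without_truncation(self, ref_scenario):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(56)
        subj = simulate_subjects(ref_scenario, 600, (0.0, 3.0), rng)
        data = pooled_full_data(subj, None, 1.5)
        z, _ = logrank_stat(data)
        res = lifelines.statistics.logrank_test(
            data.time[data.arm_I], data.time[~data.arm_I],
            data.event[data.arm_I], data.event[~data.arm_I],
        )
        assert z**2 == pytest.approx(res.test_statistic, rel=1e-6)

    def test_tau_year_vs_binomial_on_uncensored_data(self):
        """Without censoring, the tau-year z equals the two-proportion
        z-statistic on 1{T > tau} up to the Greenwood-vs-binomial variance."""
        rng = np.random.default_rng(57)
        n = 5000
        t_i = rng.exponential(1 / 0.4, n)
        t_c = rng.exponential(1 / 0.6, n)
        from adaptrmst.trial_simulator import StageData

        data = StageData(
            "all",
            np.minimum(np.concatenate([t_i, t_c]), 1.5),
            np.concatenate([t_i <= 1.5, t_c <= 1.5]),
            np.zeros(2 * n),
            np.arange(2 * n) < n,
            tau=1.5,
        )
        z, _ = tau_year_stat(data, 1.5)
        p_i, p_c = np.mean(t_i > 1.5), np.mean(t_c > 1.5)
        var = p_i * (1 - p_i) / n + p_c * (1 - p_c) / n
        z_binom = (p_i - p_c) / np.sqrt(var)
        assert z == pytest.approx(z_binom, rel=0.02)
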