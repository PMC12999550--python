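"""Trial data generator and stage-wise assembly."""

import numpy as np
import pytest

from adaptrmst import (
    HazardScenario,
    StageData,
    interim_snapshot,
    pooled_full_data,
    read_subjects,
    simulate_subjects,
    stage_two_assemble,
    write_subjects,
)
from adaptrmst.sequential_testing import stage_statistic
from adaptrmst.trial_simulator import censoring_probability, observe_full, two_piece_survival


class TestSimulateSubjects:
    def test_validation(self, ref_scenario):
        with pytest.raises(ValueError, match="even"):
            simulate_subjects(ref_scenario, 7, seed=0)
        with pytest.raises(ValueError, match="positive"):
            simulate_subjects(ref_scenario, 0, seed=0)
        with pytest.raises(ValueError, match="rates"):
            HazardScenario(0.8, -0.4, 0.7, 0.7, 0.0, 1.5, 3.0)

    def test_null_configuration_arms_identical(self, null_scenario):
        subj = simulate_subjects(null_scenario, 40_000, seed=1)
        from scipy.stats import ks_2samp

        p = ks_2samp(
            subj.event_time[subj.arm_I], subj.event_time[~subj.arm_I]
        ).pvalue
        assert p > 0.01

    def test_control_survival_closed_form(self, ref_scenario):
        """Empirical S(t) matches exp(-0.32) at t0 and exp(-0.81) at tau."""
        subj = simulate_subjects(ref_scenario, 200_000, seed=2)
        t = subj.event_time[~subj.arm_I]
        assert np.mean(t > 0.8) == pytest.approx(np.exp(-0.32), abs=0.005)
        assert np.mean(t > 1.5) == pytest.approx(np.exp(-0.32 - 0.49), abs=0.005)

    def test_allocation_balanced_and_alternating(self, ref_scenario):
        subj = simulate_subjects(ref_scenario, 1000, seed=3)
        assert subj.arm_I.sum() == 500
        assert np.all(subj.arm_I[::2]) and not np.any(subj.arm_I[1::2])
        assert np.all(np.diff(subj.entry) >= 0)

    def test_dropout_fraction_matches_numeric_integration(self, ref_scenario):
        """Fraction censored by dropout within tau vs quadrature of P(C < min(T, tau))."""
        subj = simulate_subjects(ref_scenario, 200_000, seed=4)
        time, event = observe_full(subj, 1.5)
        dropped = (~event) & (time < 1.5)
        for arm, label in ((subj.arm_I, "I"), (~subj.arm_I, "C")):
            expected = censoring_probability(ref_scenario, label)
            assert dropped[arm].mean() == pytest.approx(expected, abs=0.005)

    def test_delta_property_matches_survival_curves(self, ref_scenario):
        from scipy.integrate import quad

        s = ref_scenario
        diff = quad(
            lambda t: two_piece_survival(t, s.t0, s.lambda0, s.lambdaI)
            - two_piece_survival(t, s.t0, s.lambda0, s.lambdaC),
            0, s.tau, points=[s.t0],
        )[0]
        assert s.delta == pytest.approx(diff, abs=1e-9)
        assert s.delta == pytest.approx(0.075, abs=1e-10)


class TestInterimSnapshot:
    def test_fully_observed_event(self, ref_scenario):
        import dataclasses

        subj = simulate_subjects(ref_scenario, 2, (0.0, 0.1), seed=0)
        subj.entry[:] = [1.8 - 2.0, 1.8 - 2.0]  # entered 2y before interim
        subj.event_time[:] = [1.0, 1.0]
        subj.dropout_time[:] = [3.0, 3.0]
        snap = interim_snapshot(subj, 1.8, 1.5)
        assert np.all(snap.time == 1.0) and np.all(snap.event)
        assert snap.n_pipeline == 0

    def test_administrative_censoring_and_pipeline(self, ref_scenario):
        subj = simulate_subjects(ref_scenario, 2, (0.0, 0.1), seed=0)
        subj.entry[:] = [1.8 - 0.4, 1.8 - 0.4]
        subj.event_time[:] = [1.0, 1.0]
        subj.dropout_time[:] = [3.0, 3.0]
        snap = interim_snapshot(subj, 1.8, 1.5)
        assert np.all(snap.time == pytest.approx(0.4))
        assert not np.any(snap.event)
        assert snap.n_pipeline == 2

    def test_entry_after_interim_rejected(self, ref_scenario):
        subj = simulate_subjects(ref_scenario, 10, (0.0, 3.0), seed=5)
        subj.entry[-1] = 2.5
        with pytest.raises(ValueError, match="before t_int"):
            interim_snapshot(subj, 1.8, 1.5)

    def test_expected_stage_one_size_fraction(self, ref_scenario):
        # n1 = n * t_int / tE: 400 * 1.8 / 3.0 = 240 expected entries before interim
        rng = np.random.default_rng(6)
        n_before = [
            (simulate_subjects(ref_scenario, 400, (0.0, 3.0), rng).entry < 1.8).sum()
            for _ in range(200)
        ]
        assert np.mean(n_before) == pytest.approx(240, rel=0.02)


class TestStageTwoAssemble:
    def test_definition_on_seeded_instance(self, ref_scenario):
        """Figure-1-style configuration: every subject still under observation
        at interim appears in stage 2 with truncation t_int - E."""
        t_int, tau = 2.0, 1.5
        subj = simulate_subjects(ref_scenario, 400, (0.0, t_int), seed=7)
        stage2 = stage_two_assemble(subj, t_int, None, tau)
        time_full, event_full = observe_full(subj, tau)
        admin = t_int - subj.entry
        expect = time_full > admin
        assert stage2.n_pipeline == expect.sum() == stage2.n
        np.testing.assert_allclose(np.sort(stage2.entry), np.sort(admin[expect]))
        assert np.all(stage2.time > stage2.entry)

    def test_follow_up_partition(self, ref_scenario):
        """Interim plus post-interim follow-up reconstructs the full follow-up,
        and each event is counted exactly once across the stages."""
        t_int, tau = 1.8, 1.5
        subj = simulate_subjects(ref_scenario, 600, (0.0, t_int), seed=8)
        snap = interim_snapshot(subj, t_int, tau)
        stage2 = stage_two_assemble(subj, t_int, None, tau)
        time_full, event_full = observe_full(subj, tau)
        pipe = time_full > (t_int - subj.entry)
        # non-pipeline subjects: interim record is the final record
        np.testing.assert_allclose(snap.time[~pipe], time_full[~pipe])
        np.testing.assert_array_equal(snap.event[~pipe], event_full[~pipe])
        # pipeline subjects: interim censored, stage-2 record carries the event
        assert not np.any(snap.event[pipe])
        assert stage2.event.sum() + snap.event.sum() == event_full.sum()

    def test_new_recruits_have_zero_truncation(self, ref_scenario):
        subj = simulate_subjects(ref_scenario, 100, (0.0, 1.8), seed=9)
        new = simulate_subjects(ref_scenario, 50, (1.8, 3.0), seed=10)
        stage2 = stage_two_assemble(subj, 1.8, new, 1.5)
        assert stage2.n2 == 50
        assert (stage2.entry == 0).sum() >= 50

    def test_information_additivity_at_large_n(self, ref_scenario):
        """I_all ~ I_1 + I_2 within 5% on a large simulated trial."""
        rng = np.random.default_rng(11)
        gaps = []
        for _ in range(3):
            subj = simulate_subjects(ref_scenario, 12_000, (0.0, 1.8), rng)
            new = simulate_subjects(ref_scenario, 8_000, (1.8, 3.0), rng)
            i1 = stage_statistic(interim_snapshot(subj, 1.8, 1.5), 1.5).info
            i2 = stage_statistic(stage_two_assemble(subj, 1.8, new, 1.5), 1.5).info
            ia = stage_statistic(pooled_full_data(subj, new, 1.5), 1.5).info
            gaps.append(abs(ia - (i1 + i2)) / ia)
        assert np.mean(gaps) < 0.05


class TestStageIndependence:
    def test_null_correlation_z1_z2(self, null_scenario):
        """Corr(Z1, Z2) over 2000 null replicates is 0 within +/- 0.05."""
        z1s, z2s = np.empty(2000), np.empty(2000)
        for b in range(2000):
            rng = np.random.default_rng(20_000 + b)
            subj = simulate_subjects(null_scenario, 400, (0.0, 1.8), rng)
            new = simulate_subjects(null_scenario, 200, (1.8, 3.0), rng)
            z1s[b] = stage_statistic(interim_snapshot(subj, 1.8, 1.5), 1.5).z
            z2s[b] = stage_statistic(stage_two_assemble(subj, 1.8, new, 1.5), 1.5).z
        assert abs(np.corrcoef(z1s, z2s)[0, 1]) < 0.05
        assert z1s.mean() == pytest.approx(0.0, abs=0.07)


class TestIO:
    def test_round_trip(self, ref_scenario, tmp_path):
        subj = simulate_subjects(ref_scenario, 100, (0.0, 1.8), seed=12)
        stage2 = stage_two_assemble(
            subj, 1.8, simulate_subjects(ref_scenario, 40, (1.8, 3.0), seed=13), 1.5
        )
        path = tmp_path / "stage2.csv"
        write_subjects(stage2, path)
        back = read_subjects(path, stage="stage2", tau=1.5)
        np.testing.assert_allclose(back.time, stage2.time)
        np.testing.assert_array_equal(back.event, stage2.event)
        np.testing.assert_allclose(back.entry, stage2.entry)
        np.testing.assert_array_equal(back.arm_I, stage2.arm_I)

    def test_invalid_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,entry_time,followup_time,event,truncation_time,arm\n"
            "0,0.0,0.5,1,0.9,I\n"
        )
        with pytest.raises(ValueError, match="truncation"):
            read_subjects(path)
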