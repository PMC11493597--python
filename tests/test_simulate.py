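"""Synthetic cohort generator: waveform oracles, dynamics consistency,
determinism, and distributional sanity."""

import math

import numpy as np
import pytest

from vgrf.config import GRAVITY, CohortConfig
from vgrf.signals import SubjectInfo
from vgrf.simulate import (
    StanceParams,
    derive_vertical_acceleration,
    draw_stance_params,
    simulate_cohort,
    simulate_stance_vgrf,
    simulate_trial_from_params,
    stance_impulse_closed_form,
    stance_waveform,
    true_impact_peak,
)

MASS = 75.0


class TestStanceWaveform:
    def test_half_sine_peak_at_midpoint(self):
        p = StanceParams(active_peak=2.5, contact_time=0.25, step_period=0.35)
        sig = simulate_stance_vgrf(p, MASS, 1200.0)
        bw = sig.values / (MASS * GRAVITY)
        assert bw.max() == pytest.approx(2.5, abs=1e-6)
        assert np.argmax(bw) / 1200.0 == pytest.approx(0.125, abs=1.0 / 1200.0)

    def test_half_sine_impulse_closed_form(self):
        p = StanceParams(active_peak=2.5, contact_time=0.25, step_period=0.35)
        closed = stance_impulse_closed_form(p)
        assert closed == pytest.approx(2 * 2.5 * 0.25 / math.pi, rel=1e-12)
        sig = simulate_stance_vgrf(p, MASS, 1200.0)
        quad = np.trapezoid(sig.values / (MASS * GRAVITY), dx=1 / 1200.0)
        assert quad == pytest.approx(closed, rel=5e-3)

    def test_impact_bump_creates_early_local_maximum(self):
        p = StanceParams(
            active_peak=2.4, contact_time=0.26, step_period=0.36,
            impact_peak=0.4, impact_time_frac=0.05, impact_width=0.005,
        )
        sig = simulate_stance_vgrf(p, MASS, 1200.0)
        window = sig.values[: int(0.026 * 1200) + 2]
        d = np.diff(window)
        assert np.any((d[:-1] > 0) & (d[1:] <= 0)), "no local max in first 10%"

    def test_impulse_closed_form_with_bump_matches_quadrature(self):
        p = StanceParams(
            active_peak=2.4, contact_time=0.26, step_period=0.36,
            impact_peak=1.0, impact_time_frac=0.06, impact_width=0.006,
        )
        sig = simulate_stance_vgrf(p, MASS, 1200.0)
        quad = np.trapezoid(sig.values / (MASS * GRAVITY), dx=1 / 1200.0)
        assert quad == pytest.approx(stance_impulse_closed_form(p), rel=5e-3)

    def test_nonnegative_and_zero_outside_stance(self):
        p = StanceParams(active_peak=2.2, contact_time=0.3, step_period=0.4)
        t = np.array([-0.01, 0.31, 0.5])
        assert np.all(stance_waveform(t, p) == 0.0)
        sig = simulate_stance_vgrf(p, MASS, 1200.0)
        assert np.all(sig.values >= 0.0)

    @pytest.mark.parametrize(
        "bad,match",
        [
            (dict(active_peak=-1.0, contact_time=0.25, step_period=0.35), "active_peak"),
            (dict(active_peak=2.5, contact_time=0.25, step_period=0.2), "step_period"),
            (
                dict(active_peak=2.5, contact_time=0.25, step_period=0.35,
                     impact_peak=0.5, impact_time_frac=0.2),
                "impact_time_frac",
            ),
            (
                dict(active_peak=1.0, contact_time=0.25, step_period=0.35,
                     impact_peak=1.5, impact_time_frac=0.05),
                "active_peak must exceed",
            ),
        ],
    )
    def test_invalid_params_named(self, bad, match):
        with pytest.raises(ValueError, match=match):
            simulate_stance_vgrf(StanceParams(**bad), MASS, 1200.0)

    def test_true_impact_peak_absent_without_bump(self):
        p = StanceParams(active_peak=2.5, contact_time=0.25, step_period=0.35)
        assert true_impact_peak(p) is None


class TestDeriveAcceleration:
    def _const_force(self, bw):
        from vgrf.signals import SampledSignal

        return SampledSignal(np.full(100, bw * MASS * GRAVITY), 1200.0, "N", "grf")

    @pytest.mark.parametrize("bw,expected_g", [(1.0, 0.0), (0.0, -1.0), (2.0, 1.0)])
    def test_static_cases(self, bw, expected_g):
        out = derive_vertical_acceleration(self._const_force(bw), MASS)
        assert out.units == "g"
        assert np.allclose(out.values, expected_g, atol=1e-12)

    def test_force_recovery_to_machine_precision(self):
        p = StanceParams(active_peak=2.4, contact_time=0.26, step_period=0.36)
        sig = simulate_stance_vgrf(p, MASS, 1200.0)
        a = derive_vertical_acceleration(sig, MASS)
        recovered = MASS * GRAVITY * (a.values + 1.0)
        assert np.allclose(recovered, sig.values, rtol=1e-14, atol=1e-9)


class TestSimulateTrial:
    CFG = CohortConfig(
        n_subjects=1, trial_duration=10.0, noise_sd_accel=0.0, noise_sd_grf=0.0
    )
    SUBJ = SubjectInfo("S0", MASS, 0.92)

    def test_step_count_matches_floor(self):
        p = StanceParams(active_peak=2.4, contact_time=0.26, step_period=0.35)
        trial = simulate_trial_from_params(self.SUBJ, 2.5, [p] * 40, self.CFG)
        assert len(trial.steps) == 28  # floor(10 / 0.35)

    def test_noiseless_equal_rates_identity(self):
        cfg = CohortConfig(
            n_subjects=1, trial_duration=5.0, grf_rate=1200.0, accel_rate=1200.0,
            noise_sd_accel=0.0, noise_sd_grf=0.0,
        )
        p = StanceParams(active_peak=2.4, contact_time=0.26, step_period=0.35)
        trial = simulate_trial_from_params(self.SUBJ, 2.5, [p] * 20, cfg)
        expected = derive_vertical_acceleration(trial.record.grf, MASS)
        assert np.array_equal(trial.record.accel_v.values, expected.values)

    def test_too_short_duration_raises(self):
        cfg = CohortConfig(n_subjects=1, trial_duration=0.2)
        p = StanceParams(active_peak=2.4, contact_time=0.26, step_period=0.35)
        with pytest.raises(ValueError, match="too short"):
            simulate_trial_from_params(self.SUBJ, 2.5, [p], cfg)

    def test_seeded_determinism_bitwise(self):
        cfg = CohortConfig(n_subjects=2, speeds=(2.22, 2.78), trial_duration=6.0, seed=5)
        t1, g1 = simulate_cohort(cfg)
        t2, g2 = simulate_cohort(cfg)
        assert g1.equals(g2)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.record.grf.values, b.record.grf.values)
            assert np.array_equal(a.record.accel_v.values, b.record.accel_v.values)


class TestSimulateCohort:
    def test_trial_count_is_product(self):
        cfg = CohortConfig(n_subjects=5, speeds=(2.22, 2.78), trial_duration=3.0, seed=2)
        trials, _ = simulate_cohort(cfg)
        assert len(trials) == 10

    def test_impact_probability_zero_means_no_impacts(self):
        cfg = CohortConfig(
            n_subjects=3, speeds=(2.5,), trial_duration=8.0,
            impact_probability=0.0, seed=3,
        )
        _, truth = simulate_cohort(cfg)
        assert truth["impact_peak_bw"].isna().all()

    def test_subject_traits_persist_across_speeds(self):
        cfg = CohortConfig(n_subjects=3, speeds=(2.22, 3.33), trial_duration=6.0, seed=4)
        trials, truth = simulate_cohort(cfg)
        by_subj = {t.record.subject.subject_id: t.record.subject.mass for t in trials}
        for trial in trials:
            assert trial.record.subject.mass == by_subj[trial.record.subject.subject_id]
        # contact time decreases with speed within each subject
        means = truth.groupby(["subject_id", "speed"])["contact_time_s"].mean().unstack()
        assert (means[2.22] > means[3.33]).all()

    def test_enlarging_cohort_preserves_existing_subjects(self):
        small = CohortConfig(n_subjects=2, speeds=(2.5,), trial_duration=5.0, seed=9)
        big = CohortConfig(n_subjects=4, speeds=(2.5,), trial_duration=5.0, seed=9)
        t_small, _ = simulate_cohort(small)
        t_big, _ = simulate_cohort(big)
        for a, b in zip(t_small, t_big[:2]):
            assert np.array_equal(a.record.grf.values, b.record.grf.values)


@pytest.fixture(scope="module")
def big_truth():
    cfg = CohortConfig(n_subjects=40, speeds=(2.22, 2.50, 2.78, 3.33),
                       trial_duration=10.0, seed=17)
    _, truth = simulate_cohort(cfg)
    assert len(truth) >= 1000
    return truth


class TestDistributionalSanity:
    """Cohort means of the simulated characteristics sit at their configured
    population values; the impulse mean matches its closed-form implication
    (the impulse of a half-sine-plus-bump stance is determined by the peak
    and contact-time draws)."""

    @staticmethod
    def cluster_se(truth, col):
        subj_means = truth.groupby("subject_id")[col].mean()
        return subj_means.std(ddof=1) / np.sqrt(len(subj_means))

    @pytest.mark.parametrize(
        "col,target",
        [("active_peak_bw", 2.44), ("contact_time_s", 0.26)],
    )
    def test_means_within_two_se(self, big_truth, col, target):
        se = self.cluster_se(big_truth, col)
        assert abs(big_truth[col].mean() - target) <= 2 * se + 1e-9

    def test_impulse_mean_matches_closed_form_implication(self, big_truth):
        implied = 2.0 * big_truth["active_peak_bw"] * big_truth["contact_time_s"] / math.pi
        bump = big_truth["impulse_bw_s"] - implied
        assert (bump >= -1e-9).all()          # bump only adds impulse
        assert bump[big_truth["impact_peak_bw"].isna()].max() < 1e-9


class TestDrawStanceParams:
    def test_speed_trends(self, rng):
        from vgrf.simulate import SubjectTraits

        traits = SubjectTraits(info=SubjectInfo("S0", MASS, 0.92))
        slow = [draw_stance_params(traits, 2.22, 0.0, rng) for _ in range(300)]
        fast = [draw_stance_params(traits, 3.33, 0.0, rng) for _ in range(300)]
        assert np.mean([p.contact_time for p in slow]) > np.mean(
            [p.contact_time for p in fast]
        )
        assert np.mean([p.active_peak for p in slow]) < np.mean(
            [p.active_peak for p in fast]
        )

    def test_drawn_params_always_valid(self, rng):
        from vgrf.simulate import SubjectTraits

        traits = SubjectTraits(info=SubjectInfo("S0", MASS, 0.92))
        for _ in range(500):
            p = draw_stance_params(traits, 2.8, 1.0, rng)
            p.validate()
            assert p.is_valid_step
            assert p.impact_time_frac <= 0.10
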