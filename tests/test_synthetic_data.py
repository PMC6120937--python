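"""Generator contracts: populations, trials, spikes, kinematics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import planstate as ps
from planstate.synthetic_data import (
    BIN_MS,
    DIRECTIONS_RAD,
    MIN_JERK_PEAK_FACTOR,
    NO_PLAN,
    RTModel,
    TaskConfig,
    minimum_jerk_position,
    opposite_direction,
    trial_rate_profile,
)


# ---------------------------------------------------------------------------
# population


class TestPopulation:
    def test_seed_determinism(self):
        spec = ps.PopulationSpec(n_units=120, seed=1)
        p1, p2 = ps.generate_population(spec), ps.generate_population(spec)
        np.testing.assert_array_equal(p1.a, p2.a)
        np.testing.assert_array_equal(p1.phi, p2.phi)
        np.testing.assert_array_equal(p1.sqrt_depth, p2.sqrt_depth)

    def test_cosine_modulation_peak_and_trough(self):
        """Rate is maximal at the PD and minimal opposite it; its rate-space
        first harmonic equals the nominal depth b (the sqrt-domain cosine
        shape adds only a DC and second-harmonic term)."""
        pop = ps.generate_population(ps.PopulationSpec(n_units=8, seed=0))
        for u in range(pop.n_units):
            curve = np.array([pop.rate(th)[u] for th in DIRECTIONS_RAD])
            peak_dir = DIRECTIONS_RAD[np.argmax(curve)]
            assert (
                min(abs(peak_dir - pop.phi[u]), 2 * np.pi - abs(peak_dir - pop.phi[u]))
                <= np.pi / 8 + 1e-9
            )
            # first harmonic of (c + d cos)^2 is exactly 2cd = b
            c1 = 2.0 / 8.0 * np.sum(curve * np.cos(DIRECTIONS_RAD - pop.phi[u]))
            assert c1 == pytest.approx(pop.b[u], rel=1e-9)

    def test_rejects_depth_exceeding_baseline(self):
        with pytest.raises(ValueError, match="tuning_depth"):
            ps.PopulationSpec(baseline_rate=10.0, tuning_depth=11.0)

    def test_preferred_directions_cover_circle(self):
        pop = ps.generate_population(ps.PopulationSpec(n_units=40, seed=2))
        counts = np.histogram(pop.phi, bins=8, range=(0, 2 * np.pi))[0]
        assert (counts > 0).all()


# ---------------------------------------------------------------------------
# trials


class TestTrials:
    def test_condition_proportions(self):
        cfg = TaskConfig(seed=9)
        trials = ps.generate_trials(cfg, 4000)
        frac = {
            c: np.mean([t.condition == c for t in trials]) for c in cfg.trial_mix
        }
        for cond, p in cfg.trial_mix.items():
            se = np.sqrt(p * (1 - p) / 4000)
            assert abs(frac[cond] - p) < 4 * se

    def test_balanced_counts_exact(self):
        trials = ps.generate_trials(TaskConfig(seed=1), 400, balanced=True)
        ot = [t for t in trials if t.condition == "one_target"]
        assert len(ot) == 160
        counts = np.bincount([t.presented_direction for t in ot], minlength=8)
        assert (counts == 20).all()

    def test_latent_plan_single_direction_per_bin(self):
        for trial in ps.generate_trials(TaskConfig(seed=4), 200):
            assert trial.latent_plan.ndim == 1
            assert set(np.unique(trial.latent_plan)) <= set(range(-1, 8))

    def test_epoch_boundaries_increase_and_snap(self):
        for t in ps.generate_trials(TaskConfig(seed=2), 50):
            bounds = [t.target_on_ms, t.blank_on_ms]
            if t.cue_on_ms is not None:
                bounds += [t.cue_on_ms, t.cue_off_ms]
            bounds += [t.go_ms, t.end_ms]
            assert all(x < y for x, y in zip(bounds, bounds[1:]))
            assert all(b % BIN_MS == 0 for b in bounds)

    def test_degenerate_axis_bias(self):
        cfg = TaskConfig(axis_bias=1.0, error_rates={}, seed=3)
        for t in ps.generate_trials(cfg, 300):
            if t.condition in ("two_target_cued", "free_choice"):
                active = t.latent_plan[t.latent_plan != NO_PLAN]
                # initial plan is always the favored (first) axis end
                assert active[0] == t.target_pair[0]

    def test_axis_bias_recovered_within_binomial_ci(self):
        cfg = TaskConfig(axis_bias=0.75, error_rates={}, seed=8)
        trials = ps.generate_trials(cfg, 4000)
        initial = []
        for t in trials:
            if t.condition in ("two_target_cued", "free_choice"):
                active = t.latent_plan[t.latent_plan != NO_PLAN]
                initial.append(active[0] == t.target_pair[0])
        frac = np.mean(initial)
        half = 2.576 * np.sqrt(0.75 * 0.25 / len(initial))  # binomial 99% CI
        assert abs(frac - 0.75) < half

    def test_no_errors_means_every_cued_trial_correct(self):
        cfg = TaskConfig(error_rates={}, seed=5)
        for t in ps.generate_trials(cfg, 400):
            if t.condition == "two_target_cued":
                assert t.correct and t.choice == t.cue_direction

    def test_free_choice_follows_plan_at_go(self):
        for t in ps.generate_trials(TaskConfig(seed=6), 400):
            if t.condition == "free_choice":
                assert t.choice == t.plan_at(t.go_ms)

    def test_error_templates_match_labels(self):
        cfg = TaskConfig(error_rates={1: 0.2, 2: 0.2, 3: 0.2}, seed=7)
        trials = [
            t
            for t in ps.generate_trials(cfg, 600)
            if t.condition == "two_target_cued" and t.error_type
        ]
        assert len(trials) > 30
        for t in trials:
            assert not t.correct
            cue = t.cue_direction
            late_blank = t.plan_at(t.cue_on_ms - 50)
            late_cue = t.plan_at(t.cue_off_ms - 50)
            pre_go = t.plan_at(t.go_ms - 50)
            if t.error_type == 1:
                assert late_blank != cue and late_cue != cue
            elif t.error_type == 2:
                assert late_blank != cue and late_cue == cue and pre_go != cue
            elif t.error_type == 3:
                assert late_blank == cue and late_cue == cue and pre_go != cue

    def test_target_pair_must_be_opposite(self):
        trial = ps.generate_trials(TaskConfig(seed=1), 10)[0]
        import dataclasses

        with pytest.raises(ValueError, match="180"):
            dataclasses.replace(trial, target_pair=(0, 3))


# ---------------------------------------------------------------------------
# spikes


class TestSpikes:
    def test_untuned_quiet_units_are_poisson(self, rng):
        """With zero tuning depth and all excess variability off, counts in
        a window are Poisson: index of dispersion near 1."""
        pop = ps.generate_population(
            ps.PopulationSpec(
                n_units=4,
                baseline_rate=20.0,
                tuning_depth=0.0,
                unit_gain_sd=0.0,
                unit_gain_trial_sd=0.0,
                population_gain_sd=0.0,
                shared_noise_sd=0.0,
                drift_step_sd=0.0,
                seed=2,
            )
        )
        trials = ps.generate_trials(TaskConfig(seed=2), 300)
        spikes = ps.generate_spikes(pop, trials, seed=11)
        counts = np.array(
            [
                [np.sum((ts >= 0) & (ts < 1000.0)) for ts in spikes.spikes[t.trial_id]]
                for t in trials
            ]
        )  # trials × units, 1 s window at 20 spikes/s
        for u in range(pop.n_units):
            c = counts[:, u]
            dispersion = c.var(ddof=1) / c.mean()
            # chi-square bounds on the dispersion index at n=300
            lo = stats.chi2.ppf(0.005, 299) / 299
            hi = stats.chi2.ppf(0.995, 299) / 299
            assert lo < dispersion < hi

    def test_mean_count_matches_rate(self, quiet_population):
        trials = ps.generate_trials(TaskConfig(seed=3), 500)
        spikes = ps.generate_spikes(quiet_population, trials, seed=4)
        # pre-Target-On window: all units at baseline a
        u = 0
        a = quiet_population.a[u]
        window = 500.0
        counts = [
            np.sum(spikes.spikes[t.trial_id][u] < window) for t in trials
        ]
        expect = a * window / 1000.0
        se = np.sqrt(expect / len(trials))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_zero_rate_means_no_spikes(self):
        pop = ps.generate_population(
            ps.PopulationSpec(
                n_units=3,
                baseline_rate=0.0,
                tuning_depth=0.0,
                unit_gain_sd=0.0,
                unit_gain_trial_sd=0.0,
                population_gain_sd=0.0,
                shared_noise_sd=0.0,
                drift_step_sd=0.0,
            )
        )
        trials = ps.generate_trials(TaskConfig(seed=0), 20)
        spikes = ps.generate_spikes(pop, trials, seed=0)
        assert all(
            ts.size == 0 for tr in spikes.spikes.values() for ts in tr
        )

    def test_spike_times_sorted_and_in_range(self, quiet_population):
        trials = ps.generate_trials(TaskConfig(seed=1), 20)
        spikes = ps.generate_spikes(quiet_population, trials, seed=1)
        for t in trials:
            for ts in spikes.spikes[t.trial_id]:
                assert (np.diff(ts) >= 0).all()
                assert ts.size == 0 or (ts[0] >= 0 and ts[-1] <= t.end_ms)

    def test_dual_encoding_is_mean_of_single_plan_rates(self, quiet_population):
        trials = [
            t
            for t in ps.generate_trials(TaskConfig(seed=2), 60)
            if t.condition == "two_target_cued"
        ]
        t = trials[0]
        dual = trial_rate_profile(quiet_population, t, encoding="dual")
        d0, d1 = t.target_pair
        pre_cue = int(t.cue_on_ms // BIN_MS) - 1
        assert t.latent_plan[pre_cue] != NO_PLAN
        prof = t.strength_profile[pre_cue]
        expect = 0.5 * (
            quiet_population.rate(DIRECTIONS_RAD[d0], prof)
            + quiet_population.rate(DIRECTIONS_RAD[d1], prof)
        )
        np.testing.assert_allclose(dual[:, pre_cue], expect, rtol=1e-12)

    def test_session_reproducible(self):
        s1 = ps.generate_session(n_trials=40, seed=17)
        s2 = ps.generate_session(n_trials=40, seed=17)
        np.testing.assert_array_equal(s1.population.a, s2.population.a)
        for tid in s1.spikes.trial_ids():
            for a, b in zip(s1.spikes.spikes[tid], s2.spikes.spikes[tid]):
                np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# kinematics


class TestKinematics:
    def test_minimum_jerk_peak_speed_factor(self):
        """7 cm in 500 ms peaks at 1.875 * 7/0.5 = 26.25 cm/s."""
        tau = np.linspace(0, 1, 20001)
        disp = minimum_jerk_position(tau) * 7.0
        speed = np.diff(disp) / (0.5 / 20000)
        assert speed.max() == pytest.approx(
            MIN_JERK_PEAK_FACTOR * 7.0 / 0.5, rel=1e-4
        )
        assert speed.max() == pytest.approx(26.25, rel=1e-4)

    def test_speed_is_position_difference_quotient(self):
        ses = ps.generate_session(n_trials=20, seed=6)
        for kin in ses.kinematics.values():
            d = np.linalg.norm(np.diff(kin.position_cm, axis=0), axis=1) / 0.025
            np.testing.assert_allclose(kin.speed_cm_s[1:], d, atol=1e-9)
            assert np.linalg.norm(kin.position_cm[0]) < 1.5  # starts in center

    def test_threshold_crossing_after_go(self):
        ses = ps.generate_session(n_trials=30, seed=7)
        for t in ses.trials:
            kin = ses.kinematics[t.trial_id]
            moving = kin.t_ms[kin.speed_cm_s > 5.0]
            if moving.size:
                assert moving[0] > t.go_ms

    def test_zero_rt_gain_decouples_rt_from_strength(self):
        trials = ps.generate_trials(TaskConfig(seed=9), 400)
        kin = ps.generate_kinematics(
            trials, RTModel(rt_gain_ms=0.0, rt_noise_sd_ms=40.0), seed=3
        )
        strengths = np.array([t.plan_strength for t in trials])
        rts = np.array([kin[t.trial_id].rt_ms for t in trials])
        slope, _, _, p, _ = stats.linregress(strengths, rts)
        assert p > 0.01  # no detectable dependence

    def test_peak_speeds_centered_near_default(self):
        ses = ps.generate_session(n_trials=150, seed=8)
        peaks = [k.speed_cm_s.max() for k in ses.kinematics.values()]
        assert 21.0 < np.median(peaks) < 27.0  # log-normal around 23.9


def test_opposite_direction_involution():
    for d in range(8):
        assert opposite_direction(opposite_direction(d)) == d
        assert (DIRECTIONS_RAD[opposite_direction(d)] - DIRECTIONS_RAD[d]) % (
            2 * np.pi
        ) == pytest.approx(np.pi)
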