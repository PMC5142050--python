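"""Generator determinism, closed-form limits, and truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from shoalresp.respirometry import ChamberGeometry, fit_slope, segment_trace
from shoalresp.metabolism import mmr_from_trace
from shoalresp.simulate import (
    SimConfig,
    config_with,
    expected_recovery_window_mean,
    simulate_chase_recovery,
    simulate_choice_events,
    simulate_choice_trajectory,
    simulate_cohort,
    simulate_oxygen_trace,
)


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(uninformed_prob=1.5)
        with pytest.raises(ValueError):
            SimConfig(p_familiar=((450, 1.2), (750, 0.5), (1000, 0.5)))

    def test_bad_sojourn_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mean_sojourn_s=0.0)


class TestTraceGenerator:
    def test_same_seed_identical_trace(self, default_config):
        a, _ = simulate_oxygen_trace(0.6, 1.29, default_config, "alone", 99)
        b, _ = simulate_oxygen_trace(0.6, 1.29, default_config, "alone", 99)
        np.testing.assert_array_equal(a.o2, b.o2)
        np.testing.assert_array_equal(a.time, b.time)

    def test_calming_multiplier_one_removes_group_effect(self, default_config):
        cfg = config_with(default_config, calming_multiplier=1.0)
        alone, _ = simulate_oxygen_trace(0.6, 1.29, cfg, "alone", 4)
        group, _ = simulate_oxygen_trace(0.6, 1.29, cfg, "group", 4)
        np.testing.assert_array_equal(alone.o2, group.o2)

    def test_group_trace_declines_slower(self, default_config):
        cfg = config_with(default_config, sensor_noise_sd=0.0,
                          trial_hours_range=(2.0, 2.0))
        alone, _ = simulate_oxygen_trace(0.6, 1.29, cfg, "alone", 4)
        group, _ = simulate_oxygen_trace(0.6, 1.29, cfg, "group", 4)
        sched = cfg.schedule
        s_alone = fit_slope(segment_trace(alone, sched)[0]).slope
        s_group = fit_slope(segment_trace(group, sched)[0]).slope
        assert abs(s_group) < abs(s_alone)

    def test_truth_mean_matches_numeric_integral(self, default_config):
        _, truth = simulate_oxygen_trace(0.6, 1.29, default_config, "alone", 8)
        grid = np.linspace(18000.0, truth.duration_s, 20001)
        numeric = float(np.trapezoid(truth.mo2_at(grid), grid)) / (
            truth.duration_s - 18000.0
        )
        assert truth.mean_mo2(18000.0, truth.duration_s) == pytest.approx(
            numeric, rel=1e-6
        )

    def test_oxygen_floor_guard(self, default_config):
        cfg = config_with(default_config, o2_saturation_mg_l=2.5)
        with pytest.raises(ValueError, match="floor"):
            simulate_oxygen_trace(1.5, 1.29, cfg, "alone", 1)


class TestChaseGenerator:
    def test_truth_satisfies_scope_identity(self, default_config):
        _, mmr_true = simulate_chase_recovery(0.6, 1.29, default_config, 2)
        assert mmr_true == pytest.approx(0.6 * default_config.scope_multiplier)

    def test_scope_multiplier_one_boundary(self, default_config):
        cfg = config_with(default_config, scope_multiplier=1.0,
                          sensor_noise_sd=0.0)
        trace, mmr_true = simulate_chase_recovery(0.6, 1.29, cfg, 2)
        assert mmr_true == pytest.approx(0.6)
        est, _ = mmr_from_trace(trace, ChamberGeometry(fish_mass_g=1.29))
        assert est == pytest.approx(0.6, rel=1e-6)

    def test_noiseless_window_mean_matches_closed_form(self, default_config):
        """The first 3-min window of a noiseless recovery reproduces the
        closed-form window mean of the decaying exponential."""
        cfg = config_with(default_config, sensor_noise_sd=0.0)
        trace, mmr_true = simulate_chase_recovery(0.6, 1.29, cfg, 5)
        est, _ = mmr_from_trace(trace, ChamberGeometry(fish_mass_g=1.29))
        closed = expected_recovery_window_mean(
            0.6, mmr_true, 180.0, cfg.recovery_decay_s
        )
        assert est == pytest.approx(closed, rel=0.02)
        assert est <= mmr_true


class TestChoiceGenerator:
    def test_forced_informed_injects_other_zone(self, default_config):
        cfg = config_with(default_config, uninformed_prob=0.0)
        for seed in range(25):
            ev = simulate_choice_events(1.0, cfg, seed, force_informed=True)
            if ev.total_visits >= 2:
                assert ev.informed
                assert ev.time_unfamiliar > 0.0

    def test_symmetric_p_centres_time_difference(self, default_config):
        cfg = config_with(default_config, uninformed_prob=0.0)
        diffs = [
            (lambda e: e.time_familiar - e.time_unfamiliar)(
                simulate_choice_events(0.5, cfg, s, force_informed=True)
            )
            for s in range(200)
        ]
        mean_frac = float(np.mean(diffs)) / cfg.choice_duration_s
        assert abs(mean_frac) < 0.03

    def test_trajectory_consistent_with_events(self, default_config):
        from shoalresp.behavior import ArenaGeometry, build_zones, score_trajectory

        cfg = default_config
        ev = simulate_choice_events(0.65, cfg, 42, force_informed=True)
        trajectory = simulate_choice_trajectory(ev, cfg, "left", 43)
        scored = score_trajectory(
            trajectory, build_zones(ArenaGeometry(), "left")
        )
        assert scored.informed == ev.informed
        assert scored.initial_choice == ev.initial_choice
        assert scored.total_visits == pytest.approx(ev.total_visits, abs=3)
        assert scored.prop_familiar == pytest.approx(
            ev.time_familiar / ev.duration_s, abs=0.06
        )


class TestCohort:
    def test_deterministic_under_fixed_seed(self, default_config):
        cfg = config_with(default_config, n_fish_per_treatment=2,
                          n_shoals_per_treatment=2)
        a = simulate_cohort(cfg, emit_trajectories=False)
        b = simulate_cohort(cfg, emit_trajectories=False)
        pd.testing.assert_frame_equal(a.fish, b.fish)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        np.testing.assert_array_equal(
            a.physiology[0].trace.o2, b.physiology[0].trace.o2
        )

    def test_empty_cohort_has_valid_schema(self, default_config):
        cfg = config_with(default_config, n_fish_per_treatment=0,
                          n_shoals_per_treatment=0)
        ds = simulate_cohort(cfg)
        assert ds.physiology == [] and ds.choice == []
        assert ds.ground_truth.empty

    def test_truth_covers_every_fish_and_both_testings(self, small_cohort):
        phys_ids = {t.fish_id for t in small_cohort.physiology}
        truth_ids = set(small_cohort.ground_truth["fish_id"])
        assert phys_ids <= truth_ids
        per_fish = pd.DataFrame(
            [(t.fish_id, t.testing) for t in small_cohort.physiology],
            columns=["fish_id", "testing"],
        ).groupby("fish_id")["testing"].nunique()
        assert (per_fish == 2).all()

    def test_retest_logic_keeps_final_attempt_informed_biased(self, small_cohort):
        by_fish = {}
        for trial in small_cohort.choice:
            by_fish[trial.fish_id] = trial
        informed_final = [t.events.informed for t in by_fish.values()]
        # forced final attempts make nearly all final trials informed
        assert np.mean(informed_final) > 0.9
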