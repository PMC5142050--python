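"""Trace segmentation, slope fitting, MO2 conversion and background
correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shoalresp.respirometry import (
    BackgroundModel,
    ChamberGeometry,
    InsufficientDataError,
    Mo2Record,
    OxygenTrace,
    PhaseSchedule,
    correct_background,
    estimate_background,
    fit_slope,
    process_trace,
    segment_trace,
    slope_to_mo2,
)
from shoalresp.simulate import SimConfig, config_with, simulate_oxygen_trace


def make_trace(duration_s=3600.0, slope_per_h=-1.0, o2_0=8.0, dt=2.0):
    t = np.arange(0.0, duration_s, dt)
    return OxygenTrace(t, o2_0 + slope_per_h / 3600.0 * t, dt)


class TestSegmentation:
    def test_cycle_arithmetic(self):
        """3600 s at 540/180 with 60 s discard -> 5 windows of 480 s."""
        trace = make_trace(3600.0)
        windows = segment_trace(trace, PhaseSchedule(540.0, 180.0, 60.0))
        assert len(windows) == 5
        for w in windows:
            assert w.duration == pytest.approx(478.0, abs=2.0)  # grid-quantized

    def test_zero_discard_full_phase(self):
        trace = make_trace(720.0)
        (window,) = segment_trace(trace, PhaseSchedule(540.0, 180.0, 0.0))
        assert window.time[0] == 0.0
        assert window.duration == pytest.approx(538.0, abs=2.0)

    def test_short_trace_warns_and_returns_empty(self):
        trace = make_trace(200.0)
        with pytest.warns(UserWarning, match="shorter"):
            assert segment_trace(trace, PhaseSchedule()) == []

    def test_windows_match_generator_phase_labels(self, default_config):
        """Clock-based windows must land inside the generator's true
        measurement phases (flush samples excluded)."""
        cfg = config_with(default_config, trial_hours_range=(2.0, 2.0))
        trace, _ = simulate_oxygen_trace(0.6, 1.29, cfg, "alone", 5)
        schedule = cfg.schedule
        for w in segment_trace(trace, schedule):
            within = np.mod(w.time, schedule.cycle_s)
            assert within.min() >= schedule.equilibration_discard_s
            assert within.max() < schedule.measure_s


class TestSlopeFit:
    def test_exact_line(self):
        fit = fit_slope(make_trace(480.0, slope_per_h=-1.0))
        assert fit.slope == pytest.approx(-1.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_o2(self):
        fit = fit_slope(make_trace(480.0, slope_per_h=0.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_points(self):
        trace = OxygenTrace(np.arange(5) * 2.0 + 1.0, np.full(5, 8.0))
        with pytest.raises(InsufficientDataError):
            fit_slope(trace)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_equals_closed_form_ols(self, seed):
        """fit_slope is the closed-form OLS solution on arbitrary inputs."""
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 300))
        t = np.cumsum(r.uniform(0.5, 3.0, n))
        y = r.uniform(4.0, 9.0, n)
        fit = fit_slope(OxygenTrace(t, y))
        ref_slope, ref_icept = np.polyfit(t, y, 1)
        assert fit.slope == pytest.approx(ref_slope * 3600.0, rel=1e-9, abs=1e-12)
        assert fit.intercept == pytest.approx(ref_icept, rel=1e-9, abs=1e-12)

    def test_noisy_slope_recovery_matches_sampling_theory(self):
        """With sigma = 0.01 mg/L noise on a 480 s / 2 s phase, ~95% of
        estimates fall within 1.96 closed-form standard errors of the true
        slope (-0.8 mg/L/h)."""
        t = np.arange(0.0, 480.0, 2.0)
        sxx = float(((t - t.mean()) ** 2).sum())
        se_per_h = 0.01 / np.sqrt(sxx) * 3600.0
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            y = 8.0 - 0.8 / 3600.0 * t + r.normal(0.0, 0.01, t.size)
            fit = fit_slope(OxygenTrace(t, y))
            hits += abs(fit.slope + 0.8) < 1.96 * se_per_h
        assert hits / n_seeds > 0.90


class TestMo2Conversion:
    def test_hand_computed_effective_volume(self, geometry):
        """100 ml chamber, 1.29 g fish -> V_eff 0.09871 L; slope -1 mg/L/h
        gives MO2 = 0.09871 mg/h."""
        assert geometry.effective_volume_l == pytest.approx(0.09871, abs=1e-6)
        fit = fit_slope(make_trace(480.0, slope_per_h=-1.0))
        rec = slope_to_mo2(fit, geometry)
        assert rec.mo2 == pytest.approx(0.09871, rel=1e-6)

    def test_zero_slope_zero_mo2(self, geometry):
        rec = slope_to_mo2(fit_slope(make_trace(480.0, 0.0)), geometry)
        assert rec.mo2 == 0.0

    def test_linear_in_volume(self):
        fit = fit_slope(make_trace(480.0, -1.0))
        small = slope_to_mo2(fit, ChamberGeometry(0.100, 0.0))
        big = slope_to_mo2(fit, ChamberGeometry(0.200, 0.0))
        assert big.mo2 == pytest.approx(2.0 * small.mo2, rel=1e-12)

    def test_positive_slope_flagged(self, geometry):
        rec = slope_to_mo2(fit_slope(make_trace(480.0, +0.5)), geometry)
        assert rec.flagged and rec.mo2 == 0.0


class TestBackground:
    def _fit(self, slope):
        return fit_slope(make_trace(480.0, slope))

    def test_zero_background(self, geometry):
        model = estimate_background([self._fit(0.0)], [self._fit(0.0)], (0, 3600))
        recs = [Mo2Record(t_mid=1800.0, mo2=0.5)]
        assert correct_background(recs, model, geometry)[0].mo2 == pytest.approx(0.5)

    def test_midpoint_interpolation(self):
        model = estimate_background(
            [self._fit(0.0)], [self._fit(-0.02)], (0.0, 3600.0)
        )
        assert model.slope_at(1800.0) == pytest.approx(0.01, rel=1e-9)

    def test_uniform_background_uniform_shift(self, geometry):
        model = BackgroundModel(0.1, 0.1, 0.0, 3600.0)
        recs = [Mo2Record(t_mid=t, mo2=0.5) for t in (100.0, 1800.0, 3500.0)]
        out = correct_background(recs, model, geometry)
        expected = 0.5 - 0.1 * geometry.effective_volume_l
        for rec in out:
            assert rec.mo2 == pytest.approx(expected, rel=1e-9)
            assert rec.background_corrected

    def test_negative_corrected_floored_and_flagged(self, geometry):
        model = BackgroundModel(10.0, 10.0, 0.0, 3600.0)
        (rec,) = correct_background(
            [Mo2Record(t_mid=100.0, mo2=0.1)], model, geometry
        )
        assert rec.mo2 == 0.0 and rec.flagged

    def test_out_of_span_warns_uses_endpoint(self, geometry):
        model = BackgroundModel(0.0, 0.02, 0.0, 3600.0)
        with pytest.warns(UserWarning, match="outside"):
            (rec,) = correct_background(
                [Mo2Record(t_mid=4000.0, mo2=0.5)], model, geometry
            )
        assert rec.mo2 == pytest.approx(0.5 - 0.02 * geometry.effective_volume_l)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="each side"):
            estimate_background([], [self._fit(0.0)], (0, 100))


class TestPipelineProperties:
    def test_noiseless_trace_recovers_programmed_slope_exactly(
        self, default_config, geometry
    ):
        """noise -> 0, stress -> 0, drift -> 0: every phase slope equals
        -SMR/V_eff to floating point."""
        cfg = config_with(
            default_config,
            sensor_noise_sd=0.0,
            stress_multiplier=0.0,
            background_b0=0.0,
            background_b1=0.0,
            trial_hours_range=(3.0, 3.0),
        )
        trace, truth = simulate_oxygen_trace(0.6, 1.29, cfg, "alone", 11)
        expected = -0.6 / truth.effective_volume_l
        for w in segment_trace(trace, cfg.schedule):
            assert fit_slope(w).slope == pytest.approx(expected, rel=1e-9)

    def test_correction_commutes_with_concentration_scaling(
        self, default_config, geometry
    ):
        """Scaling all concentrations by c scales slopes and corrected MO2
        by c."""
        cfg = config_with(default_config, trial_hours_range=(2.0, 2.0))
        trace, truth = simulate_oxygen_trace(0.6, 1.29, cfg, "alone", 13)
        model = BackgroundModel(0.004, 0.006, 0.0, truth.duration_s)
        scaled_model = BackgroundModel(0.008, 0.012, 0.0, truth.duration_s)
        c = 2.0
        scaled = OxygenTrace(trace.time, trace.o2 * c, trace.sample_interval)
        base = process_trace(trace, cfg.schedule, geometry, background=model)
        doubled = process_trace(
            scaled, cfg.schedule, geometry, background=scaled_model
        )
        assert len(base) == len(doubled)
        for a, b in zip(base, doubled):
            if not (a.flagged or b.flagged):
                assert b.mo2 == pytest.approx(c * a.mo2, rel=1e-9)
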