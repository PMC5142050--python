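"""Intermittent-flow respirometry trace processing.

A trial alternates sealed measurement phases (dissolved O2 falls as the fish
respires) with flush phases (the chamber is re-equilibrated with saturated
water).  This module segments a raw trace on the pump clock, fits an ordinary
least-squares line to each measurement phase, converts slopes to whole-animal
oxygen uptake rates (MO2, mg O2 h-1) using the effective chamber volume, and
subtracts microbial background respiration assumed to grow linearly between
pre- and post-trial empty-chamber measurements.

Sign convention: oxygen concentration falls during measurement, so raw slopes
are negative; MO2 is stored positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class InsufficientDataError(ValueError):
    pass


@dataclass
class OxygenTrace:
    """Dissolved-oxygen time series: time (s, strictly increasing) and O2
    concentration (mg/L), nominally sampled every 2 s."""

    time: np.ndarray
    o2: np.ndarray
    sample_interval: float = 2.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.time.size < 2:
            raise InsufficientDataError("trace needs at least 2 points")
        if self.time.shape != self.o2.shape:
            raise ValueError("time and o2 must have equal length")
        dt = np.diff(self.time)
        if not np.all(dt > 0):
            bad = np.flatnonzero(dt <= 0)
            raise ValueError(
                f"time must be strictly increasing; offending rows {bad[:10].tolist()}"
            )
        if np.any(self.o2 <= 0):
            raise ValueError("o2 concentrations must be positive")
        if np.any(dt > 5.0 * self.sample_interval):
            warnings.warn(
                f"trace contains gaps larger than 5x the sample interval "
                f"({self.sample_interval} s)",
                stacklevel=2,
            )

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class PhaseSchedule:
    """Pump timing: measurement duration, flush duration, and the leading
    seconds of each measurement phase discarded for re-equilibration."""

    measure_s: float = 540.0
    flush_s: float = 180.0
    equilibration_discard_s: float = 60.0

    def __post_init__(self) -> None:
        if not self.measure_s > self.equilibration_discard_s >= 0:
            raise ValueError("need measure_s > equilibration_discard_s >= 0")
        if not self.flush_s > 0:
            raise ValueError("flush_s must be positive")

    @property
    def cycle_s(self) -> float:
        return self.measure_s + self.flush_s


@dataclass(frozen=True)
class SlopeFit:
    slope: float  # mg O2 L-1 h-1, signed (uptake negative)
    intercept: float  # mg/L
    r_squared: float
    n_points: int
    t_mid: float  # s, phase midpoint

    @property
    def valid(self) -> bool:
        return self.n_points >= 10 and 0.0 <= self.r_squared <= 1.0


@dataclass(frozen=True)
class ChamberGeometry:
    """Respirometer geometry. Effective volume subtracts the fish's body
    volume (mass at ~1 g/ml) from the chamber + tubing volume."""

    chamber_volume_l: float = 0.100
    fish_mass_g: float = 0.0
    fish_density_g_per_ml: float = 1.0
    subtract_fish_volume: bool = True

    @property
    def effective_volume_l(self) -> float:
        v = self.chamber_volume_l
        if self.subtract_fish_volume:
            v -= self.fish_mass_g / (1000.0 * self.fish_density_g_per_ml)
        if v <= 0:
            raise ValueError(
                f"effective volume {v} L <= 0 (chamber {self.chamber_volume_l} L, "
                f"fish {self.fish_mass_g} g)"
            )
        return v


@dataclass(frozen=True)
class BackgroundModel:
    """Microbial background O2 consumption (slope units, mg O2 L-1 h-1)
    interpolated linearly between the pre- and post-trial means."""

    pre_slope: float
    post_slope: float
    t_start: float
    t_end: float

    def slope_at(self, t: float | np.ndarray) -> float | np.ndarray:
        if self.t_end <= self.t_start:
            return self.pre_slope
        frac = np.clip((np.asarray(t, float) - self.t_start)
                       / (self.t_end - self.t_start), 0.0, 1.0)
        out = self.pre_slope + frac * (self.post_slope - self.pre_slope)
        return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class Mo2Record:
    t_mid: float
    mo2: float  # mg O2 h-1, whole animal, >= 0
    background_corrected: bool = False
    flagged: bool = False  # positive-slope or floored-negative records
    source_fit: Optional[SlopeFit] = None
    background_model: Optional[BackgroundModel] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.mo2):
            raise ValueError("mo2 must be finite")


def segment_trace(
    trace: OxygenTrace, schedule: PhaseSchedule
) -> list[OxygenTrace]:
    """Split a trace into its measurement-phase windows on the pump clock.

    Each window drops the leading ``equilibration_discard_s`` seconds; a
    partial trailing measurement phase is dropped.  Phase boundaries are
    clock-based (the apparatus cycles pumps on a fixed timer), measured from
    the first sample.
    """
    t0 = trace.time[0]
    if trace.duration < schedule.cycle_s - schedule.flush_s:
        warnings.warn("trace shorter than one measurement phase", stacklevel=2)
        return []
    windows: list[OxygenTrace] = []
    n_cycles = int(np.floor((trace.duration + schedule.flush_s) / schedule.cycle_s))
    for k in range(n_cycles):
        start = t0 + k * schedule.cycle_s + schedule.equilibration_discard_s
        end = t0 + k * schedule.cycle_s + schedule.measure_s
        if end > trace.time[-1] + 0.5 * trace.sample_interval:
            break
        lo = np.searchsorted(trace.time, start - 1e-9)
        hi = np.searchsorted(trace.time, end - 1e-9)
        if hi - lo >= 2:
            windows.append(
                OxygenTrace(
                    trace.time[lo:hi], trace.o2[lo:hi], trace.sample_interval
                )
            )
    return windows


def fit_slope(phase: OxygenTrace, min_points: int = 10) -> SlopeFit:
    """Ordinary least squares of O2 on time, rescaled to mg O2 L-1 h-1.

    Identical to the closed-form OLS solution; r² is the squared Pearson
    correlation (1.0 for an exact line, 0.0 when O2 is constant).
    """
    t, y = phase.time, phase.o2
    if t.size < min_points:
        raise InsufficientDataError(
            f"phase has {t.size} points; need >= {min_points}"
        )
    tc = t - t.mean()
    sxx = float(tc @ tc)
    if sxx == 0.0:
        raise FloatingPointError("degenerate time variance in phase")
    slope_per_s = float(tc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope_per_s * t.mean())
    resid = y - (intercept + slope_per_s * t)
    syy = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 0.0
    return SlopeFit(
        slope=slope_per_s * 3600.0,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=int(t.size),
        t_mid=float(0.5 * (t[0] + t[-1])),
    )


def slope_to_mo2(
    fit: SlopeFit,
    geom: ChamberGeometry,
    positive_slope_tol: float = 0.0,
) -> Mo2Record:
    """Convert a phase slope to whole-animal oxygen uptake:
    MO2 = |slope| × V_eff (mg O2 h-1).

    Oxygen-increasing slopes beyond ``positive_slope_tol`` are returned with
    mo2 = 0 and flagged for downstream exclusion.
    """
    v = geom.effective_volume_l
    if fit.slope > positive_slope_tol:
        return Mo2Record(t_mid=fit.t_mid, mo2=0.0, flagged=True, source_fit=fit)
    return Mo2Record(t_mid=fit.t_mid, mo2=abs(fit.slope) * v, source_fit=fit)


def estimate_background(
    pre_fits: Sequence[SlopeFit],
    post_fits: Sequence[SlopeFit],
    trial_span: tuple[float, float],
) -> BackgroundModel:
    """Background model from empty-chamber slope fits before and after the
    trial: endpoint slopes are the means of each side (uptake magnitude,
    positive), interpolated linearly across the trial."""
    if not pre_fits or not post_fits:
        raise ValueError("need at least one background fit on each side")
    pre = float(np.mean([abs(f.slope) for f in pre_fits]))
    post = float(np.mean([abs(f.slope) for f in post_fits]))
    return BackgroundModel(
        pre_slope=pre, post_slope=post,
        t_start=float(trial_span[0]), t_end=float(trial_span[1]),
    )


def correct_background(
    records: Sequence[Mo2Record],
    model: BackgroundModel,
    geom: ChamberGeometry,
) -> list[Mo2Record]:
    """Subtract interpolated background uptake (slope × V_eff) from each
    record.  Negative corrected values are floored at 0 and flagged; records
    outside the model span use the nearest endpoint with a warning."""
    v = geom.effective_volume_l
    out: list[Mo2Record] = []
    for rec in records:
        if rec.t_mid < model.t_start or rec.t_mid > model.t_end:
            warnings.warn(
                f"record at t={rec.t_mid} s outside background span "
                f"[{model.t_start}, {model.t_end}]; endpoint value used",
                stacklevel=2,
            )
        corrected = rec.mo2 - float(model.slope_at(rec.t_mid)) * v
        flagged = rec.flagged
        if corrected < 0:
            corrected, flagged = 0.0, True
        out.append(
            Mo2Record(
                t_mid=rec.t_mid,
                mo2=corrected,
                background_corrected=True,
                flagged=flagged,
                source_fit=rec.source_fit,
                background_model=model,
            )
        )
    return out


def process_trace(
    trace: OxygenTrace,
    schedule: PhaseSchedule,
    geom: ChamberGeometry,
    background: Optional[BackgroundModel] = None,
    r2_min: float = 0.9,
) -> list[Mo2Record]:
    """Full chain: segment → fit → convert → (optionally) background-correct.

    Phases failing the slope-quality filter (r² < ``r2_min``) are excluded;
    constant-O2 phases (slope 0, undefined r²) are kept.
    """
    records = []
    for phase in segment_trace(trace, schedule):
        fit = fit_slope(phase)
        if fit.r_squared < r2_min and abs(fit.slope) > 1e-12:
            continue
        records.append(slope_to_mo2(fit, geom))
    if background is not None:
        records = correct_background(records, background, geom)
    return records
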