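"""Synthetic-study generator with recorded ground truth.

No raw data accompany the study this package models, so every upstream stage
is exercised against simulated inputs whose generating parameters are known:

* **Respirometry traces** — intermittent-flow O2 series (9-min measure /
  3-min flush, 2-s sampling, 17–19 h overnight trials).  True instantaneous
  oxygen uptake is SMR × calming(testing) × (1 + A·exp(−t/τ)): a handling-
  stress elevation that decays over the first hours, a multiplicative group
  "calming" reduction, linearly growing microbial background respiration, and
  Gaussian optode noise.
* **Chase recoveries** — 8–10 min post-exercise traces whose uptake starts at
  MMR (SMR × aerobic-scope multiplier) and relaxes exponentially toward SMR.
* **Choice trajectories** — a continuous-time sojourn model of a focal fish
  alternating zone visits and neutral transits in the 90 × 30 cm arena; each
  transit targets the familiar zone with probability p_familiar.  An
  uninformed fraction of trials never samples both zones and triggers the
  retest rule.

Determinism: a master seed fans out per-fish/per-purpose child seeds through
``numpy.random.SeedSequence``, so identical configs give identical datasets
at every granularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .behavior import ArenaGeometry, Trajectory
from .respirometry import ChamberGeometry, OxygenTrace, PhaseSchedule

Testing = Literal["alone", "group"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.  Defaults are the study conditions: mean mass
    1.29 g (SD 0.22 = SEM 0.04 × √30), 9/3-min cycling at 2-s sampling over
    17–19 h, group calming multiplier 0.772 (a 22.8% MR_min reduction),
    ~5 h stress stabilization (exponential, τ = 1.5 h), 22% uninformed
    choice trials, and sojourn/transit means calibrated to the observed
    mean of 44.7 zone visits per 15-min trial."""

    seed: int = 0
    # cohort layout
    n_fish_per_treatment: int = 10      # experiment 2 (physiology)
    n_shoals_per_treatment: int = 9     # experiment 1 (behaviour)
    n_focal_per_shoal: int = 2
    # fish
    mass_mean_g: float = 1.29
    mass_sd_g: float = 0.22
    length_mean_cm: float = 3.22
    length_sd_cm: float = 0.16
    # metabolism: SMR = allometry_a * mass^allometry_b, lognormal scatter
    allometry_a: float = 0.49           # mg O2 h-1 at 1 g
    allometry_b: float = 0.8
    smr_cv: float = 0.15
    stress_multiplier: float = 1.0      # A: fractional elevation at transfer
    stress_decay_h: float = 1.5         # tau; elevation ~3% of A by 5 h
    calming_multiplier: float = 0.772   # group-testing MR_min factor
    scope_multiplier: float = 3.0       # MMR = SMR * scope_multiplier
    recovery_decay_s: float = 600.0     # post-chase relaxation constant
    # apparatus
    chamber_volume_l: float = 0.100
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    sample_interval_s: float = 2.0
    o2_saturation_mg_l: float = 6.4     # ~29 degC, 35 psu
    flush_tau_s: float = 30.0
    sensor_noise_sd: float = 0.01       # mg/L
    background_b0: float = 0.005        # mg O2 L-1 h-1 at trial start
    background_b1: float = 0.002        # growth per hour
    trial_hours_range: tuple[float, float] = (17.0, 19.0)
    recovery_minutes_range: tuple[float, float] = (8.0, 10.0)
    o2_floor_mg_l: float = 2.0
    # activity (turns/min, daylight)
    activity_mean_turns: float = 9.5
    activity_cv: float = 0.6
    # choice trials
    p_familiar: tuple[tuple[int, float], ...] = ((450, 0.65), (750, 0.5), (1000, 0.5))
    shoal_pref_sd_logit: float = 0.25   # between-shoal spread of p_familiar
    uninformed_prob: float = 0.22
    mean_sojourn_s: float = 14.0
    mean_transit_s: float = 6.0
    choice_duration_s: float = 900.0
    traj_dt_s: float = 0.5
    max_retests: int = 3
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)

    def __post_init__(self) -> None:
        if self.mean_sojourn_s <= 0 or self.mean_transit_s <= 0:
            raise ValueError("sojourn/transit means must be positive")
        if not 0.0 <= self.uninformed_prob <= 1.0:
            raise ValueError("uninformed_prob must lie in [0, 1]")
        for _, p in self.p_familiar:
            if not 0.0 <= p <= 1.0:
                raise ValueError("p_familiar values must lie in [0, 1]")
        if self.calming_multiplier <= 0 or self.scope_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        if min(self.smr_cv, self.sensor_noise_sd, self.mass_sd_g,
               self.shoal_pref_sd_logit, self.activity_cv) < 0:
            raise ValueError("dispersions must be non-negative")

    def p_familiar_for(self, co2: int) -> float:
        return dict(self.p_familiar)[co2]


@dataclass
class TraceTruth:
    smr_true: float           # mg O2 h-1 (pre-calming baseline)
    calming_applied: float    # multiplier actually applied to this trial
    mo2_baseline: float       # smr_true * calming_applied
    stress_multiplier: float
    stress_decay_h: float
    background_b0: float
    background_b1: float
    effective_volume_l: float
    duration_s: float

    def mo2_at(self, t_s: np.ndarray | float) -> np.ndarray | float:
        """True instantaneous uptake (mg O2 h-1) at time t seconds."""
        decay = np.exp(-np.asarray(t_s, float) / (self.stress_decay_h * 3600.0))
        return self.mo2_baseline * (1.0 + self.stress_multiplier * decay)

    def mean_mo2(self, t_from_s: float, t_to_s: float) -> float:
        """Exact time-average of the true uptake over [t_from, t_to]."""
        tau = self.stress_decay_h * 3600.0
        span = t_to_s - t_from_s
        integral = span + self.stress_multiplier * tau * (
            math.exp(-t_from_s / tau) - math.exp(-t_to_s / tau)
        )
        return self.mo2_baseline * integral / span


def _integrated_consumption(truth: TraceTruth, t: np.ndarray) -> np.ndarray:
    """Cumulative O2 (mg/L) consumed by fish + background from time 0 to t,
    were the chamber permanently sealed (closed form)."""
    tau = truth.stress_decay_h * 3600.0
    fish = truth.mo2_baseline * (
        t + truth.stress_multiplier * tau * (1.0 - np.exp(-t / tau))
    ) / truth.effective_volume_l
    t_h = t / 3600.0
    bg = truth.background_b0 * t_h + 0.5 * truth.background_b1 * t_h ** 2
    return (fish / 3600.0) * 1.0 + bg  # fish term converted from h to s basis


def simulate_oxygen_trace(
    smr_true: float,
    mass_g: float,
    config: SimConfig,
    testing: Testing,
    seed: int | np.random.SeedSequence,
) -> tuple[OxygenTrace, TraceTruth]:
    """One overnight intermittent-flow trial for one fish.

    Within each measurement phase O2 falls at (MO2(t) + bg(t)·V_eff)/V_eff;
    flush phases relax O2 back toward saturation with a 30-s constant.
    Gaussian sensor noise is added to every sample.  Same seed, same trace.
    """
    rng = np.random.default_rng(seed)
    geom = ChamberGeometry(config.chamber_volume_l, mass_g)
    calming = config.calming_multiplier if testing == "group" else 1.0
    hours = rng.uniform(*config.trial_hours_range)
    duration = hours * 3600.0
    dt = config.sample_interval_s
    t = np.arange(0.0, duration, dt)

    truth = TraceTruth(
        smr_true=smr_true,
        calming_applied=calming,
        mo2_baseline=smr_true * calming,
        stress_multiplier=config.stress_multiplier,
        stress_decay_h=config.stress_decay_h,
        background_b0=config.background_b0,
        background_b1=config.background_b1,
        effective_volume_l=geom.effective_volume_l,
        duration_s=duration,
    )

    # Worst case O2 at the end of the first (stress-elevated) phase.
    peak_rate = (truth.mo2_at(0.0) / truth.effective_volume_l
                 + config.background_b0)  # mg/L/h
    worst = config.o2_saturation_mg_l - peak_rate * config.schedule.measure_s / 3600.0
    if worst < config.o2_floor_mg_l:
        raise ValueError(
            f"parameters imply O2 {worst:.2f} mg/L < floor "
            f"{config.o2_floor_mg_l} mg/L within a measurement phase"
        )

    cycle = config.schedule.cycle_s
    measure = config.schedule.measure_s
    consumed = _integrated_consumption(truth, t)
    tc = np.mod(t, cycle)
    k = np.floor_divide(t, cycle).astype(int)
    n_cycles = int(k.max()) + 1

    o2 = np.empty_like(t)
    sat = config.o2_saturation_mg_l
    o2_start = sat
    for c in range(n_cycles):
        sel = k == c
        tcs = tc[sel]
        cons = consumed[sel]
        base = np.interp(c * cycle, t, consumed) if c else 0.0
        phase_o2 = np.where(
            tcs < measure,
            o2_start - (cons - base),
            np.nan,  # flush filled below
        )
        # value at the end of the measurement phase
        end_meas = o2_start - (
            float(np.interp(c * cycle + measure, t, consumed)) - base
        )
        flush_sel = tcs >= measure
        phase_o2[flush_sel] = sat + (end_meas - sat) * np.exp(
            -(tcs[flush_sel] - measure) / config.flush_tau_s
        )
        o2[sel] = phase_o2
        o2_start = sat + (end_meas - sat) * math.exp(
            -config.schedule.flush_s / config.flush_tau_s
        )

    if config.sensor_noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.sensor_noise_sd, size=o2.shape)
    o2 = np.maximum(o2, 1e-3)
    return OxygenTrace(t, o2, dt), truth


def expected_recovery_window_mean(
    smr_true: float, mmr_true: float, window_s: float, tau_s: float
) -> float:
    """Closed-form mean uptake over the first recovery window of length
    ``window_s`` when MO2 relaxes as SMR + (MMR−SMR)·exp(−t/τ)."""
    frac = (tau_s / window_s) * (1.0 - math.exp(-window_s / tau_s))
    return smr_true + (mmr_true - smr_true) * frac


def simulate_chase_recovery(
    smr_true: float,
    mass_g: float,
    config: SimConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[OxygenTrace, float]:
    """Post-chase recovery trace; returns (trace, true MMR).

    Uptake starts at MMR_true = SMR × scope multiplier and relaxes
    exponentially (constant ``recovery_decay_s``) toward SMR while the
    chamber stays sealed for 8–10 min.
    """
    rng = np.random.default_rng(seed)
    geom = ChamberGeometry(config.chamber_volume_l, mass_g)
    v = geom.effective_volume_l
    mmr_true = smr_true * config.scope_multiplier
    minutes = rng.uniform(*config.recovery_minutes_range)
    dt = config.sample_interval_s
    t = np.arange(0.0, minutes * 60.0, dt)
    tau = config.recovery_decay_s

    # integral of MO2 (mg/h) over [0, t] seconds -> consumed mg/L
    integral_h = smr_true * t / 3600.0 + (mmr_true - smr_true) * tau * (
        1.0 - np.exp(-t / tau)
    ) / 3600.0
    o2 = config.o2_saturation_mg_l - integral_h / v
    # The protocol caps the sealed recovery so saturation never falls too
    # far: truncate the trace where O2 would cross the floor.
    above = o2 >= config.o2_floor_mg_l
    if not above.all():
        cut = int(np.argmin(above))  # first sample below the floor
        if (cut - 1) * dt < 180.0:
            raise ValueError(
                f"O2 reaches the {config.o2_floor_mg_l} mg/L floor after "
                f"{cut * dt:.0f} s; not even one 180 s recovery window fits"
            )
        t, o2 = t[:cut], o2[:cut]
    if config.sensor_noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.sensor_noise_sd, size=o2.shape)
    return OxygenTrace(t, np.maximum(o2, 1e-3), dt), mmr_true


def simulate_background_trace(
    config: SimConfig,
    at_hour: float,
    n_phases: int,
    seed: int | np.random.SeedSequence,
) -> OxygenTrace:
    """Empty-chamber trace of ``n_phases`` measure/flush cycles with the
    microbial drift evaluated at ``at_hour`` hours into the trial clock."""
    rng = np.random.default_rng(seed)
    dt = config.sample_interval_s
    cycle = config.schedule.cycle_s
    t = np.arange(0.0, n_phases * cycle, dt)
    bg = config.background_b0 + config.background_b1 * at_hour  # mg/L/h
    tc = np.mod(t, cycle)
    within = np.minimum(tc, config.schedule.measure_s)
    o2 = config.o2_saturation_mg_l - bg * within / 3600.0
    flush = tc >= config.schedule.measure_s
    end_meas = config.o2_saturation_mg_l - bg * config.schedule.measure_s / 3600.0
    o2[flush] = config.o2_saturation_mg_l + (
        end_meas - config.o2_saturation_mg_l
    ) * np.exp(-(tc[flush] - config.schedule.measure_s) / config.flush_tau_s)
    if config.sensor_noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.sensor_noise_sd, size=o2.shape)
    return OxygenTrace(t, np.maximum(o2, 1e-3), dt)


# ---------------------------------------------------------------------------
# choice trials
# ---------------------------------------------------------------------------

@dataclass
class ChoiceEvents:
    """Event-level ground truth for one choice trial: alternating neutral
    transits and zone sojourns within the trial duration."""

    zones: list[str]            # visit sequence, 'familiar'/'unfamiliar'
    sojourns_s: list[float]     # realized in-zone durations
    transits_s: list[float]     # neutral transit before each visit
    duration_s: float
    uninformed: bool            # generator drew this trial as single-zone
    p_familiar: float

    @property
    def total_visits(self) -> int:
        return len(self.zones)

    @property
    def time_familiar(self) -> float:
        return sum(s for z, s in zip(self.zones, self.sojourns_s) if z == "familiar")

    @property
    def time_unfamiliar(self) -> float:
        return sum(s for z, s in zip(self.zones, self.sojourns_s) if z != "familiar")

    @property
    def initial_choice(self) -> str:
        return self.zones[0] if self.zones else "none"

    @property
    def informed(self) -> bool:
        return len(set(self.zones)) == 2

    @property
    def familiar_preference(self) -> float:
        tot = self.time_familiar + self.time_unfamiliar
        return self.time_familiar / tot if tot > 0 else float("nan")


def simulate_choice_events(
    p_familiar: float,
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    force_informed: bool = False,
) -> ChoiceEvents:
    """Draw the zone-visit event sequence for one trial.

    Sojourn and transit durations are exponential; each visit targets the
    familiar zone with probability ``p_familiar``.  With probability
    ``uninformed_prob`` (unless ``force_informed``) the fish samples a single
    zone only; otherwise a trial whose draws all landed on one zone has one
    uniformly chosen visit flipped so both zones are sampled (informed-choice
    guarantee).
    """
    rng = np.random.default_rng(seed)
    uninformed = (not force_informed) and rng.random() < config.uninformed_prob
    zones: list[str] = []
    sojourns: list[float] = []
    transits: list[float] = []
    elapsed = 0.0
    single_zone = (
        ("familiar" if rng.random() < p_familiar else "unfamiliar")
        if uninformed
        else None
    )
    while True:
        transit = rng.exponential(config.mean_transit_s)
        if elapsed + transit >= config.choice_duration_s:
            break
        elapsed += transit
        zone = single_zone or (
            "familiar" if rng.random() < p_familiar else "unfamiliar"
        )
        sojourn = rng.exponential(config.mean_sojourn_s)
        sojourn = min(sojourn, config.choice_duration_s - elapsed)
        zones.append(zone)
        sojourns.append(sojourn)
        transits.append(transit)
        elapsed += sojourn
        if elapsed >= config.choice_duration_s:
            break
    if not uninformed and zones and len(set(zones)) == 1:
        flip = int(rng.integers(len(zones)))
        zones[flip] = "unfamiliar" if zones[flip] == "familiar" else "familiar"
    return ChoiceEvents(
        zones=zones,
        sojourns_s=sojourns,
        transits_s=transits,
        duration_s=config.choice_duration_s,
        uninformed=uninformed,
        p_familiar=p_familiar,
    )


def simulate_choice_trajectory(
    events: ChoiceEvents,
    config: SimConfig,
    familiar_side: Literal["left", "right"],
    seed: int | np.random.SeedSequence,
) -> Trajectory:
    """Emit a positional random walk consistent with an event sequence.

    The fish starts at the arena centre; each transit is a two-leg path
    through a random neutral waypoint (guaranteeing a zone exit between
    consecutive visits), and each sojourn jitters around an anchor inside
    the association zone.  Sampled every ``traj_dt_s`` seconds.
    """
    rng = np.random.default_rng(seed)
    arena = config.arena
    mid_y = arena.width_cm / 2.0
    anchor_off = arena.container_offset_cm + arena.container_radius_cm + 1.5
    anchors = {"left": (anchor_off, mid_y),
               "right": (arena.length_cm - anchor_off, mid_y)}
    side_of = {"familiar": familiar_side,
               "unfamiliar": "left" if familiar_side == "right" else "right"}

    dt = config.traj_dt_s
    pos = np.array([arena.length_cm / 2.0, mid_y])
    xs: list[float] = []
    ys: list[float] = []

    def emit_path(target: np.ndarray, duration: float) -> None:
        nonlocal pos
        n = max(int(round(duration / dt)), 1)
        frac = np.arange(1, n + 1) / n
        path_x = pos[0] + (target[0] - pos[0]) * frac
        path_y = pos[1] + (target[1] - pos[1]) * frac
        xs.extend(path_x)
        ys.extend(path_y)
        pos = target.copy()

    def emit_sojourn(center: np.ndarray, duration: float) -> None:
        nonlocal pos
        n = max(int(round(duration / dt)), 1)
        jit = rng.normal(0.0, 1.0, size=(n, 2)).clip(-3.0, 3.0)
        pts = center[None, :] + jit
        xs.extend(pts[:, 0])
        ys.extend(pts[:, 1])
        pos = pts[-1]

    for zone, sojourn, transit in zip(
        events.zones, events.sojourns_s, events.transits_s
    ):
        waypoint = np.array([
            rng.uniform(arena.length_cm * 0.40, arena.length_cm * 0.60),
            rng.uniform(arena.width_cm * 0.2, arena.width_cm * 0.8),
        ])
        anchor = np.array(anchors[side_of[zone]])
        emit_path(waypoint, transit / 2.0)
        emit_path(anchor, transit / 2.0)
        emit_sojourn(anchor, sojourn)

    # trailing neutral time to fill the trial
    total_emitted = len(xs) * dt
    if total_emitted < events.duration_s:
        waypoint = np.array([arena.length_cm / 2.0, mid_y])
        emit_path(waypoint, events.duration_s - total_emitted)

    n = len(xs)
    time = np.arange(1, n + 1) * dt
    x = np.clip(np.array(xs), 0.0, arena.length_cm)
    y = np.clip(np.array(ys), 0.0, arena.width_cm)
    return Trajectory(time=time, x=x, y=y, familiar_side=familiar_side)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class PhysiologyTrial:
    fish_id: str
    shoal_id: str
    co2: int
    mass_g: float
    testing: Testing
    trace: OxygenTrace
    truth: TraceTruth
    background_pre: OxygenTrace
    background_post: OxygenTrace


@dataclass
class ChoiceTrial:
    fish_id: str
    shoal_id: str
    co2: int
    body_length_cm: float
    familiar_side: Literal["left", "right"]
    attempt: int
    events: ChoiceEvents
    trajectory: Optional[Trajectory]


@dataclass
class CohortDataset:
    """One complete simulated study: metadata, all traces and trajectories,
    and the ground-truth table every estimator can be checked against."""

    config: SimConfig
    fish: pd.DataFrame                      # experiment 2 metadata
    physiology: list[PhysiologyTrial]
    chase: dict[str, tuple[OxygenTrace, float]]   # fish_id -> (trace, MMR_true)
    activity: pd.DataFrame                  # fish_id, testing, turns_per_min
    choice: list[ChoiceTrial]               # experiment 1, retests included
    ground_truth: pd.DataFrame


def _spawn(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))


def simulate_cohort(
    config: SimConfig,
    emit_trajectories: bool = True,
) -> CohortDataset:
    """Generate the full factorial study for one master seed.

    Experiment 2: ``n_fish_per_treatment`` fish per CO2 level, each with an
    alone and a group overnight trial (order randomized), pre/post empty-
    chamber backgrounds, one chase recovery, and activity counts.
    Experiment 1: ``n_shoals_per_treatment`` shoals × ``n_focal_per_shoal``
    focal fish per CO2 level; uninformed trials are retested with fresh
    seeds (final permitted attempt forced informed, mirroring the protocol's
    retest-until-informed rule).
    """
    co2_levels = [co2 for co2, _ in config.p_familiar]
    master = np.random.default_rng(_spawn(config.seed, 0))

    fish_rows = []
    physiology: list[PhysiologyTrial] = []
    chase: dict[str, tuple[OxygenTrace, float]] = {}
    activity_rows = []
    truth_rows = []

    for i_co2, co2 in enumerate(co2_levels):
        for i in range(config.n_fish_per_treatment):
            fid = f"F{co2}_{i:02d}"
            shoal = f"P{co2}_{i:02d}"  # one focal fish per physiology shoal
            rng = np.random.default_rng(_spawn(config.seed, 1, i_co2, i))
            mass = max(float(rng.normal(config.mass_mean_g, config.mass_sd_g)), 0.4)
            length = max(
                float(rng.normal(config.length_mean_cm, config.length_sd_cm)), 1.5
            )
            smr = (
                config.allometry_a
                * mass ** config.allometry_b
                * float(rng.lognormal(0.0, config.smr_cv))
            )
            order: list[Testing] = ["alone", "group"]
            if rng.random() < 0.5:
                order.reverse()
            for j, testing in enumerate(order):
                trace, truth = simulate_oxygen_trace(
                    smr, mass, config, testing,
                    _spawn(config.seed, 2, i_co2, i, j),
                )
                hours = truth.duration_s / 3600.0
                bg_pre = simulate_background_trace(
                    config, 0.0, 3, _spawn(config.seed, 3, i_co2, i, j, 0)
                )
                bg_post = simulate_background_trace(
                    config, hours, 3, _spawn(config.seed, 3, i_co2, i, j, 1)
                )
                physiology.append(
                    PhysiologyTrial(
                        fish_id=fid, shoal_id=shoal, co2=co2, mass_g=mass,
                        testing=testing, trace=trace, truth=truth,
                        background_pre=bg_pre, background_post=bg_post,
                    )
                )
                turns = float(
                    rng.lognormal(
                        math.log(config.activity_mean_turns)
                        - 0.5 * math.log1p(config.activity_cv ** 2),
                        math.sqrt(math.log1p(config.activity_cv ** 2)),
                    )
                )
                activity_rows.append(
                    {"fish_id": fid, "testing": testing, "turns_per_min": turns}
                )
            chase_trace, mmr_true = simulate_chase_recovery(
                smr, mass, config, _spawn(config.seed, 4, i_co2, i)
            )
            chase[fid] = (chase_trace, mmr_true)
            fish_rows.append(
                {
                    "fish_id": fid, "shoal_id": shoal, "co2_uatm": co2,
                    "mass_g": mass, "standard_length_cm": length,
                }
            )
            truth_rows.append(
                {
                    "fish_id": fid, "co2_uatm": co2, "smr_true": smr,
                    "mmr_true": mmr_true,
                    "calming_multiplier": config.calming_multiplier,
                    "true_pct_reduction": 100.0 * (1.0 - config.calming_multiplier),
                    "p_familiar": float("nan"),
                }
            )

    choice: list[ChoiceTrial] = []
    for i_co2, co2 in enumerate(co2_levels):
        p_co2 = config.p_familiar_for(co2)
        for s in range(config.n_shoals_per_treatment):
            rng = np.random.default_rng(_spawn(config.seed, 5, i_co2, s))
            logit = math.log(p_co2 / (1.0 - p_co2)) if 0 < p_co2 < 1 else (
                math.inf if p_co2 >= 1 else -math.inf
            )
            if math.isfinite(logit):
                shifted = logit + float(rng.normal(0.0, config.shoal_pref_sd_logit))
                p_shoal = 1.0 / (1.0 + math.exp(-shifted))
            else:
                p_shoal = p_co2
            shoal_id = f"S{co2}_{s:02d}"
            for f in range(config.n_focal_per_shoal):
                fid = f"C{co2}_{s:02d}_{f}"
                length = max(
                    float(rng.normal(config.length_mean_cm, config.length_sd_cm)),
                    1.5,
                )
                side: Literal["left", "right"] = (
                    "left" if rng.random() < 0.5 else "right"
                )
                for attempt in range(config.max_retests):
                    force = attempt == config.max_retests - 1
                    events = simulate_choice_events(
                        p_shoal, config,
                        _spawn(config.seed, 6, i_co2, s, f, attempt),
                        force_informed=force,
                    )
                    traj = (
                        simulate_choice_trajectory(
                            events, config, side,
                            _spawn(config.seed, 7, i_co2, s, f, attempt),
                        )
                        if emit_trajectories
                        else None
                    )
                    choice.append(
                        ChoiceTrial(
                            fish_id=fid, shoal_id=shoal_id, co2=co2,
                            body_length_cm=length, familiar_side=side,
                            attempt=attempt, events=events, trajectory=traj,
                        )
                    )
                    if events.informed:
                        break
                truth_rows.append(
                    {
                        "fish_id": fid, "co2_uatm": co2,
                        "smr_true": float("nan"), "mmr_true": float("nan"),
                        "calming_multiplier": float("nan"),
                        "true_pct_reduction": float("nan"),
                        "p_familiar": p_shoal,
                    }
                )

    _ = master  # reserved for future cohort-level draws
    return CohortDataset(
        config=config,
        fish=pd.DataFrame(fish_rows),
        physiology=physiology,
        chase=chase,
        activity=pd.DataFrame(activity_rows),
        choice=choice,
        ground_truth=pd.DataFrame(truth_rows),
    )


def config_with(config: SimConfig, **overrides) -> SimConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
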