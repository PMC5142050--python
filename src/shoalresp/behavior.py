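"""Shoal-choice trial scoring.

The choice arena is a 90 × 30 cm tank with a stimulus-shoal container near
each end wall; the focal fish associates with a shoal when it swims within
two body lengths of the container's outer wall.  A trial is scored into three
endpoints: the fraction of time spent in each association zone, the initial
zone choice after the start barrier lifts, and the total number of zone
visits (an activity proxy).  Fish that never sample both zones made no
informed comparison and are flagged for retest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena and stimulus-container layout (cm).  The association radius is
    expressed in body lengths beyond the container's outer wall."""

    length_cm: float = 90.0
    width_cm: float = 30.0
    container_offset_cm: float = 6.0  # container centre from the end wall
    container_radius_cm: float = 5.0
    association_radius_bl: float = 2.0
    body_length_cm: float = 3.22

    @property
    def association_radius_cm(self) -> float:
        """Zone radius around the container centre: container wall plus
        ``association_radius_bl`` body lengths."""
        return (
            self.container_radius_cm
            + self.association_radius_bl * self.body_length_cm
        )


@dataclass(frozen=True)
class ZoneMap:
    familiar_center: tuple[float, float]
    unfamiliar_center: tuple[float, float]
    radius_cm: float

    def membership(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-sample zone code: 1 familiar, -1 unfamiliar, 0 neutral."""
        fx, fy = self.familiar_center
        ux, uy = self.unfamiliar_center
        in_f = (x - fx) ** 2 + (y - fy) ** 2 <= self.radius_cm ** 2
        in_u = (x - ux) ** 2 + (y - uy) ** 2 <= self.radius_cm ** 2
        return np.where(in_f, 1, np.where(in_u, -1, 0))


def build_zones(geom: ArenaGeometry, familiar_side: Literal["left", "right"]) -> ZoneMap:
    """Construct the familiar/unfamiliar association zones.

    Zones are circles of ``association_radius_cm`` around each container
    centre; they must not cross the arena midline (the neutral corridor), and
    must fit inside the arena.
    """
    r = geom.association_radius_cm
    if geom.container_offset_cm + r >= geom.length_cm / 2.0:
        raise GeometryError(
            f"association zones (radius {r:.2f} cm from x="
            f"{geom.container_offset_cm} cm) would reach the arena midline"
        )
    mid_y = geom.width_cm / 2.0
    left = (geom.container_offset_cm, mid_y)
    right = (geom.length_cm - geom.container_offset_cm, mid_y)
    if familiar_side == "left":
        return ZoneMap(familiar_center=left, unfamiliar_center=right, radius_cm=r)
    if familiar_side == "right":
        return ZoneMap(familiar_center=right, unfamiliar_center=left, radius_cm=r)
    raise ValueError(f"familiar_side must be 'left' or 'right', got {familiar_side!r}")


@dataclass
class Trajectory:
    """Focal-fish positions (cm) over a trial, nominally 900 s."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    familiar_side: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time.shape == self.x.shape == self.y.shape):
            raise ValueError("time, x, y must have equal length")
        if self.time.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class ChoiceTestResult:
    prop_familiar: float
    prop_unfamiliar: float
    initial_choice: Literal["familiar", "unfamiliar", "none"]
    total_visits: int
    informed: bool
    fish_id: Optional[str] = None
    shoal_id: Optional[str] = None
    co2_treatment: Optional[int] = None

    def __post_init__(self) -> None:
        if self.prop_familiar + self.prop_unfamiliar > 1.0 + 1e-9:
            raise ValueError("zone time fractions exceed the trial duration")

    @property
    def prop_neutral(self) -> float:
        return 1.0 - self.prop_familiar - self.prop_unfamiliar

    @property
    def familiar_preference(self) -> float:
        """Familiar share of shoaling time,
        prop_familiar / (prop_familiar + prop_unfamiliar) — the quantity
        whose no-preference null is 0.5.  NaN if the fish never shoaled."""
        tot = self.prop_familiar + self.prop_unfamiliar
        return self.prop_familiar / tot if tot > 0 else float("nan")


def score_trajectory(
    traj: Trajectory,
    zones: ZoneMap,
    debounce_samples: int = 1,
    **ids,
) -> ChoiceTestResult:
    """Score one trial.

    Zone membership is evaluated per sample at the trajectory's native rate;
    time in zone weights each sample by its sampling interval.  A visit is an
    entry event into either association zone sustained for at least
    ``debounce_samples`` consecutive samples (debounce > 1 suppresses
    boundary jitter, mimicking human video scoring).
    """
    code = zones.membership(traj.x, traj.y)
    if debounce_samples > 1:
        code = _debounce(code, debounce_samples)

    dt = np.diff(traj.time)
    weights = np.concatenate([dt, dt[-1:]])
    total = float(weights.sum())
    prop_f = float(weights[code == 1].sum()) / total
    prop_u = float(weights[code == -1].sum()) / total

    in_zone = code != 0
    entries = np.flatnonzero(in_zone & ~np.concatenate([[False], in_zone[:-1]]))
    if in_zone[0]:
        entries = np.concatenate([[0], entries[entries != 0]])
    total_visits = int(entries.size)

    if total_visits == 0:
        initial: Literal["familiar", "unfamiliar", "none"] = "none"
    else:
        initial = "familiar" if code[entries[0]] == 1 else "unfamiliar"
    informed = bool(np.any(code == 1) and np.any(code == -1))

    return ChoiceTestResult(
        prop_familiar=prop_f,
        prop_unfamiliar=prop_u,
        initial_choice=initial,
        total_visits=total_visits,
        informed=informed,
        **ids,
    )


def _debounce(code: np.ndarray, n: int) -> np.ndarray:
    """Suppress zone residence shorter than ``n`` consecutive samples."""
    out = code.copy()
    i = 0
    while i < len(code):
        j = i
        while j < len(code) and code[j] == code[i]:
            j += 1
        if code[i] != 0 and (j - i) < n:
            out[i:j] = 0
        i = j
    return out


def apply_informed_filter(
    results: Sequence[ChoiceTestResult],
) -> tuple[list[ChoiceTestResult], list[Optional[str]]]:
    """Partition trials into informed (retained) and uninformed (retest).

    The retest list carries fish identifiers; no outcome is imputed.
    """
    retained = [r for r in results if r.informed]
    retest = [r.fish_id for r in results if not r.informed]
    return retained, retest
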