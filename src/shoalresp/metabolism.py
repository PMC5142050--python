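"""Per-fish metabolic summary statistics from corrected MO2 sequences.

Definitions (all in mg O2 h-1, whole animal):

* MR_min — minimal measured metabolic rate: the mean of the lowest 10% of
  all MO2 measurements from the long quiescent trial (SMR proxy).
* RMR — routine metabolic rate: mean MO2 excluding the first 5 h of
  habituation.
* MMR — maximum metabolic rate: the greatest MO2 over consecutive 3-min
  windows of the post-chase recovery trace.
* FS — the first measurement-phase MO2 after transfer to the respirometer.
* AS — aerobic scope, MMR − MR_min.
* ISR — initial stress response, (FS − MR_min)/AS: the fraction of aerobic
  scope consumed by handling stress.
* Calming effect — percentage reduction in MR_min when tested with
  shoal-mate cues versus alone.

Inference always uses whole-animal values with body mass as a covariate;
``mass_correct`` (residuals from the log-log mass scaling, re-anchored at the
study's mean mass) is for presentation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .respirometry import (
    ChamberGeometry,
    InsufficientDataError,
    Mo2Record,
    OxygenTrace,
    PhaseSchedule,
    fit_slope,
    slope_to_mo2,
)

CO2_TREATMENTS = (450, 750, 1000)  # µatm nominal


@dataclass(frozen=True)
class FishRecord:
    fish_id: str
    shoal_id: str
    co2_treatment: int
    mass_g: float
    standard_length_cm: float = float("nan")

    def __post_init__(self) -> None:
        if self.co2_treatment not in CO2_TREATMENTS:
            raise ValueError(
                f"co2_treatment must be one of {CO2_TREATMENTS}, "
                f"got {self.co2_treatment}"
            )
        if not self.mass_g > 0:
            raise ValueError("mass_g must be positive")


@dataclass(frozen=True)
class MetabolicSummary:
    fish_id: str
    testing_treatment: Literal["alone", "group"]
    mr_min: float
    rmr: float
    mmr: float
    fs: float
    aerobic_scope: float
    isr: float
    isr_out_of_range: bool = False
    mr_min_exceeds_rmr: bool = False

    def __post_init__(self) -> None:
        if not math.isclose(
            self.aerobic_scope, self.mmr - self.mr_min, rel_tol=1e-12, abs_tol=1e-12
        ):
            raise ValueError("aerobic_scope must equal mmr - mr_min")


@dataclass(frozen=True)
class CalmingEffect:
    fish_id: str
    pct_reduction: float  # 100 * (MR_min,alone - MR_min,group) / MR_min,alone


def _valid_mo2(records: Sequence[Mo2Record]) -> np.ndarray:
    return np.array([r.mo2 for r in records if not r.flagged], dtype=float)


def compute_mr_min(
    records: Sequence[Mo2Record],
    method: Literal["decile_mean", "quantile"] = "decile_mean",
) -> float:
    """MR_min as the lowest 10th percentile of all MO2 measurements.

    ``decile_mean`` (default, the convention of the SMR-quantification
    literature) averages the lowest ceil(n/10) values; ``quantile`` returns
    the 10% quantile point instead.
    """
    vals = _valid_mo2(records)
    if vals.size < 10:
        raise InsufficientDataError(
            f"need >= 10 valid MO2 records for MR_min, have {vals.size}"
        )
    if method == "quantile":
        return float(np.quantile(vals, 0.10))
    k = math.ceil(vals.size / 10)
    return float(np.sort(vals)[:k].mean())


def compute_rmr(
    records: Sequence[Mo2Record], exclude_first_h: float = 5.0
) -> float:
    """Routine metabolic rate: mean MO2 with the first ``exclude_first_h``
    hours (habituation window) excluded."""
    vals = np.array(
        [r.mo2 for r in records
         if not r.flagged and r.t_mid > exclude_first_h * 3600.0],
        dtype=float,
    )
    if vals.size == 0:
        raise InsufficientDataError(
            f"no records remain after excluding the first {exclude_first_h} h"
        )
    return float(vals.mean())


def compute_fs(records: Sequence[Mo2Record]) -> float:
    """First slope: the earliest valid measurement-phase MO2 after transfer."""
    ordered = sorted((r for r in records if not r.flagged), key=lambda r: r.t_mid)
    if not ordered:
        raise InsufficientDataError("no valid records for FS")
    return ordered[0].mo2


def compute_mmr(recovery_records: Sequence[Mo2Record]) -> float:
    """MMR: the greatest windowed MO2 of the post-chase recovery."""
    vals = _valid_mo2(recovery_records)
    if vals.size == 0:
        raise InsufficientDataError("no valid recovery windows for MMR")
    return float(vals.max())


def mmr_from_trace(
    trace: OxygenTrace,
    geom: ChamberGeometry,
    window_s: float = 180.0,
    mode: Literal["consecutive", "rolling"] = "consecutive",
) -> tuple[float, list[Mo2Record]]:
    """Windowed MMR from a raw recovery trace.

    Slopes are fit over ``window_s`` windows — consecutive and
    non-overlapping by default, or rolling with a one-sample step — and the
    greatest uptake is MMR.
    """
    if trace.duration < window_s:
        raise InsufficientDataError(
            f"recovery trace ({trace.duration:.0f} s) shorter than one "
            f"{window_s:.0f} s window"
        )
    t0 = trace.time[0]
    starts: list[float]
    if mode == "consecutive":
        n = int(trace.duration // window_s)
        starts = [t0 + k * window_s for k in range(n)]
    else:
        starts = [
            float(t) for t in trace.time if t + window_s <= trace.time[-1] + 1e-9
        ]
    records = []
    for start in starts:
        lo = np.searchsorted(trace.time, start - 1e-9)
        hi = np.searchsorted(trace.time, start + window_s - 1e-9)
        if hi - lo < 10:
            continue
        window = OxygenTrace(
            trace.time[lo:hi], trace.o2[lo:hi], trace.sample_interval
        )
        records.append(slope_to_mo2(fit_slope(window), geom))
    if not records:
        raise InsufficientDataError("no fittable recovery windows")
    return compute_mmr(records), records


def compute_isr(fs: float, mr_min: float, aerobic_scope: float) -> tuple[float, bool]:
    """ISR = (FS − MR_min)/AS; the flag marks values outside [0, 1]
    (returned unclamped)."""
    if not aerobic_scope > 0:
        raise ValueError(f"aerobic_scope must be positive, got {aerobic_scope}")
    isr = (fs - mr_min) / aerobic_scope
    return isr, not (0.0 <= isr <= 1.0)


def summarize(
    fish_id: str,
    testing_treatment: Literal["alone", "group"],
    records: Sequence[Mo2Record],
    mmr: float,
    mr_min_method: Literal["decile_mean", "quantile"] = "decile_mean",
    exclude_first_h: float = 5.0,
) -> MetabolicSummary:
    """Assemble the full per-fish × testing-treatment summary."""
    mr_min = compute_mr_min(records, method=mr_min_method)
    rmr = compute_rmr(records, exclude_first_h=exclude_first_h)
    fs = compute_fs(records)
    aerobic_scope = mmr - mr_min
    isr, out_of_range = compute_isr(fs, mr_min, aerobic_scope)
    return MetabolicSummary(
        fish_id=fish_id,
        testing_treatment=testing_treatment,
        mr_min=mr_min,
        rmr=rmr,
        mmr=mmr,
        fs=fs,
        aerobic_scope=aerobic_scope,
        isr=isr,
        isr_out_of_range=out_of_range,
        mr_min_exceeds_rmr=mr_min > rmr,
    )


def compute_calming(
    summary_alone: MetabolicSummary, summary_group: MetabolicSummary
) -> CalmingEffect:
    """Calming effect: 100 × (MR_min,alone − MR_min,group)/MR_min,alone.

    Increases under group testing come out negative (sign preserved).
    """
    if summary_alone.fish_id != summary_group.fish_id:
        raise ValueError(
            f"fish mismatch: {summary_alone.fish_id} vs {summary_group.fish_id}"
        )
    if (summary_alone.testing_treatment, summary_group.testing_treatment) != (
        "alone",
        "group",
    ):
        raise ValueError("summaries must be (alone, group) in that order")
    pct = 100.0 * (summary_alone.mr_min - summary_group.mr_min) / summary_alone.mr_min
    return CalmingEffect(fish_id=summary_alone.fish_id, pct_reduction=pct)


def mass_correct(
    values: Sequence[float],
    masses: Sequence[float],
    reference_mass: float = 1.29,
) -> np.ndarray:
    """Mass-correct metabolic values for presentation.

    Fits log10(value) ~ log10(mass) by OLS and returns
    10^(residual + fitted value at ``reference_mass``), i.e. every fish's
    value re-expressed at the study's mean mass.  Never used for inference.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(masses, dtype=float)
    if v.size != m.size:
        raise ValueError("values and masses must have equal length")
    if v.size < 3:
        raise ValueError("need >= 3 fish for the mass-scaling fit")
    if np.any(v <= 0) or np.any(m <= 0):
        raise ValueError("values and masses must be positive")
    log_v, log_m = np.log10(v), np.log10(m)
    x = log_m - log_m.mean()
    sxx = float(x @ x)
    if sxx == 0.0:
        # All masses identical: zero-leverage fit, residuals reproduce values.
        slope = 0.0
    else:
        slope = float(x @ (log_v - log_v.mean())) / sxx
    intercept = float(log_v.mean() - slope * log_m.mean())
    fitted = intercept + slope * log_m
    resid = log_v - fitted
    fitted_ref = intercept + slope * math.log10(reference_mass)
    return 10.0 ** (resid + fitted_ref)
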