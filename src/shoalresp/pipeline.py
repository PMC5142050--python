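"""End-to-end orchestration: cohort → MO2 records → summaries → inference.

Every step delegates to the module that owns it; this file only wires the
stages together and keeps tidy tables at the joints so each stage can also be
driven from CSV inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, inference, metabolism, respirometry
from .simulate import CohortDataset, PhysiologyTrial

log = logging.getLogger(__name__)


def background_for_trial(trial: PhysiologyTrial) -> respirometry.BackgroundModel:
    """Empty-chamber background model for one trial from its pre/post traces."""
    schedule = respirometry.PhaseSchedule()
    pre_fits = [
        respirometry.fit_slope(ph)
        for ph in respirometry.segment_trace(trial.background_pre, schedule)
    ]
    post_fits = [
        respirometry.fit_slope(ph)
        for ph in respirometry.segment_trace(trial.background_post, schedule)
    ]
    return respirometry.estimate_background(
        pre_fits, post_fits, (0.0, trial.truth.duration_s)
    )


def mo2_records_for_trial(
    trial: PhysiologyTrial,
    schedule: Optional[respirometry.PhaseSchedule] = None,
    r2_min: float = 0.9,
) -> list[respirometry.Mo2Record]:
    """Corrected MO2 sequence for one fish × testing trial."""
    schedule = schedule or respirometry.PhaseSchedule()
    geom = respirometry.ChamberGeometry(fish_mass_g=trial.mass_g)
    background = background_for_trial(trial)
    return respirometry.process_trace(
        trial.trace, schedule, geom, background=background, r2_min=r2_min
    )


@dataclass
class CohortResults:
    summaries: pd.DataFrame
    calming: pd.DataFrame
    choice_results: pd.DataFrame  # final attempt per fish
    retest_log: pd.DataFrame
    inference: dict = field(default_factory=dict)


def summarize_physiology(dataset: CohortDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per fish × testing metabolic summaries and per-fish calming effects."""
    meta = dataset.fish.set_index("fish_id")
    rows = []
    per_fish: dict[str, dict[str, metabolism.MetabolicSummary]] = {}
    for trial in dataset.physiology:
        records = mo2_records_for_trial(trial)
        geom = respirometry.ChamberGeometry(fish_mass_g=trial.mass_g)
        mmr, _ = metabolism.mmr_from_trace(dataset.chase[trial.fish_id][0], geom)
        summary = metabolism.summarize(
            trial.fish_id, trial.testing, records, mmr
        )
        per_fish.setdefault(trial.fish_id, {})[trial.testing] = summary
        rows.append(
            {
                "fish_id": trial.fish_id,
                "shoal_id": trial.shoal_id,
                "co2_uatm": trial.co2,
                "mass_g": trial.mass_g,
                "testing": trial.testing,
                "mr_min": summary.mr_min,
                "rmr": summary.rmr,
                "mmr": summary.mmr,
                "fs": summary.fs,
                "aerobic_scope": summary.aerobic_scope,
                "isr": summary.isr,
            }
        )
    summaries = pd.DataFrame(rows)

    calming_rows = []
    for fish_id, pair in per_fish.items():
        if "alone" in pair and "group" in pair:
            effect = metabolism.compute_calming(pair["alone"], pair["group"])
            calming_rows.append(
                {
                    "fish_id": fish_id,
                    "co2_uatm": int(meta.loc[fish_id, "co2_uatm"]),
                    "pct_reduction": effect.pct_reduction,
                }
            )
    return summaries, pd.DataFrame(calming_rows)


def score_choice_trials(dataset: CohortDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every fish's final choice attempt; earlier attempts go to the
    retest log.  Scores come from the positional trajectory when it was
    emitted, otherwise from the event-level ground truth."""
    final: dict[str, object] = {}
    retests = []
    for trial in dataset.choice:
        key = trial.fish_id
        if key in final:
            retests.append(
                {"fish_id": key, "attempt": final[key].attempt,
                 "informed": final[key].events.informed}
            )
        final[key] = trial

    rows = []
    for trial in final.values():
        if trial.trajectory is not None:
            arena = behavior.ArenaGeometry(
                body_length_cm=trial.body_length_cm
            )
            zones = behavior.build_zones(arena, trial.familiar_side)
            scored = behavior.score_trajectory(
                trial.trajectory, zones,
                fish_id=trial.fish_id, shoal_id=trial.shoal_id,
                co2_treatment=trial.co2,
            )
            rows.append(
                {
                    "fish_id": trial.fish_id, "shoal_id": trial.shoal_id,
                    "co2_uatm": trial.co2,
                    "prop_familiar": scored.prop_familiar,
                    "prop_unfamiliar": scored.prop_unfamiliar,
                    "preference": scored.familiar_preference,
                    "initial_choice": scored.initial_choice,
                    "total_visits": scored.total_visits,
                    "informed": scored.informed,
                    "attempt": trial.attempt,
                }
            )
        else:
            ev = trial.events
            rows.append(
                {
                    "fish_id": trial.fish_id, "shoal_id": trial.shoal_id,
                    "co2_uatm": trial.co2,
                    "prop_familiar": ev.time_familiar / ev.duration_s,
                    "prop_unfamiliar": ev.time_unfamiliar / ev.duration_s,
                    "preference": ev.familiar_preference,
                    "initial_choice": ev.initial_choice,
                    "total_visits": ev.total_visits,
                    "informed": ev.informed,
                    "attempt": trial.attempt,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(
        retests, columns=["fish_id", "attempt", "informed"]
    )


def run_inference(
    summaries: pd.DataFrame,
    choice_results: pd.DataFrame,
    activity: Optional[pd.DataFrame] = None,
) -> dict:
    """The study's model battery over processed tables."""
    out: dict = {}

    informed = choice_results[choice_results["informed"]].copy()
    if not informed.empty:
        out["preference_by_treatment"] = inference.preference_tests_by_treatment(
            informed
        )
        informed["chose_familiar"] = (
            informed["initial_choice"] == "familiar"
        ).astype(float)
        out["initial_choice"] = inference.initial_choice_test(informed)

    if not summaries.empty:
        for endpoint in ("mr_min", "rmr", "isr"):
            out[endpoint] = inference.metabolic_mixed_model(summaries, endpoint)
        out["mr_min_tukey"] = inference.tukey_contrasts(out["mr_min"])
        for endpoint in ("mmr", "aerobic_scope"):
            out[endpoint] = inference.fixed_effect_model(
                summaries[summaries["testing"] == "alone"], endpoint
            )
        if activity is not None and not activity.empty:
            merged = activity.merge(
                summaries[
                    ["fish_id", "testing", "co2_uatm", "mass_g"]
                ].drop_duplicates(),
                on=["fish_id", "testing"],
            )
            out["activity"] = inference.metabolic_mixed_model(
                merged, "turns_per_min"
            )
    return out


def process_cohort(dataset: CohortDataset, with_inference: bool = True) -> CohortResults:
    """Process one simulated cohort through every analysis stage."""
    summaries, calming = summarize_physiology(dataset)
    choice_results, retest_log = score_choice_trials(dataset)
    results = CohortResults(
        summaries=summaries,
        calming=calming,
        choice_results=choice_results,
        retest_log=retest_log,
    )
    if with_inference:
        results.inference = run_inference(
            summaries, choice_results, dataset.activity
        )
    n_flagged = int((~choice_results["informed"]).sum())
    log.info(
        "cohort processed: %d summaries, %d calming pairs, %d choice trials "
        "(%d uninformed in final attempts), %d retests",
        len(summaries), len(calming), len(choice_results), n_flagged,
        len(retest_log),
    )
    return results


def mass_corrected_table(summaries: pd.DataFrame, reference_mass: float = 1.29) -> pd.DataFrame:
    """Presentation-layer mass correction of every metabolic endpoint."""
    out = summaries.copy()
    for endpoint in ("mr_min", "rmr", "mmr", "fs", "aerobic_scope"):
        vals = out[endpoint].to_numpy(float)
        mask = np.isfinite(vals) & (vals > 0)
        corrected = np.full_like(vals, np.nan)
        if mask.sum() >= 3:
            corrected[mask] = metabolism.mass_correct(
                vals[mask], out.loc[mask, "mass_g"].to_numpy(float),
                reference_mass=reference_mass,
            )
        out[f"{endpoint}_mass_corrected"] = corrected
    return out
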