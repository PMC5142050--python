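"""Shared I/O: CSV dialects, the run manifest, and the pipeline entry point.

CSV dialect everywhere: comma-separated, UTF-8, mandatory header row, '.'
decimal separator, units encoded in column names (time_s, o2_mg_l, x_cm ...).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .respirometry import OxygenTrace
from .behavior import Trajectory

log = logging.getLogger(__name__)

TRACE_COLUMNS = ["time_s", "o2_mg_l"]
TRAJECTORY_COLUMNS = ["time_s", "x_cm", "y_cm"]


class FormatError(ValueError):
    pass


def read_trace_csv(path: str | Path, sample_interval: float = 2.0) -> OxygenTrace:
    """Read an oxygen trace (columns time_s, o2_mg_l); non-monotone or
    duplicated timestamps raise with the offending row numbers."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = df[TRACE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    nan_rows = bad.isna().any(axis=1)
    if nan_rows.any():
        rows = (np.flatnonzero(nan_rows) + 2).tolist()  # 1-based incl. header
        raise FormatError(f"{path}: unparseable values at rows {rows[:10]}")
    t = bad["time_s"].to_numpy(float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        rows = (np.flatnonzero(dt <= 0) + 3).tolist()
        raise FormatError(
            f"{path}: time not strictly increasing at rows {rows[:10]}"
        )
    return OxygenTrace(t, bad["o2_mg_l"].to_numpy(float), sample_interval)


def write_trace_csv(trace: OxygenTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "o2_mg_l": trace.o2}).to_csv(
        path, index=False
    )


def read_trajectory_csv(path: str | Path, familiar_side: str = "left") -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return Trajectory(
        df["time_s"].to_numpy(float),
        df["x_cm"].to_numpy(float),
        df["y_cm"].to_numpy(float),
        familiar_side=familiar_side,  # type: ignore[arg-type]
    )


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": traj.time, "x_cm": traj.x, "y_cm": traj.y}
    ).to_csv(path, index=False)


@dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    command: str
    config_hash: str
    input_digests: dict
    package_version: str
    seed: Optional[int]
    started_utc: str
    finished_utc: Optional[str] = None

    @staticmethod
    def digest(path: str | Path) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()[:16]

    @classmethod
    def start(cls, command: str, config, seed: Optional[int],
              inputs: Optional[dict] = None) -> "RunManifest":
        from . import __version__

        if dataclasses.is_dataclass(config):
            blob = json.dumps(
                {f.name: repr(getattr(config, f.name))
                 for f in dataclasses.fields(config)},
                sort_keys=True,
            )
        else:
            blob = json.dumps(config, sort_keys=True, default=repr)
        return cls(
            command=command,
            config_hash=hashlib.sha256(blob.encode()).hexdigest()[:16],
            input_digests=inputs or {},
            package_version=__version__,
            seed=seed,
            started_utc=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, out_dir: str | Path) -> Path:
        self.finished_utc = datetime.now(timezone.utc).isoformat()
        out = Path(out_dir) / "manifest.json"
        if out.exists():
            raise FileExistsError(
                f"{out} already exists; outputs are write-once per run directory"
            )
        out.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return out


def run_pipeline(config, out_dir: str | Path, with_trajectories: bool = True) -> Path:
    """Simulate a cohort, run every analysis stage, and write the output
    tables plus a manifest.  Deterministic for a fixed config."""
    from .pipeline import mass_corrected_table, process_cohort
    from .simulate import simulate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest.start("run_pipeline", config, config.seed)

    dataset = simulate_cohort(config, emit_trajectories=with_trajectories)
    results = process_cohort(dataset)

    dataset.fish.to_csv(out_dir / "fish.csv", index=False)
    dataset.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    results.summaries.to_csv(out_dir / "summaries.csv", index=False)
    mass_corrected_table(results.summaries).to_csv(
        out_dir / "summaries_mass_corrected.csv", index=False
    )
    results.calming.to_csv(out_dir / "calming.csv", index=False)
    results.choice_results.to_csv(out_dir / "choice_results.csv", index=False)
    results.retest_log.to_csv(out_dir / "retest_log.csv", index=False)

    rows = []
    for name, res in results.inference.items():
        if isinstance(res, dict):  # per-treatment preference tests
            for co2, sub in res.items():
                t = sub.table.copy()
                t.insert(0, "model", f"{name}_{co2}")
                rows.append(t)
        elif isinstance(res, pd.DataFrame):
            t = res.copy()
            t.insert(0, "model", name)
            rows.append(t)
        else:
            t = res.table.copy()
            t.insert(0, "model", name)
            rows.append(t)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            out_dir / "inference.csv", index=False
        )
    manifest.write(out_dir)
    log.info("pipeline outputs written to %s", out_dir)
    return out_dir
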