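"""Structured input/output: tidy trajectory CSVs, run summaries, configs.

The CSV contract is long/tidy: one row per (time, follicle) with columns
time, follicle_id, size, relative_size, phase.  Floats are written at
17 significant digits so runs with the same seed produce byte-identical
files.  A JSON run summary (parameters, seed, surge time, outcome) is
written next to the CSV.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .core import BiphasicParams
from .simulate import OvulationOutcome, SimulationConfig, Trajectory

__all__ = [
    "trajectory_to_frame",
    "write_trajectory",
    "read_trajectory_frame",
    "run_summary",
    "config_to_yaml",
    "config_from_yaml",
]

_FLOAT_FMT = "%.17g"


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format view of a trajectory."""
    n_t, n_f = traj.sizes.shape
    phase = traj.phase_matrix()
    rel = traj.sizes / traj.total_size[:, None]
    return pd.DataFrame(
        {
            "time": traj.times.repeat(n_f),
            "follicle_id": list(range(n_f)) * n_t,
            "size": traj.sizes.ravel(),
            "relative_size": rel.ravel(),
            "phase": [
                "competing" if p else "pre-competition" for p in phase.ravel()
            ],
        }
    )


def write_trajectory(
    traj: Trajectory,
    path,
    outcome: Optional[OvulationOutcome] = None,
) -> Path:
    """Write the tidy CSV plus a sibling ``.summary.json`` run summary."""
    if traj.sizes.size == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    frame = trajectory_to_frame(traj)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    summary = run_summary(traj, outcome)
    path.with_suffix(".summary.json").write_text(json.dumps(summary, indent=2))
    return path


def read_trajectory_frame(path) -> pd.DataFrame:
    # round_trip parser so the 17-digit floats come back bit-exact
    return pd.read_csv(path, float_precision="round_trip")


def run_summary(traj: Trajectory, outcome: Optional[OvulationOutcome] = None) -> dict:
    """Everything needed to reproduce the run with the same build."""
    s = {
        "software_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": traj.config.seed,
        "params": traj.params.to_dict(),
        "config": traj.config.to_dict(),
        "surge_time": traj.surge_time,
        "t_end": float(traj.times[-1]),
        "final_total_size": float(traj.total_size[-1]),
    }
    if outcome is not None:
        s["ovulating_indices"] = sorted(outcome.ovulating_indices)
        s["ovulation_count"] = outcome.count
        s["classification_rule"] = outcome.classification_rule
    return s


def config_to_yaml(params: BiphasicParams, config: SimulationConfig) -> str:
    return yaml.safe_dump(
        {"params": params.to_dict(), "config": config.to_dict()},
        sort_keys=True,
    )


def config_from_yaml(text: str):
    """Parse a YAML/JSON config document into (BiphasicParams, SimulationConfig)."""
    doc = yaml.safe_load(text)
    params = BiphasicParams(**doc["params"])
    cfg = dict(doc.get("config", {}))
    if cfg.get("explicit_initial_sizes") is not None:
        cfg["explicit_initial_sizes"] = tuple(cfg["explicit_initial_sizes"])
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(cfg) - fields
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return params, SimulationConfig(**cfg)
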