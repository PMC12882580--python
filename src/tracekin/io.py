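"""File schemas and dataset round-tripping (plain delimited text).

A dataset directory holds four UTF-8 CSV files plus a JSON manifest:

* ``trajectories.csv`` — one row per stylus sample: participant_id, group,
  day, block, shape, trial, attempt, success, t_s, x_px, y_px
* ``covariates.csv`` — one row per participant: demographics and
  questionnaire scores
* ``reaction_times.csv`` — one row per reaction-time trial
* ``schedule.csv`` — the block/attempt schedule with success flags
* ``manifest.json`` — seed, effective config and per-file checksums
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .cohort import CohortConfig, CohortDataset
from .preprocessing import RawTrajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "write_dataset",
    "read_dataset",
    "iter_trials",
    "validate_schema",
    "file_checksum",
]

TRAJECTORY_COLUMNS = {
    "participant_id": "string",
    "group": "string",
    "day": "integer",
    "block": "integer",
    "shape": "string",
    "trial": "integer",
    "attempt": "integer",
    "success": "boolean",
    "t_s": "float",
    "x_px": "float",
    "y_px": "float",
}

_FILES = ("trajectories.csv", "covariates.csv", "reaction_times.csv", "schedule.csv")


def file_checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_dataset(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write the dataset CSVs and a manifest with seed and checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = {
        "trajectories.csv": dataset.trajectories,
        "covariates.csv": dataset.covariates,
        "reaction_times.csv": dataset.reaction_times,
        "schedule.csv": dataset.schedule,
    }
    for name, df in frames.items():
        df.to_csv(out / name, index=False)
    manifest = {
        "seed": dataset.config.seed,
        "n_participants": int(dataset.covariates["participant"].nunique()),
        "config": dataclasses.asdict(dataset.config),
        "checksums": {name: file_checksum(out / name) for name in frames},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def read_dataset(in_dir: str | Path) -> CohortDataset:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg_dict = manifest["config"]
    for key in ("n_per_group", "shapes"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    config = CohortConfig(**cfg_dict)
    return CohortDataset(
        trajectories=pd.read_csv(src / "trajectories.csv"),
        covariates=pd.read_csv(src / "covariates.csv"),
        reaction_times=pd.read_csv(src / "reaction_times.csv"),
        schedule=pd.read_csv(src / "schedule.csv"),
        config=config,
    )


def iter_trials(trajectories: pd.DataFrame) -> Iterator[RawTrajectory]:
    """Yield one RawTrajectory per (participant, day, block, attempt)."""
    keys = ["participant_id", "day", "block", "shape", "trial", "attempt"]
    for (pid, day, block, shape, trial, attempt), g in trajectories.groupby(keys, sort=True):
        yield RawTrajectory(
            participant=str(pid),
            group=str(g["group"].iloc[0]),
            day=int(day),
            block=int(block),
            shape=str(shape),
            trial=int(trial),
            attempt=int(attempt),
            t=g["t_s"].to_numpy(),
            x=g["x_px"].to_numpy(),
            y=g["y_px"].to_numpy(),
            success=bool(g["success"].iloc[0]),
        )


def validate_schema(path: str | Path) -> dict:
    """Column presence/type/monotonicity checks on a trajectory file.

    Column order is irrelevant.  Returns a report dict; never raises on
    content problems (``ok`` is False with the first offending row noted).
    """
    path = Path(path)
    report: dict = {"path": str(path), "ok": True, "errors": []}
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col, kind in TRAJECTORY_COLUMNS.items():
        if col not in df.columns:
            report["ok"] = False
            report["errors"].append({"error": "missing_column", "column": col})
            continue
        if kind in ("float", "integer") and not np.issubdtype(df[col].dtype, np.number):
            report["ok"] = False
            report["errors"].append({"error": "non_numeric", "column": col})
    if report["ok"]:
        keys = ["participant_id", "day", "block", "attempt"]
        for key, g in df.groupby(keys):
            dt = np.diff(g["t_s"].to_numpy())
            bad = np.nonzero(dt < 0)[0]
            if len(bad):
                report["ok"] = False
                report["errors"].append(
                    {
                        "error": "non_monotone_t",
                        "trial": dict(zip(keys, key)),
                        "row": int(g.index[bad[0] + 1]),
                    }
                )
                break
    return report
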