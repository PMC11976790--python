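"""Structured output: HDF5 trajectories, CSV metrics, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .engine import TrajectoryRecord

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "trajectory_to_csv",
    "write_metrics",
    "load_config",
    "save_config",
]


def save_trajectory(path: str | Path, record: TrajectoryRecord) -> None:
    """Write a trajectory to HDF5.

    Layout: /positions [S+1, N, d], /directors, /unwrapped, /types, /ids,
    /time, optional /rewards; the full run configuration and seed are stored
    as root attributes.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=record.positions)
        f.create_dataset("directors", data=record.directors)
        f.create_dataset("unwrapped", data=record.unwrapped)
        f.create_dataset("time", data=record.times)
        f.create_dataset("ids", data=record.ids)
        f.create_dataset("types", data=record.types)
        if record.rewards is not None:
            f.create_dataset("rewards", data=record.rewards)
        f.attrs["config"] = record.config_json()
        if record.seed is not None:
            f.attrs["seed"] = record.seed


def load_trajectory(path: str | Path) -> TrajectoryRecord:
    with h5py.File(path, "r") as f:
        return TrajectoryRecord(
            positions=f["positions"][...],
            directors=f["directors"][...],
            unwrapped=f["unwrapped"][...],
            times=f["time"][...],
            ids=f["ids"][...],
            types=f["types"][...],
            config=json.loads(f.attrs.get("config", "{}")),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            rewards=f["rewards"][...] if "rewards" in f else None,
        )


def trajectory_to_csv(path: str | Path, record: TrajectoryRecord) -> None:
    """Flat long-format export: one row per (slice, particle)."""
    s1, n, d = record.positions.shape
    rows = {
        "time": np.repeat(record.times, n),
        "id": np.tile(record.ids, s1),
        "type": np.tile(record.types, s1),
    }
    for k in range(d):
        rows[f"x{k}"] = record.positions[:, :, k].reshape(-1)
        rows[f"e{k}"] = record.directors[:, :, k].reshape(-1)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metrics(path: str | Path, metrics: list[dict]) -> None:
    """Training metrics, one row per update (CSV or JSON-lines by suffix)."""
    path = Path(path)
    df = pd.DataFrame(metrics)
    if path.suffix in (".jsonl", ".json"):
        df.to_json(path, orient="records", lines=True)
    else:
        df.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError("config document must be a mapping")
    return cfg


def save_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
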