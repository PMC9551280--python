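"""Configuration files, result tables and reproducibility bookkeeping.

Configs are flat YAML mappings whose keys are exactly the ``ModelParams``
field names; missing keys fall back to the baseline defaults and the MIC
calibration (mu, sigma) is solved at load time unless given explicitly.
Outputs are plain CSV/JSON: ``trajectory.csv`` (long-format snapshots),
``events.csv`` (microhabitat additions), ``summary.json`` (establishment
outcome) and ``manifest.json`` (config fingerprint, seeds, file
inventory; written last so its presence signals a complete run).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import Trajectory
from .model import ModelParams

__all__ = [
    "load_config",
    "params_fingerprint",
    "dump_config",
    "write_outputs",
    "read_trajectory",
    "RunManifest",
]


def load_config(path) -> ModelParams:
    """Read a flat YAML config into a validated ``ModelParams``.

    Unknown keys are rejected with the offending key names; all validation
    errors carry the configuration context.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of parameter: value")
    try:
        return ModelParams.create(**data)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid config {path}: {err}") from err


def dump_config(params: ModelParams) -> str:
    """Canonical YAML rendering (sorted keys) of a parameter set."""
    return yaml.safe_dump(_canonical_dict(params), sort_keys=True)


def _canonical_dict(params: ModelParams) -> dict:
    out = {}
    for key, val in sorted(params.to_dict().items()):
        if isinstance(val, (np.floating, np.integer)):
            val = val.item()
        out[key] = val
    return out


def params_fingerprint(params: ModelParams) -> str:
    """Stable hash of the canonicalized configuration."""
    blob = json.dumps(_canonical_dict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    fingerprint: str
    version: str
    seed: int
    timestamp: str
    files: list[str]

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)
        return path


def _trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    rows = {
        "time_h": [],
        "habitat": [],
        "ecotype_id": [],
        "mic_ppm": [],
        "count": [],
    }
    for snap in traj.snapshots:
        k = len(snap.count)
        rows["time_h"].append(np.full(k, snap.t))
        rows["habitat"].append(snap.habitat)
        rows["ecotype_id"].append(snap.ecotype_id)
        rows["mic_ppm"].append(snap.mic)
        rows["count"].append(snap.count)
    if rows["time_h"]:
        data = {k: np.concatenate(v) for k, v in rows.items()}
    else:
        data = {k: [] for k in rows}
    return pd.DataFrame(data)


def write_outputs(traj: Trajectory, out_dir) -> RunManifest:
    """Write trajectory.csv, events.csv, summary.json and the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []

    tpath = out_dir / "trajectory.csv"
    _trajectory_frame(traj).to_csv(tpath, index=False)
    files.append(tpath.name)

    epath = out_dir / "events.csv"
    pd.DataFrame(
        {
            "event": ["microhabitat_added"] * len(traj.addition_times),
            "time_h": traj.addition_times,
        }
    ).to_csv(epath, index=False)
    files.append(epath.name)

    est = traj.establishment_time
    summary = {
        "establishment_time_h": None if est is None else float(est),
        "censored": traj.censored,
        "end_reason": traj.end_reason.value if traj.end_reason else None,
        "end_time_h": float(traj.end_time),
        "final_L": int(traj.final_L),
        "seed": int(traj.seed),
        "replicate": int(traj.replicate),
        "params_fingerprint": params_fingerprint(traj.params),
    }
    spath = out_dir / "summary.json"
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=2)
    files.append(spath.name)

    cpath = out_dir / "config.yaml"
    with open(cpath, "w") as fh:
        fh.write(dump_config(traj.params))
    files.append(cpath.name)

    manifest = RunManifest(
        fingerprint=params_fingerprint(traj.params),
        version=__version__,
        seed=int(traj.seed),
        timestamp=datetime.now(timezone.utc).isoformat(),
        files=files,
    )
    manifest.write(out_dir)
    return manifest


def read_trajectory(run_dir) -> tuple[pd.DataFrame, dict]:
    """Read back a written run: (trajectory table, summary dict)."""
    run_dir = Path(run_dir)
    table = pd.read_csv(run_dir / "trajectory.csv")
    with open(run_dir / "summary.json") as fh:
        summary = json.load(fh)
    return table, summary
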