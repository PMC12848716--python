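"""Delimited-text I/O for trajectories, feature tables and reports.

Trajectory files are CSV with a mandatory header and one row per frame:
``traj_id,frame,t,x,y,z,label`` (times in seconds, coordinates in
micrometres).  The label column may be absent for external tracking data;
such trajectories are loaded with labels marked ``unknown`` — prediction
works on them but evaluation does not.  Feature tables round-trip through
CSV with the canonical column order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_NAMES
from .simulate import InvalidParameterError, SimulationConfig, Trajectory3D

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_features",
    "write_features",
    "read_config",
    "write_config",
    "write_report",
]

TRAJ_COLUMNS = ("traj_id", "frame", "t", "x", "y", "z", "label")
FLOAT_FMT = "%.12g"


def write_trajectories(trajs: Iterable[Trajectory3D], path: str | Path) -> None:
    """Write trajectories as delimited text, one row per frame."""
    frames = []
    for traj in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "traj_id": traj.id,
                    "frame": np.arange(traj.n_frames),
                    "t": traj.t,
                    "x": traj.pos[:, 0],
                    "y": traj.pos[:, 1],
                    "z": traj.pos[:, 2],
                    "label": traj.labels,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRAJ_COLUMNS)
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trajectories(path: str | Path) -> list[Trajectory3D]:
    """Read a trajectory file, validating schema and time monotonicity.

    Raises a schema error naming any missing required column; a label
    column is optional (missing labels become ``unknown``).
    """
    table = pd.read_csv(path)
    required = [c for c in TRAJ_COLUMNS if c != "label"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing required column(s) {missing}")
    has_label = "label" in table.columns
    out: list[Trajectory3D] = []
    for traj_id, grp in table.groupby("traj_id", sort=False):
        grp = grp.sort_values("frame")
        t = grp["t"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.nonzero(np.diff(t) <= 0)[0][0])
            line = int(grp.index[bad + 1]) + 2  # +2: header and 0-based index
            raise InvalidParameterError(
                f"{path}: non-monotone time for trajectory {traj_id!r} at line {line}"
            )
        labels = (
            grp["label"].to_numpy(dtype=object)
            if has_label
            else np.full(len(grp), "unknown", dtype=object)
        )
        pos = grp[["x", "y", "z"]].to_numpy(dtype=float)
        out.append(
            Trajectory3D(
                str(traj_id), t, pos, labels,
                motion_class="unknown" if not has_label else "",
            )
        )
    return out


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_features(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing feature column(s) {missing}")
    if "center_label" not in table.columns:
        raise InvalidParameterError(f"{path}: missing center_label column")
    return table


def read_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML mapping of field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidParameterError(f"{path}: unknown config field(s) {sorted(unknown)}")
    for key in ("D_range", "coef_range", "alpha_range", "B_range", "mm_segment_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    for key, val in data.items():
        if isinstance(val, tuple):
            data[key] = list(val)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Write a structured evaluation/run report as JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
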