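"""File formats: trajectory / button / questionnaire / sync-time CSV,
flat key-value config files, and run manifests.

All angles are serialised in radians and all lengths in metres.
Trajectory files carry the header ``t,side,x,y,z`` with time in seconds
printed to 6 decimals; one file per player hand per trial.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .core_model import HandTrajectory, ModelConfig
from .errors import TrajectoryFormatError

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_button",
    "write_button",
    "read_config",
    "write_config",
    "RunManifest",
]

_TRAJ_COLUMNS = ["t", "side", "x", "y", "z"]


def write_trajectory(traj: HandTrajectory, path) -> None:
    """Write one hand trajectory as CSV (``t,side,x,y,z``, 6 decimals)."""
    df = pd.DataFrame(
        {
            "t": traj.times,
            "side": traj.side,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "z": traj.positions[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trajectory(path) -> HandTrajectory:
    """Read a trajectory CSV; validates header, monotone uniform grid."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError(f"{path}: empty trajectory file")
    if list(df.columns) != _TRAJ_COLUMNS:
        raise TrajectoryFormatError(
            f"{path}: expected header {','.join(_TRAJ_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if len(df) == 0:
        raise TrajectoryFormatError(f"{path}: no samples")
    sides = df["side"].unique()
    if len(sides) != 1:
        raise TrajectoryFormatError(
            f"{path}: mixed sides {sorted(sides)} in one file"
        )
    t = df["t"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TrajectoryFormatError(
            f"{path}: non-monotone time at t={t[bad[0] + 1]:.6f}"
        )
    if len(t) >= 3 and np.ptp(np.diff(t)) > 1e-6:
        raise TrajectoryFormatError(f"{path}: non-uniform sampling grid")
    pos = df[["x", "y", "z"]].to_numpy(float)
    try:
        return HandTrajectory(str(sides[0]), t, pos)
    except ValueError as exc:
        raise TrajectoryFormatError(f"{path}: {exc}") from exc


def write_button(times: np.ndarray, pressed: np.ndarray, path) -> None:
    """Write a button stream CSV (``t,pressed`` with pressed in {0,1})."""
    pd.DataFrame(
        {"t": times, "pressed": np.asarray(pressed, dtype=int)}
    ).to_csv(path, index=False, float_format="%.6f")


def read_button(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError(f"{path}: empty button file")
    if list(df.columns) != ["t", "pressed"]:
        raise TrajectoryFormatError(f"{path}: expected header t,pressed")
    if not df["pressed"].isin([0, 1]).all():
        raise TrajectoryFormatError(f"{path}: pressed must be 0 or 1")
    return df


_CONFIG_KEYS = (
    "k_inter", "k_intra", "noise_amplitude", "sample_rate",
    "plane_offset", "partner_distance", "duration",
)


def read_config(path) -> Dict:
    """Read a flat key-value (YAML) config; returns a plain dict.

    Recognised keys are the ModelConfig fields plus ``seed``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise TrajectoryFormatError(f"{path}: config must be key-value pairs")
    unknown = set(data) - set(_CONFIG_KEYS) - {"seed"}
    if unknown:
        raise TrajectoryFormatError(
            f"{path}: unknown config keys {sorted(unknown)}"
        )
    return data


def write_config(config: ModelConfig, path, seed: Optional[int] = None) -> None:
    data = {k: getattr(config, k) for k in _CONFIG_KEYS}
    if seed is not None:
        data["seed"] = seed
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_mapping(data: Dict) -> ModelConfig:
    kwargs = {k: float(v) for k, v in data.items() if k in _CONFIG_KEYS}
    return ModelConfig(**kwargs)


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to reproduce its outputs."""

    command: str
    seed: Optional[int]
    config: Dict
    inputs: List[str] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""
    notes: Dict = field(default_factory=dict)

    def write(self, path) -> None:
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()
        if not self.version:
            from . import __version__

            self.version = __version__
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @staticmethod
    def read(path) -> "RunManifest":
        with open(path) as fh:
            return RunManifest(**json.load(fh))
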