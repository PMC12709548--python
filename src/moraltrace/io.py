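"""Delimited-text serialization for trial tables, trajectories and matrices.

All files are UTF-8, comma-delimited, with a header row; floats are
written with a fixed repr so that re-running a stage with the same seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mouse import Trajectory

__all__ = [
    "TRIAL_COLUMNS", "write_trials", "read_trials",
    "write_trajectories", "read_trajectories",
    "write_matrix", "read_matrix",
]

TRIAL_COLUMNS = ["subject", "run", "question", "reward_correct",
                 "reward_incorrect", "correct_side", "cr_correct",
                 "cr_incorrect", "history", "islie", "rt", "timeout"]


def write_trials(trials: pd.DataFrame, path) -> None:
    df = trials.copy()
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table lacks columns: {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    df[TRIAL_COLUMNS + extra].to_csv(path, index=False, float_format="%.10g")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timeout"] = df["timeout"].astype(bool)
    return df


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    """Long format: trial_uid, t, x, y (one row per sample)."""
    frames = []
    for k, traj in enumerate(trajectories):
        uid = traj.trial_uid if traj.trial_uid is not None else f"trial{k:05d}"
        frames.append(pd.DataFrame(
            {"trial_uid": uid, "t": traj.t, "x": traj.x, "y": traj.y}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")


def read_trajectories(path, standardized: bool = True) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for uid, grp in df.groupby("trial_uid", sort=False):
        out.append(Trajectory(t=grp["t"].to_numpy(),
                              x=grp["x"].to_numpy(),
                              y=grp["y"].to_numpy(),
                              standardized=standardized,
                              trial_uid=str(uid)))
    return out


def write_matrix(matrix: np.ndarray, path, labels: list[str] | None = None) -> None:
    """Square or rectangular matrix with a label header/sidecar column."""
    arr = np.asarray(matrix)
    if labels is None:
        labels = [f"r{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=labels)
    df.to_csv(path, index=True, header=True, float_format="%.10g")


def read_matrix(path):
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), list(df.index)
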