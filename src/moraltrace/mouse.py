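"""Mouse-trajectory standardization and the conflict metric AUC.

A trajectory is the cursor path recorded while a participant moves from a
start button at the bottom-centre of the screen to one of two response
options in the top corners.  Preprocessing follows the standard
mouse-tracking recipe: rescale to a coordinate space with the start at
(0, 0) and the top corners at (-1, 1) / (+1, 1); flip right-ending paths to
the left so that spatial direction is irrelevant; linearly interpolate onto
101 equally spaced time bins so trials of different duration can be
averaged.  The conflict metric is the signed geometric area (AUC) between
the path and the ideal straight start-to-end line: excursions toward the
non-chosen option count positive, overshoot on the chosen side negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Trajectory",
    "rescale",
    "remap_left",
    "time_normalize",
    "compute_auc",
    "x_velocity",
    "TrajectoryNormalizer",
]


@dataclass(frozen=True)
class Trajectory:
    """Ordered (t, x, y) cursor samples.

    ``standardized`` marks that coordinates live in the standard space
    (start at the origin, top corners at (+-1, 1)).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    standardized: bool = False
    trial_uid: str | None = field(default=None, compare=False)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def end_side(self) -> str:
        return "right" if self.x[-1] > 0 else "left"


def rescale(
    t: np.ndarray,
    x_px: np.ndarray,
    y_px: np.ndarray,
    *,
    screen_width: float,
    screen_height: float,
    start_px: tuple[float, float],
    trial_uid: str | None = None,
) -> Trajectory:
    """Map raw pixel samples into the standard coordinate space.

    The start point maps to (0, 0) and the screen's top corners to
    (-1, 1) and (+1, 1).  The map is affine and axis-aligned; pixel y is
    assumed to increase downward (screen convention), so the screen top
    (pixel y = 0) maps to standardized y = 1.
    """
    if screen_width <= 0 or screen_height <= 0:
        raise ValueError("screen dimensions must be positive")
    sx, sy = start_px
    if not (0 <= sx <= screen_width and 0 <= sy <= screen_height):
        raise ValueError("start point must lie inside the screen")
    x_px = np.asarray(x_px, dtype=float)
    y_px = np.asarray(y_px, dtype=float)
    # Horizontal: start -> 0, screen edges -> +-1 (half-width is the unit).
    x = (x_px - sx) / (screen_width / 2.0)
    # Vertical: start -> 0, screen top (pixel 0) -> 1.
    if sy == 0:
        raise ValueError("start point must not sit on the screen top edge")
    y = (sy - y_px) / sy
    return Trajectory(t=np.asarray(t, float), x=x, y=y, standardized=True,
                      trial_uid=trial_uid)


def remap_left(traj: Trajectory) -> Trajectory:
    """Flip a right-ending trajectory to the left; idempotent."""
    if not traj.standardized:
        raise ValueError("remap_left requires a standardized trajectory")
    if traj.end_side == "left":
        return traj
    return replace(traj, x=-traj.x)


def time_normalize(traj: Trajectory, n_bins: int = 101) -> Trajectory:
    """Resample onto ``n_bins`` equally spaced times by linear interpolation.

    Endpoints are preserved exactly; interior samples are interpolated on
    the original piecewise-linear path.
    """
    if traj.n_samples < 2:
        raise ValueError("time normalization needs at least 2 samples")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    tt = np.linspace(traj.t[0], traj.t[-1], n_bins)
    x = np.interp(tt, traj.t, traj.x)
    y = np.interp(tt, traj.t, traj.y)
    # exact endpoints, immune to float round-off in linspace
    x[0], y[0] = traj.x[0], traj.y[0]
    x[-1], y[-1] = traj.x[-1], traj.y[-1]
    return replace(traj, t=tt, x=x, y=y)


def compute_auc(traj: Trajectory, *, signed: bool = True) -> float:
    """Signed area between the path and the straight start-to-end segment.

    The polygon formed by the trajectory plus the closing segment back to
    the start is integrated with the shoelace formula.  The sign convention
    puts excursions toward the non-chosen side positive and overshoot
    beyond the direct path on the chosen side negative; self-intersecting
    paths contribute algebraically.  The value is mirror-symmetric: a path
    and its left/right reflection give the same AUC.
    """
    if not traj.standardized:
        raise ValueError("compute_auc requires a standardized trajectory")
    if traj.n_samples < 2:
        raise ValueError("compute_auc needs at least 2 samples")
    x, y = traj.x, traj.y
    if x[-1] > 0:  # mirror right-enders so the sign rule is side-invariant
        x = -x
    # shoelace over the closed polygon (trajectory + closing edge)
    area = 0.5 * float(
        np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    )
    return area if signed else abs(area)


def x_velocity(traj: Trajectory) -> np.ndarray:
    """Per-bin horizontal velocity: first differences of x over bin duration.

    Intended for time-normalized trajectories (uniform bins); returns one
    value per inter-sample interval.
    """
    if traj.n_samples < 2:
        raise ValueError("x_velocity needs at least 2 samples")
    dt = np.diff(traj.t)
    if traj.t[-1] - traj.t[0] <= 0:
        raise ValueError("zero total duration")
    return np.diff(traj.x) / dt


class TrajectoryNormalizer:
    """Transformer applying the full standardization chain to trajectories.

    Parameters
    ----------
    n_bins : number of time bins after temporal normalization (101 by
        default, the convention for averaging across trials).
    remap : flip right-ending trajectories to the left.
    signed_auc : sign convention for the AUC column produced by
        :meth:`metrics`.
    """

    def __init__(self, n_bins: int = 101, remap: bool = True,
                 signed_auc: bool = True):
        self.n_bins = n_bins
        self.remap = remap
        self.signed_auc = signed_auc

    # --- sklearn-style surface -------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"n_bins": self.n_bins, "remap": self.remap,
                "signed_auc": self.signed_auc}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):  # stateless; kept for pipeline compatibility
        return self

    def transform(self, X: list[Trajectory]) -> list[Trajectory]:
        out = []
        for traj in X:
            if not traj.standardized:
                raise ValueError("inputs must be standardized (use rescale)")
            if self.remap:
                traj = remap_left(traj)
            out.append(time_normalize(traj, self.n_bins))
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def metrics(self, X: list[Trajectory]) -> "pd.DataFrame":
        """AUC and peak |x-velocity| per trajectory, one row per trial."""
        import pandas as pd

        rows = []
        for traj in self.transform(X):
            vel = x_velocity(traj)
            rows.append({
                "trial_uid": traj.trial_uid,
                "auc": compute_auc(traj, signed=self.signed_auc),
                "peak_xvel": float(np.max(np.abs(vel))),
            })
        return pd.DataFrame(rows)
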