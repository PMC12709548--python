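"""Synthetic cursor trajectories whose curvature tracks decision conflict.

This is fixture machinery, not a cognitive model: a damped-attractor
polyline runs from the start (0, 0) to the chosen top corner (+-1, 1) with
a smooth pull toward the unchosen side whose magnitude scales with the
supplied conflict scalar, plus small endpoint-pinned noise.  Its only
contract is that the downstream AUC increases with conflict in
expectation and is exactly 0 for a straight, noise-free path.
"""

from __future__ import annotations

import numpy as np

from .._utils import substream
from ..mouse import Trajectory

__all__ = ["simulate_trajectory"]


def simulate_trajectory(boundary: str, rt: float, conflict: float,
                        n_samples: int = 60, noise: float = 0.03,
                        seed: int = 0, trial_uid: str | None = None) -> Trajectory:
    """One standardized trajectory ending at the chosen corner.

    ``boundary`` "upper" ends at the right corner (+1, 1) — the dishonest
    option — and "lower" at the left corner (-1, 1); y increases
    monotonically from 0 to 1 over ``rt`` seconds.
    """
    if rt <= 0:
        raise ValueError("rt must be positive")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if conflict < 0:
        raise ValueError("conflict must be non-negative")
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    rng = substream(seed, "trajectories")
    x_end = 1.0 if boundary == "upper" else -1.0
    tau = np.linspace(0.0, 1.0, n_samples)
    # straight path plus a half-sine pull toward the unchosen side
    pull = 0.35 * conflict * np.sin(np.pi * tau)
    x = x_end * tau - x_end * pull
    y = tau.copy()
    if noise > 0:
        # smooth, endpoint-pinned wiggle
        raw = rng.standard_normal(n_samples)
        kernel = np.ones(7) / 7.0
        smooth = np.convolve(raw, kernel, mode="same")
        x = x + noise * smooth * np.sin(np.pi * tau)
    t = tau * rt
    return Trajectory(t=t, x=x, y=y, standardized=True, trial_uid=trial_uid)
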