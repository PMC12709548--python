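"""First-passage-time density of the Wiener diffusion with two boundaries.

The accumulator starts at z*a between a lower boundary at 0 and an upper
boundary at a, drifts at rate v with unit diffusion, and the density of
absorption times at either boundary is evaluated with the classic pair of
series expansions (an infinite sum over image charges for small times, a
spectral sine series for large times), switching to whichever needs fewer
terms at the requested precision.  The upper boundary codes the dishonest
choice throughout the package.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["wiener_logpdf", "wiener_density", "absorption_upper"]

_EPS = 1e-7


@njit(cache=True)
def _f_lower_norm(tt: float, w: float) -> float:
    """Driftless density at the lower bound, unit boundary, normalized time."""
    if tt <= 0.0:
        return 0.0
    # number of terms each series needs for error < _EPS (Navarro-Fuss bounds)
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * _EPS < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * _EPS * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    if math.pi * tt * _EPS < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * _EPS) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        s = 0.0
        for k in range(-((K - 1) // 2), ((K - 1) // 2) + 1):
            u = w + 2.0 * k
            s += u * math.exp(-u * u / (2.0 * tt))
        return s / math.sqrt(2.0 * math.pi * tt ** 3)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        s = 0.0
        for k in range(1, K + 1):
            s += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        return math.pi * s


@njit(cache=True)
def wiener_logpdf(t: float, upper: bool, v: float, a: float, z: float,
                  t0: float) -> float:
    """Log first-passage density at the stated boundary; -inf below t0."""
    td = t - t0
    if td <= 0.0 or a <= 0.0 or z <= 0.0 or z >= 1.0:
        return -np.inf
    if upper:
        vv, w = -v, 1.0 - z
    else:
        vv, w = v, z
    tt = td / (a * a)
    f0 = _f_lower_norm(tt, w)
    if f0 <= 0.0:
        return -np.inf
    return math.log(f0) - math.log(a * a) - vv * a * w - vv * vv * td / 2.0


def wiener_density(t, boundary: str, v: float, a: float, z: float,
                   t0: float = 0.0):
    """First-passage density (per second) at the upper or lower boundary.

    Vectorized over ``t``; zero density for t <= t0.
    """
    if a <= 0:
        raise ValueError("threshold a must be positive")
    if not 0 < z < 1:
        raise ValueError("relative start point z must lie in (0, 1)")
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    up = boundary == "upper"
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i in range(t_arr.size):
        lp = wiener_logpdf(t_arr[i], up, v, a, z, t0)
        out[i] = 0.0 if lp == -np.inf else math.exp(lp)
    return out if np.ndim(t) else float(out[0])


def absorption_upper(v: float, a: float, z: float) -> float:
    """Probability the accumulator is absorbed at the upper boundary."""
    if a <= 0 or not 0 < z < 1:
        raise ValueError("require a > 0 and 0 < z < 1")
    if abs(v) < 1e-12:
        return z
    # P(upper) = (1 - exp(-2 v z a)) / (1 - exp(-2 v a))
    num = -math.expm1(-2.0 * v * z * a)
    den = -math.expm1(-2.0 * v * a)
    return num / den
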