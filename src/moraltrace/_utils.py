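"""Shared helpers: seeded substreams and input validation."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "check_positive", "check_proportion"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible random substream.

    All randomness in the package flows from one integer ``seed``; every
    stochastic stage draws from its own named stream so that adding a stage
    never perturbs the draws of another.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


def check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def check_proportion(**kwargs) -> None:
    for name, value in kwargs.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
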