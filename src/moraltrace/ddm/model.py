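"""The multi-attribute diffusion model family M1-M7.

Every model shares the same skeleton: on trial t of run s the drift rate
is a weighted sum of the trial's relative reward R (incorrect minus
correct, normalized) and relative cumulative response C (incorrect-choice
count minus correct-choice count, normalized),

    v_t = (w_r + d_r * s~) * R~_t + (w_c + d_c * s~) * C~_t [+ w_h * h_t],

the decision threshold shrinks or grows across runs through a log link,
a_t = exp(alpha0 + alpha_s * s~), and the starting bias uses a logistic
link, z_t = logistic(zeta0 [+ zeta_s * s~] [+ zeta_h * h_t]), with s~ the
run index centered and scaled to [-1, 1] and h_t the previous run's choice
for the same question (+1 lie / -1 honest / 0 none).  The family differs
only in which session-modulation and history terms are free:

    M1  d_r = d_c = 0, no zeta_s        M5  M4 + zeta_s
    M2  d_c free                        M6  M5 + zeta_h
    M3  d_r free                        M7  M5 + w_h
    M4  d_r and d_c free

A subject-level non-decision time t0 completes each model.  Inactive
coefficients are pinned to exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PARAM_NAMES", "MODEL_IDS", "DDMModelSpec", "assemble_covariates",
           "trial_vaz"]

PARAM_NAMES = ["w_r", "w_c", "d_r", "d_c", "w_h",
               "alpha0", "alpha_s", "zeta0", "zeta_s", "zeta_h", "t0"]

_BASE = ["w_r", "w_c", "alpha0", "alpha_s", "zeta0", "t0"]
_ACTIVE = {
    "M1": _BASE,
    "M2": _BASE + ["d_c"],
    "M3": _BASE + ["d_r"],
    "M4": _BASE + ["d_r", "d_c"],
    "M5": _BASE + ["d_r", "d_c", "zeta_s"],
    "M6": _BASE + ["d_r", "d_c", "zeta_s", "zeta_h"],
    "M7": _BASE + ["d_r", "d_c", "zeta_s", "w_h"],
}
MODEL_IDS = tuple(_ACTIVE)

# parameter block used for the sampler's grouped Metropolis updates
_BLOCK = {"w_r": 0, "w_c": 0, "d_r": 0, "d_c": 0, "w_h": 0,
          "alpha0": 1, "alpha_s": 1, "zeta0": 1, "zeta_s": 1, "zeta_h": 1,
          "t0": 2}

# weakly-informative group-level priors on the link scale:
# group means ~ N(m0, 2^2), group SDs ~ half-normal(1)
_PRIOR_MEAN = {name: 0.0 for name in PARAM_NAMES}
_PRIOR_MEAN["alpha0"] = 0.5   # threshold near exp(0.5) ~ 1.6
_PRIOR_MEAN["t0"] = 0.3


@dataclass(frozen=True)
class DDMModelSpec:
    """One member of the model family plus its data-preparation rules.

    ``normalization`` controls how rewards and CR enter the drift:
    "design" (default) z-scores R within subject over the full design and
    divides C by sqrt(run - 1), its standard deviation under exchangeable
    coin-flip choices — both quantities are known before any choice is
    made, so the same rule serves generation and fitting;  "zscore"
    z-scores both R and C within subject over the realized included
    trials.  ``session_coding`` "run" maps runs 1..n linearly onto
    [-1, 1]; "session" uses the 3-scan-session grouping (3 runs each).
    """

    model_id: str = "M5"
    normalization: str = "design"
    session_coding: str = "run"
    rt_min: float = 0.3
    rt_max: float = 4.0

    def __post_init__(self):
        if self.model_id not in _ACTIVE:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.normalization not in ("design", "zscore"):
            raise ValueError("normalization must be 'design' or 'zscore'")
        if self.session_coding not in ("run", "session"):
            raise ValueError("session_coding must be 'run' or 'session'")

    @property
    def active(self) -> list[str]:
        return list(_ACTIVE[self.model_id])

    @property
    def active_idx(self) -> np.ndarray:
        return np.array([PARAM_NAMES.index(p) for p in self.active])

    @property
    def blocks(self) -> np.ndarray:
        return np.array([_BLOCK[p] for p in self.active])

    @property
    def prior_mean(self) -> np.ndarray:
        return np.array([_PRIOR_MEAN[p] for p in self.active])

    @property
    def prior_sd(self) -> np.ndarray:
        return np.full(len(self.active), 2.0)

    def full_vector(self, values: dict[str, float]) -> np.ndarray:
        """Embed an active-parameter dict into the pinned full vector."""
        full = np.zeros(len(PARAM_NAMES))
        for name, v in values.items():
            if name not in self.active:
                raise ValueError(f"{name!r} is not active in {self.model_id}")
            full[PARAM_NAMES.index(name)] = v
        return full


def _session_scaled(run: np.ndarray, n_runs: int, coding: str) -> np.ndarray:
    if coding == "session":
        sess = (run - 1) // 3 + 1
        n = int(np.ceil(n_runs / 3))
        run, n_runs = sess, n
    if n_runs == 1:
        return np.zeros_like(run, dtype=float)
    return (run - (n_runs + 1) / 2.0) / ((n_runs - 1) / 2.0)


def assemble_covariates(trials: pd.DataFrame, spec: DDMModelSpec,
                        n_runs: int | None = None) -> pd.DataFrame:
    """Attach the model's normalized trial covariates R~, C~, s~, h.

    Works per subject.  The table must already carry the CR bookkeeping
    columns (see :func:`moraltrace.behavior.cr_features`).
    """
    df = trials.copy()
    if n_runs is None:
        n_runs = int(df["run"].max())
    rel_reward = (df["reward_incorrect"] - df["reward_correct"]).astype(float)
    df["relative_reward"] = rel_reward

    r_tilde = np.empty(len(df))
    c_tilde = np.empty(len(df))
    for _, idx in df.groupby("subject").groups.items():
        r = rel_reward.loc[idx].to_numpy()
        c = df.loc[idx, "relative_cr"].to_numpy(dtype=float)
        if spec.normalization == "design":
            sd = r.std()
            r_t = (r - r.mean()) / (sd if sd > 0 else 1.0)
            run = df.loc[idx, "run"].to_numpy(dtype=float)
            c_t = c / np.sqrt(np.maximum(run - 1.0, 1.0))
        else:
            ok = ~df.loc[idx, "timeout"].to_numpy(dtype=bool)
            r_mu, r_sd = r[ok].mean(), r[ok].std()
            c_mu, c_sd = c[ok].mean(), c[ok].std()
            r_t = (r - r_mu) / (r_sd if r_sd > 0 else 1.0)
            c_t = (c - c_mu) / (c_sd if c_sd > 0 else 1.0)
        pos = df.index.get_indexer(idx)
        r_tilde[pos] = r_t
        c_tilde[pos] = c_t
    df["r_tilde"] = r_tilde
    df["c_tilde"] = c_tilde
    df["s_tilde"] = _session_scaled(df["run"].to_numpy(dtype=float), n_runs,
                                    spec.session_coding)
    return df


def trial_vaz(full_params: np.ndarray, r_tilde, c_tilde, s_tilde, h):
    """Per-trial (v, a, z) from a full parameter vector and covariates."""
    w_r, w_c, d_r, d_c, w_h, a0, a_s, z0, z_s, z_h, _t0 = full_params
    v = (w_r + d_r * s_tilde) * r_tilde + (w_c + d_c * s_tilde) * c_tilde \
        + w_h * h
    a = np.exp(a0 + a_s * s_tilde)
    z = 1.0 / (1.0 + np.exp(-(z0 + z_s * s_tilde + z_h * h)))
    return v, a, z
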