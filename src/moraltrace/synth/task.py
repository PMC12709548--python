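"""Diffusion-driven choice/RT generation with sequential CR bookkeeping.

Subject parameters are drawn from group-level normal distributions; each
trial's drift, threshold and bias come from the model's link rules applied
to the trial's normalized relative reward, relative CR, scaled run index
and history response; the decision itself is a simulated diffusion first
passage.  CR counters update sequentially across runs per question, and a
response slower than the 4 s window is a timeout that never advances the
counters.

The default group parameters are the package's study conditions: a
positive reward weight and a larger consistency (CR) weight, a threshold
that shrinks across runs (reproducing the speed-up of responses), a
slight initial bias toward honesty (group lie rate below one half), and
realistic between-subject spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._utils import substream
from ..ddm.model import PARAM_NAMES, DDMModelSpec
from ..ddm.simulate import simulate_many

__all__ = ["GroupParams", "simulate_dataset"]

_DEFAULT_MEANS = {
    "w_r": 0.8, "w_c": 1.2, "d_r": 0.2, "d_c": 0.2, "w_h": 0.3,
    "alpha0": 0.5, "alpha_s": -0.15, "zeta0": -0.3, "zeta_s": 0.1,
    "zeta_h": 0.2, "t0": 0.35,
}
_DEFAULT_SDS = {
    "w_r": 0.4, "w_c": 0.4, "d_r": 0.15, "d_c": 0.15, "w_h": 0.15,
    "alpha0": 0.15, "alpha_s": 0.08, "zeta0": 0.25, "zeta_s": 0.1,
    "zeta_h": 0.1, "t0": 0.08,
}


@dataclass(frozen=True)
class GroupParams:
    """Group-level means and SDs for the subject-level model parameters.

    Only parameters active in ``model_id`` are used; the rest are pinned
    to zero when simulating.
    """

    model_id: str = "M5"
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        spec = DDMModelSpec(model_id=self.model_id)
        means = {**{k: _DEFAULT_MEANS[k] for k in spec.active}, **self.means}
        sds = {**{k: _DEFAULT_SDS[k] for k in spec.active}, **self.sds}
        unknown = (set(self.means) | set(self.sds)) - set(spec.active)
        if unknown:
            raise ValueError(f"parameters not active in {self.model_id}: "
                             f"{sorted(unknown)}")
        if any(s < 0 for s in sds.values()):
            raise ValueError("group SDs must be >= 0")
        if means["t0"] <= 0:
            raise ValueError("group mean of t0 must be positive")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    @property
    def spec(self) -> DDMModelSpec:
        return DDMModelSpec(model_id=self.model_id)

    def draw_subject(self, rng: np.random.Generator) -> np.ndarray:
        """One subject's full parameter vector (inactive entries zero)."""
        full = np.zeros(len(PARAM_NAMES))
        for name in self.spec.active:
            val = rng.normal(self.means[name], self.sds[name])
            if name == "t0":
                val = max(val, 0.1)  # non-decision time cannot vanish
            if name == "alpha0":
                val = np.clip(val, -1.0, 2.0)
            full[PARAM_NAMES.index(name)] = val
        return full


def simulate_dataset(group_params: GroupParams, design: pd.DataFrame,
                     seed: int = 0, dt: float = 1e-3,
                     return_params: bool = False):
    """Simulate a full trial table from group-level parameters.

    Returns the trial table (and, optionally, the per-subject true
    parameter vectors).  Columns match the package's trial-table schema;
    ``islie`` is NaN on timeout rows.
    """
    spec = group_params.spec
    rng = substream(seed, "parameters")
    trial_rng = substream(seed, "trials")
    n_runs = int(design["run"].max())
    records = []
    true_params = {}
    for sid, sub_design in design.groupby("subject", sort=True):
        full = group_params.draw_subject(rng)
        true_params[sid] = full
        rel = (sub_design["reward_incorrect"]
               - sub_design["reward_correct"]).to_numpy(float)
        r_sd = rel.std()
        r_mu = rel.mean()
        sub_design = sub_design.sort_values(["run", "question"])
        # per-question counters
        questions = sub_design["question"].unique()
        cr_inc = {q: 0 for q in questions}
        cr_cor = {q: 0 for q in questions}
        hist = {q: 0 for q in questions}
        for run, run_design in sub_design.groupby("run", sort=True):
            s_tilde = ((run - (n_runs + 1) / 2.0) / ((n_runs - 1) / 2.0)
                       if n_runs > 1 else 0.0)
            q_ids = run_design["question"].to_numpy()
            rr = (run_design["reward_incorrect"]
                  - run_design["reward_correct"]).to_numpy(float)
            r_t = (rr - r_mu) / (r_sd if r_sd > 0 else 1.0)
            c_raw = np.array([cr_inc[q] - cr_cor[q] for q in q_ids], float)
            c_t = c_raw / np.sqrt(max(run - 1.0, 1.0))
            h = np.array([hist[q] if run > 1 else 0 for q in q_ids], float)
            w_r, w_c, d_r, d_c, w_h = full[:5]
            a0, a_s, z0, z_s, z_h, t0 = full[5:]
            v = (w_r + d_r * s_tilde) * r_t + (w_c + d_c * s_tilde) * c_t + w_h * h
            a = np.full_like(v, np.exp(a0 + a_s * s_tilde))
            z = 1.0 / (1.0 + np.exp(-(z0 + z_s * s_tilde + z_h * h)))
            up, rt = simulate_many(v, a, z, np.full_like(v, t0), dt=dt,
                                   seed=int(trial_rng.integers(0, 2**31 - 1)))
            for i, (_, row) in enumerate(run_design.iterrows()):
                q = q_ids[i]
                timeout = rt[i] > 4.0
                islie = np.nan if timeout else float(up[i])
                records.append({
                    "subject": sid, "run": int(run), "question": int(q),
                    "reward_correct": int(row["reward_correct"]),
                    "reward_incorrect": int(row["reward_incorrect"]),
                    "correct_side": row["correct_side"],
                    "cr_correct": cr_cor[q], "cr_incorrect": cr_inc[q],
                    "history": int(hist[q]) if run > 1 else 0,
                    "islie": islie, "rt": float(rt[i]),
                    "timeout": bool(timeout),
                })
                if timeout:
                    hist[q] = 0
                elif up[i]:
                    cr_inc[q] += 1
                    hist[q] = 1
                else:
                    cr_cor[q] += 1
                    hist[q] = -1
    trials = pd.DataFrame(records)
    trials["relative_cr"] = trials["cr_incorrect"] - trials["cr_correct"]
    trials["dishonest_cr"] = trials["cr_incorrect"]
    if return_params:
        return trials, true_params
    return trials
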