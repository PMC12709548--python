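"""Task-design generation: runs x questions with reward cues.

The task repeats the same set of trivia questions across runs.  Each trial
shows the correct and the incorrect answer with coin rewards; to create an
honesty-reward conflict, a configurable fraction of trials assigns the
strictly higher reward to the incorrect answer (default 0.8 — the realized
design fraction — with the conservative "over half" value reachable via
the argument).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._utils import check_proportion, substream

__all__ = ["generate_design"]


def generate_design(n_subjects: int = 1, n_questions: int = 20,
                    n_runs: int = 9, frac_incorrect_higher: float = 0.8,
                    reward_low: int = 1, reward_high: int = 9,
                    seed: int = 0) -> pd.DataFrame:
    """One row per (subject, run, question) with reward cues and sides.

    Rewards are integers drawn uniformly on [reward_low, reward_high]; in
    round(frac * n) cells per subject the incorrect option's reward
    strictly exceeds the correct option's, in the rest it does not.  The
    correct answer's side is balanced left/right within each run (within
    one trial when the run length is odd).
    """
    for name, v in (("n_subjects", n_subjects), ("n_questions", n_questions),
                    ("n_runs", n_runs)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    check_proportion(frac_incorrect_higher=frac_incorrect_higher)
    if reward_low > reward_high or reward_low < 0:
        raise ValueError("require 0 <= reward_low <= reward_high")
    rng = substream(seed, "design")

    rows = []
    n_cells = n_questions * n_runs
    n_higher = int(round(frac_incorrect_higher * n_cells))
    for s_idx in range(n_subjects):
        sid = f"s{s_idx + 1:02d}"
        higher = np.zeros(n_cells, dtype=bool)
        higher[rng.choice(n_cells, size=n_higher, replace=False)] = True
        cell = 0
        for run in range(1, n_runs + 1):
            sides = np.array(["left", "right"]).repeat(
                [(n_questions + 1) // 2, n_questions // 2])
            rng.shuffle(sides)
            for q in range(1, n_questions + 1):
                if reward_low == reward_high:
                    rc = ri = reward_low
                    if higher[cell]:
                        raise ValueError(
                            "cannot make the incorrect reward strictly higher "
                            "with reward_low == reward_high")
                elif higher[cell]:
                    # ordered pair with strictly larger incorrect reward
                    ri = int(rng.integers(reward_low + 1, reward_high + 1))
                    rc = int(rng.integers(reward_low, ri))
                else:
                    rc = int(rng.integers(reward_low, reward_high + 1))
                    ri = int(rng.integers(reward_low, rc + 1))
                rows.append({"subject": sid, "run": run, "question": q,
                             "reward_correct": rc, "reward_incorrect": ri,
                             "correct_side": sides[q - 1]})
                cell += 1
    return pd.DataFrame(rows)
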