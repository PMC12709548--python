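import warnings

import numpy as np
import pandas as pd
import pytest

from moraltrace.synth import GroupParams, generate_design, simulate_dataset


@pytest.fixture(scope="session")
def m5_dataset():
    """A 12-subject dataset simulated from the default M5 conditions."""
    design = generate_design(n_subjects=12, seed=42)
    gp = GroupParams(model_id="M5")
    trials, true_params = simulate_dataset(gp, design, seed=42,
                                           return_params=True)
    return trials, true_params, gp


@pytest.fixture(scope="session")
def m5_fit(m5_dataset):
    """A converging (short-chain) hierarchical fit shared across tests."""
    from moraltrace.ddm import HierarchicalDDM

    trials, _, _ = m5_dataset
    est = HierarchicalDDM(model="M5", chains=3, iterations=1200, burn_in=500,
                          seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(trials)
    return est


def make_trials(choices, runs=None, question=1, subject="s01", rts=None,
                timeouts=None):
    """Hand-build a minimal trial table for bookkeeping tests."""
    n = len(choices)
    runs = list(range(1, n + 1)) if runs is None else runs
    rts = [1.0] * n if rts is None else rts
    timeouts = [False] * n if timeouts is None else timeouts
    return pd.DataFrame({
        "subject": subject, "run": runs, "question": question,
        "reward_correct": 5, "reward_incorrect": 6, "correct_side": "left",
        "islie": [np.nan if t else float(c) for c, t in zip(choices, timeouts)],
        "rt": rts, "timeout": timeouts,
    })
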