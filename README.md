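# moraltrace

Computational analysis of **repeated moral decisions**: how people
trade off a monetary reward against honesty and their own choice
history, trial after trial.

The experimental setting is an information-transmission task: over 9
runs a participant repeatedly answers the same 20 trivia questions,
choosing between the correct answer and an incorrect answer that
usually carries a larger coin reward, while the screen displays how
often each option was chosen before (cumulative responses, CR).
`moraltrace` implements the full analysis chain for this kind of data —
exercised end to end on its own synthetic-data generators — for
cognitive and decision neuroscientists who want a tested, reusable
version of these methods:

* **Mouse tracking.** Cursor trajectories are rescaled to a standard
  space (start at (0, 0), response corners at (±1, 1)), mirrored to one
  side, and time-normalized to 101 bins.  Choice conflict is the signed
  area (AUC) between the path and the straight start→end line.
* **Choice consistency.**  Per subject, the lie rate p and the binary
  response entropy H(p) = −p log₂ p − (1−p) log₂(1−p); per trial, CR
  counters and the relative CR (incorrect − correct choice counts).
* **Hierarchical drift–diffusion models (M1–M7).**  A multi-attribute
  DDM whose drift is a weighted sum of relative reward (w_r) and
  relative CR (w_c), with run-dependent threshold exp(α0 + α_s·s̃),
  optional run-dependent bias and choice-history terms.  Estimation is
  Bayesian (numba-accelerated adaptive MCMC with interweaved
  non-centered moves), with split-chain R-hat, DIC model comparison,
  posterior probabilities, and posterior predictive checks on per-run
  choice proportions and RT quantiles.
* **Sensitivity and mediation.**  Analytic minimum detectable
  correlation (Fisher z), simulation-based power curves, and the
  three-variable mediation AUC → reward weight → entropy with bootstrap
  or Monte-Carlo intervals.
* **Neural-pattern analysis.**  Template similarity to thresholded
  reference maps (z > 3.0) with run-trend tests; inter-subject RSA
  correlating the Euclidean distance matrix in (v_CR, v_reward)
  parameter space against 1 − inter-subject pattern correlation, with
  10,000-shuffle permutation tests and Benjamini–Hochberg FDR.
* **Connectivity graphs.**  Fisher-z functional connectivity, weighted
  global efficiency and betweenness centrality, run trends, and
  brain–behavior correlations over a nine-ROI default network.

See `docs/methods.md` for the model details, parameter conventions,
and design choices.

## Worked example

```python
import warnings
import numpy as np
from moraltrace.behavior import lie_rate, response_entropy, min_detectable_correlation
from moraltrace.synth import GroupParams, generate_design, simulate_dataset
from moraltrace.ddm import HierarchicalDDM

design = generate_design(n_subjects=12, seed=1)          # 9 runs x 20 questions
gp = GroupParams(model_id="M5")                          # study-condition defaults
trials = simulate_dataset(gp, design, seed=1)

print(f"pooled lie rate: {trials['islie'].mean():.3f}")
p = lie_rate(trials[trials['subject'] == 's01'])
print(f"subject s01: lie rate {p:.3f}, response entropy {response_entropy(p):.3f} bits")
print(f"minimum detectable |r| (n=34, 80% power): "
      f"{min_detectable_correlation(34, 0.80, 0.05, 2):.2f}")

est = HierarchicalDDM(model="M5", chains=3, iterations=2400, burn_in=900, seed=2)
est.fit(trials)
post = est.posterior_
for name in ("w_r", "w_c"):
    d = post.group_mean_draws(name)
    print(f"group mean {name}: {d.mean():+.2f} "
          f"[{np.percentile(d, 2.5):+.2f}, {np.percentile(d, 97.5):+.2f}]")
print(f"P(w_c > w_r) = {est.posterior_prob('w_c > w_r'):.3f}")
print(f"max R-hat {max(post.rhat.values()):.2f}, DIC {post.dic:.1f}")
```

Output:

```
pooled lie rate: 0.344
subject s01: lie rate 0.206, response entropy 0.733 bits
minimum detectable |r| (n=34, 80% power): 0.46
group mean w_r: +0.76 [+0.51, +1.01]
group mean w_c: +1.17 [+0.84, +1.50]
P(w_c > w_r) = 0.978
max R-hat 1.03, DIC 345.3
```

Reading it: under the default study conditions subjects lie on roughly
a third of trials; subject s01's inconsistency is 0.73 bits (1 bit
would be coin-flip choices).  A design of 34 subjects can only detect
between-subject correlations of |r| ≥ 0.46 at 80% power.  The
hierarchical fit recovers the generating group weights (true w_r = 0.8,
w_c = 1.2) inside their 95% credible intervals, assigns high posterior
probability to the consistency weight exceeding the reward weight, and
the chains converge (R-hat < 1.1).

## Command-line pipeline

Every stage also runs from the shell, driven by one YAML config:

```bash
moraltrace all --outdir runs/demo --seed 3          # simulate ... report
moraltrace isrsa --config my_config.yaml --resume   # one stage, resumable
```

The run directory collects delimited tables (`trials.csv`,
`model_comparison.csv`, `ppc.csv`, ...), JSON results
(`mediation.json`, `isrsa.json`, `connectivity.json`), a consolidated
`report.txt` and a `manifest.json` with the config hash and seed;
identical configs reproduce byte-identical outputs.

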