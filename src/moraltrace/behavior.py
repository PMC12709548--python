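"""Behavioral statistics for the repeated moral-decision task.

Subject-level consistency is summarized by the lie rate p (proportion of
dishonest, i.e. incorrect-answer, choices over non-timeout trials) and the
binary response entropy H(p) = -p log2 p - (1-p) log2 (1-p), which is 0
when a subject always lies or always tells the truth and 1 when choices
are maximally inconsistent.  Trial-level consistency is carried by the
cumulative-response (CR) counters: how often each option was chosen for
the same question in earlier runs.  The module also provides the
psychometric (logistic) fit of lying on relative reward stratified by the
sign of relative CR, random-intercept regressions, and the analytic and
simulation-based sensitivity utilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._utils import check_proportion, substream

__all__ = [
    "StatResult",
    "lie_rate",
    "response_entropy",
    "cr_features",
    "fit_psychometric",
    "fit_random_intercept",
    "min_detectable_correlation",
    "power_by_simulation",
    "subject_summaries",
]


@dataclass
class StatResult:
    """Coefficient table plus omnibus statistics for one fitted model."""

    params: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    statistic: float | None = None
    statistic_name: str | None = None
    statistic_p: float | None = None
    effect_size: float | None = None  # partial eta squared where applicable
    extra: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.params[name]


# ---------------------------------------------------------------------------
# subject-level summaries
# ---------------------------------------------------------------------------

def lie_rate(trials: pd.DataFrame) -> float:
    """Proportion of dishonest choices over non-timeout trials."""
    ok = trials.loc[~trials["timeout"].astype(bool)]
    if len(ok) == 0:
        raise ValueError("lie rate undefined: all trials are timeouts")
    return float(ok["islie"].mean())


def response_entropy(p: float) -> float:
    """Binary Shannon entropy of the lie probability, in bits.

    H(p) = -p log2 p - (1-p) log2 (1-p), with 0 log 0 taken as 0.
    """
    check_proportion(p=p)
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p))


def subject_summaries(trials: pd.DataFrame,
                      auc: pd.Series | None = None) -> pd.DataFrame:
    """Per-subject lie rate, response entropy and (optionally) mean AUC."""
    rows = []
    for sid, sub in trials.groupby("subject", sort=True):
        p = lie_rate(sub)
        row = {"subject": sid, "lie_rate": p,
               "entropy": response_entropy(p)}
        rows.append(row)
    out = pd.DataFrame(rows).set_index("subject")
    if auc is not None:
        out["mean_auc"] = auc
    return out


# ---------------------------------------------------------------------------
# trial-level CR bookkeeping
# ---------------------------------------------------------------------------

def cr_features(trials: pd.DataFrame) -> pd.DataFrame:
    """Populate CR counters, relative CR and history response per trial.

    For every question the counters accumulate across runs: cr_incorrect /
    cr_correct count how often the dishonest / honest option was chosen in
    earlier runs; timeouts never advance the counters.  ``history`` is the
    choice made for the same question in the immediately preceding run
    (+1 lie, -1 honest, 0 if run 1 or the previous run timed out).
    """
    required = {"subject", "run", "question", "islie", "timeout"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    if trials.duplicated(["subject", "run", "question"]).any():
        raise ValueError("duplicate (subject, run, question) rows")

    out = trials.sort_values(["subject", "question", "run"]).copy()
    cr_inc = np.zeros(len(out), dtype=int)
    cr_cor = np.zeros(len(out), dtype=int)
    hist = np.zeros(len(out), dtype=int)

    islie = out["islie"].to_numpy()
    timeout = out["timeout"].to_numpy(dtype=bool)
    pos = 0
    for _, grp in out.groupby(["subject", "question"], sort=False):
        n = len(grp)
        inc = cor = 0
        prev = 0
        for i in range(n):
            cr_inc[pos + i] = inc
            cr_cor[pos + i] = cor
            hist[pos + i] = prev if i > 0 else 0
            if timeout[pos + i]:
                prev = 0
            else:
                if islie[pos + i]:
                    inc += 1
                    prev = 1
                else:
                    cor += 1
                    prev = -1
        pos += n
    out["cr_incorrect"] = cr_inc
    out["cr_correct"] = cr_cor
    out["relative_cr"] = cr_inc - cr_cor
    out["dishonest_cr"] = cr_inc
    out["history"] = hist
    return out.sort_index()


# ---------------------------------------------------------------------------
# psychometric curve
# ---------------------------------------------------------------------------

def _logistic_nll(beta, X, y, ridge):
    eta = X @ beta
    # log(1 + e^eta) - y*eta, numerically stable
    nll = np.sum(np.logaddexp(0.0, eta) - y * eta)
    return nll + 0.5 * ridge * np.sum(beta**2)


def fit_psychometric(trials: pd.DataFrame, stratum: str | None = None,
                     predictor: str = "relative_reward") -> StatResult:
    """Logistic fit of P(lie) on relative reward within one CR stratum.

    ``stratum`` selects trials by the sign of relative CR: "+", "0", "-",
    or None for all trials.  Complete separation is detected and flagged;
    the fit then falls back to a lightly ridge-penalized likelihood so that
    finite estimates are still returned.
    """
    df = trials.loc[~trials["timeout"].astype(bool)]
    if stratum is not None:
        sign = np.sign(df["relative_cr"])
        sel = {"+": sign > 0, "0": sign == 0, "-": sign < 0}[stratum]
        df = df.loc[sel]
    y = df["islie"].to_numpy(dtype=float)
    x = df[predictor].to_numpy(dtype=float)
    x1, x0 = x[y == 1], x[y == 0]
    if len(x1) == 0 or len(x0) == 0:
        separated = True
    else:
        # complete or quasi-complete separation on a single predictor:
        # the two outcome classes occupy (weakly) disjoint x ranges
        separated = bool(x1.min() >= x0.max() or x0.min() >= x1.max())
    X = np.column_stack([np.ones_like(x), x])

    ridge = 0.0
    if not separated:
        res = optimize.minimize(_logistic_nll, np.zeros(2), args=(X, y, 0.0),
                                method="BFGS")
        # separation shows up as runaway coefficients
        if not res.success or np.max(np.abs(res.x)) > 30:
            separated = True
    if separated:
        ridge = 1.0
        res = optimize.minimize(_logistic_nll, np.zeros(2), args=(X, y, ridge),
                                method="BFGS")
    beta = res.x
    # observed-information standard errors (of the (penalized) likelihood)
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    W = p * (1 - p)
    H = (X * W[:, None]).T @ X + ridge * np.eye(2)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pv = 2 * stats.norm.sf(np.abs(z))
    names = ["intercept", "slope"]
    ci = {n: (b - 1.959963984540054 * s, b + 1.959963984540054 * s)
          for n, b, s in zip(names, beta, se)}
    return StatResult(
        params=dict(zip(names, beta)), se=dict(zip(names, se)),
        pvalues=dict(zip(names, pv)), conf_int=ci,
        extra={"separated": separated, "n": len(y), "ridge": ridge},
    )


# ---------------------------------------------------------------------------
# random-intercept regressions
# ---------------------------------------------------------------------------

def fit_random_intercept(data: pd.DataFrame, outcome: str,
                         predictors: list[str], group: str = "subject",
                         family: str = "gaussian") -> StatResult:
    """Mixed model with a single random intercept per subject.

    ``family='gaussian'`` fits a linear mixed model (REML);
    ``family='binomial'`` fits a logistic random-intercept model by
    variational Bayes.  Both return fixed-effect coefficients with
    standard errors and (approximate) p-values.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if data[group].nunique() < 2:
        raise ValueError("need at least 2 groups")
    rhs = " + ".join(predictors) if predictors else "1"
    formula = f"{outcome} ~ {rhs}"
    if family == "gaussian":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, data, groups=data[group]).fit(reml=True)
        names = [n for n in fit.params.index if n != "Group Var"]
        params = {n: float(fit.params[n]) for n in names}
        se = {n: float(fit.bse[n]) for n in names}
        pv = {n: float(fit.pvalues[n]) for n in names}
        ci_df = fit.conf_int()
        ci = {n: (float(ci_df.loc[n, 0]), float(ci_df.loc[n, 1])) for n in names}
        extra = {"group_var": float(fit.cov_re.iloc[0, 0]),
                 "resid_var": float(fit.scale)}
    elif family == "binomial":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.BinomialBayesMixedGLM.from_formula(
                formula, {"a": f"0 + C({group})"}, data)
            fit = model.fit_vb()
        names = list(model.exog_names)
        mean = fit.fe_mean
        sd = fit.fe_sd
        params = dict(zip(names, map(float, mean)))
        se = dict(zip(names, map(float, sd)))
        z = mean / sd
        pv = dict(zip(names, (2 * stats.norm.sf(np.abs(z))).tolist()))
        ci = {n: (m - 1.96 * s, m + 1.96 * s)
              for n, m, s in zip(names, mean, sd)}
        extra = {"method": "variational_bayes"}
    else:
        raise ValueError(f"unknown family {family!r}")
    return StatResult(params=params, se=se, pvalues=pv, conf_int=ci,
                      extra=extra)


# ---------------------------------------------------------------------------
# sensitivity / power
# ---------------------------------------------------------------------------

def min_detectable_correlation(n: int, power: float = 0.80,
                               alpha: float = 0.05, tails: int = 2) -> float:
    """Smallest |r| detectable with the stated power (Fisher-z approximation).

    Solves atanh(r) * sqrt(n - 3) = z_{1-alpha/tails} + z_{power}; with
    n = 34, power = 0.80 and two-tailed alpha = 0.05 this gives r = 0.46.
    """
    if n <= 3:
        raise ValueError("n must exceed 3 for the Fisher-z approximation")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    z_alpha = stats.norm.ppf(1 - alpha / tails)
    z_power = stats.norm.ppf(power)
    return float(np.tanh((z_alpha + z_power) / np.sqrt(n - 3)))


def power_by_simulation(generator, fit, beta_grid, n_sims: int = 100,
                        alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo power curve over a grid of effect sizes.

    ``generator(beta, rng)`` returns a dataset; ``fit(dataset)`` returns a
    p-value.  For each effect size the proportion of replicates with
    p < alpha is reported with its binomial standard error.  Replicates
    whose fit raises are counted; they are dropped from the denominator
    only when fewer than 5% fail, otherwise the failure itself is the
    result.
    """
    if n_sims < 20:
        raise ValueError("n_sims must be at least 20")
    rng = substream(seed, "power")
    rows = []
    for beta in beta_grid:
        n_sig = n_fail = 0
        for _ in range(n_sims):
            data = generator(beta, rng)
            try:
                p = fit(data)
            except Exception:
                n_fail += 1
                continue
            if p < alpha:
                n_sig += 1
        denom = n_sims - n_fail
        if n_fail >= 0.05 * n_sims or denom == 0:
            power = np.nan
        else:
            power = n_sig / denom
        se = np.sqrt(power * (1 - power) / denom) if denom and np.isfinite(power) else np.nan
        rows.append({"beta": beta, "power": power, "se": se,
                     "n_failed": n_fail, "n_sims": n_sims})
    return pd.DataFrame(rows)
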