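"""Hierarchical Bayesian estimation, convergence, and model comparison.

The estimator follows the scikit-learn protocol: construct with settings,
``fit`` on a trial table, read fitted attributes (``posterior_``,
``rhat_``, ``dic_``, ``converged_``).  Convergence is judged by the
split-chain Gelman-Rubin statistic (R-hat < 1.1), model comparison by the
deviance information criterion DIC = D_hat + 2 * pD with pD = D_bar -
D_hat, and adequacy by posterior predictive checks on per-run choice
proportions and RT quantiles.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._utils import substream
from .model import PARAM_NAMES, DDMModelSpec, assemble_covariates, trial_vaz
from .sampler import run_chain, _subject_ll
from .simulate import simulate_many
from .wfpt import wiener_logpdf

__all__ = ["PosteriorSet", "HierarchicalDDM", "fit_hierarchical", "rhat",
           "dic", "posterior_prob", "posterior_predictive", "trial_loglik"]


@dataclass
class PosteriorSet:
    """Posterior draws plus convergence and fit summaries."""

    spec: DDMModelSpec
    param_names: list[str]
    subjects: list
    group_draws: dict[str, np.ndarray]      # name -> (chains, draws)
    subject_draws: np.ndarray               # (chains, draws, J, K)
    rhat: dict[str, float]
    n_excluded_rt: int = 0
    dic: float | None = None
    pd_eff: float | None = None
    deviance_mean: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return max(self.rhat.values()) < 1.1

    def group_mean_draws(self, name: str) -> np.ndarray:
        return self.group_draws[f"mu_{name}"].ravel()

    def subject_posterior_means(self) -> pd.DataFrame:
        means = self.subject_draws.mean(axis=(0, 1))
        return pd.DataFrame(means, index=self.subjects,
                            columns=self.param_names)

    def to_frame(self) -> pd.DataFrame:
        """Long columnar form: chain, draw, parameter, value."""
        rows = []
        for name, arr in self.group_draws.items():
            n_chains, n_draws = arr.shape
            for c in range(n_chains):
                rows.append(pd.DataFrame({
                    "chain": c, "draw": np.arange(n_draws),
                    "parameter": name, "value": arr[c]}))
        return pd.concat(rows, ignore_index=True)


def rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  Each chain is split in half, so
    within- and between-chain variability are compared over 2m sequences.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    m = halves.shape[0]
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W <= 0:
        return np.inf if B > 0 else 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


class HierarchicalDDM:
    """Hierarchical multi-attribute diffusion model estimator.

    Parameters
    ----------
    model : model id "M1".."M7".
    chains, iterations, burn_in, thin : MCMC settings.  Defaults are
        desk-scale (4 chains x 3,000 iterations, 1,000 burn-in, no
        thinning).
    normalization, session_coding, rt_min, rt_max : forwarded to
        :class:`DDMModelSpec`.
    seed : base seed; chain c uses substream (seed, chain index).
    """

    def __init__(self, model: str = "M5", chains: int = 4,
                 iterations: int = 3000, burn_in: int = 1000, thin: int = 1,
                 normalization: str = "design", session_coding: str = "run",
                 rt_min: float = 0.3, rt_max: float = 4.0, seed: int = 0):
        self.model = model
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.normalization = normalization
        self.session_coding = session_coding
        self.rt_min = rt_min
        self.rt_max = rt_max
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("model", "chains", "iterations", "burn_in", "thin",
                 "normalization", "session_coding", "rt_min", "rt_max",
                 "seed")}

    def set_params(self, **params):
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def _prepare(self, trials: pd.DataFrame):
        spec = DDMModelSpec(model_id=self.model,
                            normalization=self.normalization,
                            session_coding=self.session_coding,
                            rt_min=self.rt_min, rt_max=self.rt_max)
        if "relative_cr" not in trials.columns:
            from ..behavior import cr_features
            trials = cr_features(trials)
        df = assemble_covariates(trials, spec)
        ok = ~df["timeout"].astype(bool)
        n_slow_fast = int((ok & ((df["rt"] < spec.rt_min) |
                                 (df["rt"] > spec.rt_max))).sum())
        if n_slow_fast:
            warnings.warn(f"excluded {n_slow_fast} trials with RT outside "
                          f"[{spec.rt_min}, {spec.rt_max}] s", UserWarning,
                          stacklevel=3)
        inc = ok & (df["rt"] >= spec.rt_min) & (df["rt"] <= spec.rt_max)
        df = df.loc[inc].sort_values(["subject", "run", "question"])
        subjects = sorted(df["subject"].unique())
        if len(subjects) < 3:
            raise ValueError("hierarchical fit needs at least 3 subjects")
        counts = df.groupby("subject").size().reindex(subjects)
        starts = np.concatenate([[0], np.cumsum(counts.to_numpy())]).astype(np.int64)
        order = {s: i for i, s in enumerate(subjects)}
        df = df.sort_values(["subject"], key=lambda s: s.map(order), kind="stable")
        data = (
            np.ascontiguousarray(df["r_tilde"], dtype=float),
            np.ascontiguousarray(df["c_tilde"], dtype=float),
            np.ascontiguousarray(df["s_tilde"], dtype=float),
            np.ascontiguousarray(df["history"], dtype=float),
            np.ascontiguousarray(df["rt"], dtype=float),
            np.ascontiguousarray(df["islie"], dtype=np.int64),
            starts,
        )
        return spec, df, subjects, data, n_slow_fast

    def fit(self, trials: pd.DataFrame) -> "HierarchicalDDM":
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")
        spec, df, subjects, data, n_excl = self._prepare(trials)
        R, C, S, H, RT, CH, starts = data
        act = spec.active_idx.astype(np.int64)
        blk = spec.blocks.astype(np.int64)
        pm = spec.prior_mean
        ps = spec.prior_sd
        J, K = len(subjects), len(act)

        # data-informed starting values, jittered per chain
        min_rt = np.array([RT[starts[j]:starts[j + 1]].min() for j in range(J)])
        g_chains, s_chains = [], []
        for c in range(self.chains):
            rng = substream(self.seed, f"ddm-chain-{c}")
            theta0 = np.zeros((J, 11))
            theta0[:, PARAM_NAMES.index("alpha0")] = 0.4 + 0.1 * rng.standard_normal(J)
            theta0[:, 10] = np.minimum(0.5 * min_rt, 0.4)
            for k, idx in enumerate(act):
                if PARAM_NAMES[idx] in ("alpha0", "t0"):
                    continue
                theta0[:, idx] += 0.2 * rng.standard_normal(J)
            mu0 = np.array([theta0[:, idx].mean() for idx in act])
            sig0 = np.full(K, 0.3)
            g, s, acc = run_chain(R, C, S, H, RT, CH, starts, act, blk, pm, ps,
                                  int(self.iterations), int(self.burn_in),
                                  int(self.thin),
                                  int(rng.integers(0, 2**31 - 1)),
                                  theta0, mu0, sig0)
            g_chains.append(g)
            s_chains.append(s)
        g_arr = np.stack(g_chains)           # (chains, draws, 2K)
        s_arr = np.stack(s_chains)           # (chains, draws, J, K)

        names = spec.active
        group_draws = {}
        for k, name in enumerate(names):
            group_draws[f"mu_{name}"] = g_arr[:, :, k]
            group_draws[f"sigma_{name}"] = g_arr[:, :, K + k]
        rh = {name: rhat(arr) for name, arr in group_draws.items()}

        post = PosteriorSet(spec=spec, param_names=names, subjects=subjects,
                            group_draws=group_draws, subject_draws=s_arr,
                            rhat=rh, n_excluded_rt=n_excl)
        post.extra["data"] = data
        if not post.converged:
            warnings.warn(
                f"chains not converged: max R-hat = {max(rh.values()):.3f}",
                UserWarning, stacklevel=2)
        d, p_eff, dbar = dic(post)
        post.dic, post.pd_eff, post.deviance_mean = d, p_eff, dbar
        self.posterior_ = post
        self.rhat_ = rh
        self.dic_ = d
        self.converged_ = post.converged
        self.trials_ = df
        return self

    def posterior_prob(self, expression: str) -> float:
        return posterior_prob(self.posterior_, expression)

    def posterior_predictive(self, n_draws: int = 100, seed: int = 0):
        return posterior_predictive(self.posterior_, self.trials_,
                                    n_draws=n_draws, seed=seed)


def fit_hierarchical(trials: pd.DataFrame, model: str = "M5", **kwargs) -> PosteriorSet:
    """Functional wrapper over :class:`HierarchicalDDM`."""
    est = HierarchicalDDM(model=model, **kwargs)
    return est.fit(trials).posterior_


# ---------------------------------------------------------------------------
# single-trial likelihood (exposed for checks and diagnostics)
# ---------------------------------------------------------------------------

def trial_loglik(record, full_params: np.ndarray, spec: DDMModelSpec) -> float:
    """Log density of one trial under a full parameter vector.

    The record must carry the assembled covariates r_tilde, c_tilde,
    s_tilde, history plus rt and islie, not be a timeout, and have an RT
    inside the inclusion window.
    """
    if bool(record["timeout"]):
        raise ValueError("timeout trials carry no likelihood")
    rt = float(record["rt"])
    if not (spec.rt_min <= rt <= spec.rt_max):
        raise ValueError(f"RT {rt} outside inclusion window "
                         f"[{spec.rt_min}, {spec.rt_max}]")
    v, a, z = trial_vaz(np.asarray(full_params, float),
                        float(record["r_tilde"]), float(record["c_tilde"]),
                        float(record["s_tilde"]), float(record["history"]))
    return float(wiener_logpdf(rt, bool(record["islie"]), float(v), float(a),
                               float(z), float(full_params[10])))


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def _total_deviance(subject_full: np.ndarray, data) -> float:
    R, C, S, H, RT, CH, starts = data
    J = starts.size - 1
    ll = 0.0
    for j in range(J):
        ll += _subject_ll(subject_full[j], R, C, S, H, RT, CH,
                          starts[j], starts[j + 1])
    return -2.0 * ll


def _full_from_active(active_vals: np.ndarray, spec: DDMModelSpec) -> np.ndarray:
    J = active_vals.shape[0]
    full = np.zeros((J, len(PARAM_NAMES)))
    for k, idx in enumerate(spec.active_idx):
        full[:, idx] = active_vals[:, k]
    return full


def dic(posterior: PosteriorSet, max_draws: int = 200, seed: int = 0):
    """Deviance information criterion focused on subject-level parameters.

    Returns (DIC, pD, D_bar) with D_bar the posterior-mean deviance, D_hat
    the deviance at the posterior means, pD = D_bar - D_hat and
    DIC = D_hat + 2 pD.
    """
    data = posterior.extra["data"]
    s = posterior.subject_draws
    n_chains, n_draws = s.shape[:2]
    rng = substream(seed, "dic")
    total = n_chains * n_draws
    take = min(max_draws, total)
    idx = rng.choice(total, size=take, replace=False)
    flat = s.reshape(total, *s.shape[2:])
    devs = np.empty(take)
    spec = posterior.spec
    for i, ix in enumerate(idx):
        devs[i] = _total_deviance(_full_from_active(flat[ix], spec), data)
    d_bar = float(devs.mean())
    theta_hat = flat.mean(axis=0)
    d_hat = _total_deviance(_full_from_active(theta_hat, spec), data)
    p_eff = d_bar - d_hat
    return d_hat + 2.0 * p_eff, p_eff, d_bar


# ---------------------------------------------------------------------------
# posterior probabilities of parameter statements
# ---------------------------------------------------------------------------

def posterior_prob(posterior: PosteriorSet, expression: str) -> float:
    """Fraction of group-mean draws satisfying a comparison expression.

    Examples: ``"w_r > 0"``, ``"|w_c| > |w_r|"``, ``"w_c - w_r > 0"``.
    Parameter names refer to group means.
    """
    expr = re.sub(r"\|([^|]+)\|", r"abs(\1)", expression)
    env = {"abs": np.abs}
    for name in posterior.param_names:
        env[name] = posterior.group_mean_draws(name)
    try:
        result = eval(expr, {"__builtins__": {}}, env)  # noqa: S307 - restricted env
    except NameError as exc:
        raise ValueError(f"unknown parameter in expression: {exc}") from exc
    result = np.asarray(result)
    if result.dtype != bool:
        raise ValueError("expression must be a comparison")
    return float(result.mean())


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

_QUANTS = (0.1, 0.3, 0.5, 0.7, 0.9)


def posterior_predictive(posterior: PosteriorSet, trials: pd.DataFrame,
                         n_draws: int = 100, seed: int = 0) -> pd.DataFrame:
    """Simulate the design from posterior draws; summarize per run.

    For each drawn parameter set the full included design is re-simulated
    and per-run choice proportions and RT quantiles are recorded; the
    central 95% predictive interval per statistic is compared with the
    observed value.
    """
    spec = posterior.spec
    df = trials
    runs = np.sort(df["run"].unique())
    rng = substream(seed, "ppc")
    s = posterior.subject_draws
    n_chains, nd = s.shape[:2]
    total = n_chains * nd
    flat = s.reshape(total, *s.shape[2:])
    pick = rng.choice(total, size=min(n_draws, total), replace=False)

    subj_index = {sid: j for j, sid in enumerate(posterior.subjects)}
    j_arr = df["subject"].map(subj_index).to_numpy()
    r_t = df["r_tilde"].to_numpy(float)
    c_t = df["c_tilde"].to_numpy(float)
    s_t = df["s_tilde"].to_numpy(float)
    h = df["history"].to_numpy(float)
    run_arr = df["run"].to_numpy()

    stats_sim = {r: {"prop": [], "q": []} for r in runs}
    for ix in pick:
        full = _full_from_active(flat[ix], spec)
        fp = full[j_arr]
        v, a, z = trial_vaz(fp.T, r_t, c_t, s_t, h)
        t0 = fp[:, 10]
        up, rt = simulate_many(v, a, z, t0, dt=1e-3,
                               seed=int(rng.integers(0, 2**31 - 1)))
        for r in runs:
            m = run_arr == r
            ok = m & (rt <= spec.rt_max)
            stats_sim[r]["prop"].append(up[m].mean())
            if ok.sum() >= 5:
                stats_sim[r]["q"].append(np.quantile(rt[ok], _QUANTS))
            else:
                stats_sim[r]["q"].append(np.full(len(_QUANTS), np.nan))

    rows = []
    for r in runs:
        m = run_arr == r
        obs_prop = float(df.loc[m, "islie"].mean())
        obs_q = np.quantile(df.loc[m, "rt"], _QUANTS)
        props = np.asarray(stats_sim[r]["prop"])
        qs = np.asarray(stats_sim[r]["q"])
        lo_p, hi_p = np.percentile(props, [2.5, 97.5])
        row = {"run": int(r), "stat": "choice_prop", "observed": obs_prop,
               "pred_mean": float(props.mean()), "lo": float(lo_p),
               "hi": float(hi_p),
               "covered": bool(lo_p <= obs_prop <= hi_p)}
        rows.append(row)
        for qi, qq in enumerate(_QUANTS):
            lo, hi = np.nanpercentile(qs[:, qi], [2.5, 97.5])
            rows.append({"run": int(r), "stat": f"rt_q{qq:.1f}",
                         "observed": float(obs_q[qi]),
                         "pred_mean": float(np.nanmean(qs[:, qi])),
                         "lo": float(lo), "hi": float(hi),
                         "covered": bool(lo <= obs_q[qi] <= hi)})
    return pd.DataFrame(rows)
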