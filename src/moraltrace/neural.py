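"""Template similarity and inter-subject representational similarity.

Template similarity tracks, run by run, how closely a subject's
multi-voxel activation pattern resembles a canonical (meta-analytic)
reference map restricted to its suprathreshold mask (z > 3.0).  IS-RSA
asks whether subjects who are close in diffusion-parameter space (weights
of relative CR and relative reward) also show similar activation
patterns: a model representational dissimilarity matrix (RDM; pairwise
Euclidean parameter distance) is rank-correlated with a neural RDM
(1 - inter-subject pattern correlation), and significance comes from
jointly permuting the rows and columns of the model RDM.  A positive
Spearman rho therefore means near-in-parameter-space subjects have
similar neural patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from ._utils import substream
from .behavior import StatResult

__all__ = [
    "TemplateMap", "template_similarity", "similarity_trend",
    "model_rdm", "neural_rdm", "isrsa", "ISRSA", "fdr_bh",
]


@dataclass(frozen=True)
class TemplateMap:
    """Reference voxel vector plus its suprathreshold inclusion mask."""

    values: np.ndarray
    z_threshold: float = 3.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.mask.sum() == 0:
            raise ValueError(
                f"no voxels survive z > {self.z_threshold}; empty mask")

    @property
    def mask(self) -> np.ndarray:
        return self.values > self.z_threshold


def template_similarity(pattern: np.ndarray, template: TemplateMap) -> float:
    """Pearson correlation of a pattern with the template inside its mask."""
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != template.values.shape:
        raise ValueError("pattern and template must have equal length")
    m = template.mask
    if m.sum() < 3:
        raise ValueError("need at least 3 masked voxels")
    x, y = pattern[m], template.values[m]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance inside the mask")
    return float(np.corrcoef(x, y)[0, 1])


def similarity_trend(values: pd.DataFrame | np.ndarray) -> StatResult:
    """Linear run-trend test on subject x run similarity values.

    Pools all subject-run observations and regresses on the numeric run
    index (the F(1, n-2) test of the slope); also returns the per-subject
    change score last run minus first run.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a subject x run array with >= 2 runs")
    n_sub, n_run = arr.shape
    runs = np.tile(np.arange(1, n_run + 1, dtype=float), n_sub)
    y = arr.ravel()
    ok = np.isfinite(y)
    runs, y = runs[ok], y[ok]
    X = np.column_stack([np.ones_like(runs), runs])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dfree = len(y) - 2
    s2 = resid @ resid / dfree
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    if s2 < 1e-30:  # degenerate (noise-free) input
        F = 0.0 if abs(coef[1]) < 1e-15 else np.inf
    else:
        F = (coef[1] / se[1]) ** 2
    p = stats.f.sf(F, 1, dfree)
    ss_tot = np.sum((y - y.mean()) ** 2)
    ss_eff = ss_tot - resid @ resid
    eta_p2 = ss_eff / ss_tot if ss_tot > 0 else 0.0
    change = arr[:, -1] - arr[:, 0]
    zc = 1.959963984540054
    return StatResult(
        params={"intercept": float(coef[0]), "slope": float(coef[1])},
        se={"intercept": float(se[0]), "slope": float(se[1])},
        pvalues={"slope": float(p)},
        conf_int={"slope": (float(coef[1] - zc * se[1]),
                            float(coef[1] + zc * se[1]))},
        statistic=float(F), statistic_name=f"F(1, {dfree})",
        statistic_p=float(p), effect_size=float(eta_p2),
        extra={"change_score": change},
    )


def model_rdm(params: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance in the 2-D parameter space."""
    P = np.asarray(params, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("need (n_subjects >= 3, n_params) parameters")
    if not np.all(np.isfinite(P)):
        raise ValueError("missing parameter values")
    diff = P[:, None, :] - P[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def neural_rdm(patterns: np.ndarray) -> np.ndarray:
    """1 - inter-subject Pearson correlation of voxel patterns."""
    X = np.asarray(patterns, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 3:
        raise ValueError("need (n_subjects >= 3, n_voxels >= 3) patterns")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"zero-variance subject rows: {bad}")
    r = np.corrcoef(X)
    out = 1.0 - r
    np.fill_diagonal(out, 0.0)
    return out


class ISRSA:
    """Inter-subject RSA estimator: Spearman rho with a permutation test.

    ``fit(neural, model)`` takes two square RDMs over the same subject
    ordering.  The observed rho correlates the condensed upper triangles;
    the null jointly permutes rows and columns of the model RDM
    ``n_perm`` times.  ``p_`` is the plain proportion of permuted rhos at
    or above the observed one (one-sided), ``p_add_one_`` the
    (1 + exceed) / (1 + n_perm) convention.
    """

    def __init__(self, n_perm: int = 10_000, seed: int = 0,
                 alternative: str = "greater"):
        self.n_perm = n_perm
        self.seed = seed
        self.alternative = alternative

    def get_params(self, deep: bool = True) -> dict:
        return {"n_perm": self.n_perm, "seed": self.seed,
                "alternative": self.alternative}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, neural: np.ndarray, model: np.ndarray) -> "ISRSA":
        N = np.asarray(neural, float)
        M = np.asarray(model, float)
        if N.shape != M.shape or N.ndim != 2 or N.shape[0] != N.shape[1]:
            raise ValueError("RDMs must be square and of equal shape")
        n = N.shape[0]
        iu = np.triu_indices(n, 1)
        nv = N[iu]
        mv = M[iu]
        # Spearman = Pearson on ranks; the rank pattern of the model RDM
        # permutes along with its entries, so rank the square form once.
        n_rank = stats.rankdata(nv)
        m_rank_sq = squareform(stats.rankdata(mv))
        rho_obs = _pearson(n_rank, m_rank_sq[iu])
        rng = substream(self.seed, "isrsa")
        count = 0
        null = np.empty(self.n_perm)
        for b in range(self.n_perm):
            perm = rng.permutation(n)
            mp = m_rank_sq[np.ix_(perm, perm)][iu]
            null[b] = _pearson(n_rank, mp)
        if self.alternative == "greater":
            count = int(np.sum(null >= rho_obs))
        elif self.alternative == "two-sided":
            count = int(np.sum(np.abs(null) >= abs(rho_obs)))
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
        self.rho_ = float(rho_obs)
        self.null_ = null
        self.p_ = count / self.n_perm
        self.p_add_one_ = (1 + count) / (1 + self.n_perm)
        return self


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def isrsa(neural: np.ndarray, model: np.ndarray, n_perm: int = 10_000,
          seed: int = 0, alternative: str = "greater") -> dict:
    """Functional wrapper over :class:`ISRSA`; returns a result dict."""
    est = ISRSA(n_perm=n_perm, seed=seed, alternative=alternative).fit(
        neural, model)
    return {"rho": est.rho_, "p": est.p_, "p_add_one": est.p_add_one_,
            "n_perm": n_perm}


def fdr_bh(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up: (reject flags, monotone q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals
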