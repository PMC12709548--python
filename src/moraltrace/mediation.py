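"""Three-variable mediation: X -> M -> Y with resampled interval estimates.

The model is the classic product-of-coefficients decomposition: path a is
the OLS effect of the predictor on the mediator (m ~ x), path b the effect
of the mediator on the outcome adjusting for the predictor (y ~ x + m),
c' the adjusted direct effect, c the total effect (y ~ x), and the
indirect effect a*b.  For linear paths c = c' + a*b holds exactly.
Uncertainty for the indirect effect comes either from a nonparametric
bootstrap over subjects or from Monte-Carlo sampling of (a, b) from their
estimated sampling distributions; both give percentile 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._utils import substream

__all__ = ["MediationResult", "Mediation", "mediation_fit"]


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci: dict[str, tuple[float, float]]
    se: dict[str, float]
    pvalues: dict[str, float]
    n: int
    method: str
    n_resamples: int


def _ols_paths(x, m, y):
    """Return (a, b, c, cp) and the (se_a, se_b) needed for Monte-Carlo CIs."""
    n = len(x)
    X1 = np.column_stack([np.ones(n), x])
    # m ~ x
    coef_a, res_a, *_ = np.linalg.lstsq(X1, m, rcond=None)
    a = coef_a[1]
    resid_a = m - X1 @ coef_a
    s2a = resid_a @ resid_a / (n - 2)
    cov_a = s2a * np.linalg.inv(X1.T @ X1)
    se_a = np.sqrt(cov_a[1, 1])
    # y ~ x + m
    X2 = np.column_stack([np.ones(n), x, m])
    coef_b, *_ = np.linalg.lstsq(X2, y, rcond=None)
    cp, b = coef_b[1], coef_b[2]
    resid_b = y - X2 @ coef_b
    s2b = resid_b @ resid_b / (n - 3)
    cov_b = s2b * np.linalg.inv(X2.T @ X2)
    se_b = np.sqrt(cov_b[2, 2])
    se_cp = np.sqrt(cov_b[1, 1])
    # y ~ x
    coef_c, *_ = np.linalg.lstsq(X1, y, rcond=None)
    c = coef_c[1]
    resid_c = y - X1 @ coef_c
    s2c = resid_c @ resid_c / (n - 2)
    se_c = np.sqrt((s2c * np.linalg.inv(X1.T @ X1))[1, 1])
    return a, b, c, cp, se_a, se_b, se_c, se_cp


class Mediation:
    """Estimator-style interface around :func:`mediation_fit`.

    Parameters
    ----------
    n_resamples : resamples for the interval estimate (default 5,000).
    method : "bootstrap" (resample subjects) or "montecarlo" (sample a and
        b from their normal sampling distributions).
    seed : integer seed for the resampling stream.
    """

    def __init__(self, n_resamples: int = 5000, method: str = "bootstrap",
                 seed: int = 0):
        self.n_resamples = n_resamples
        self.method = method
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_resamples": self.n_resamples, "method": self.method,
                "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, x, m, y) -> "Mediation":
        x = np.asarray(x, float)
        m = np.asarray(m, float)
        y = np.asarray(y, float)
        n = len(x)
        if n < 10:
            raise ValueError("mediation needs at least 10 subjects")
        if min(np.std(x), np.std(m), np.std(y)) == 0:
            raise ValueError("zero variance in x, m or y")
        if self.method not in ("bootstrap", "montecarlo"):
            raise ValueError(f"unknown method {self.method!r}")

        a, b, c, cp, se_a, se_b, se_c, se_cp = _ols_paths(x, m, y)
        rng = substream(self.seed, "mediation")
        R = int(self.n_resamples)
        if self.method == "bootstrap":
            idx = rng.integers(0, n, size=(R, n))
            ab = np.empty(R)
            a_s = np.empty(R)
            b_s = np.empty(R)
            c_s = np.empty(R)
            cp_s = np.empty(R)
            for r in range(R):
                i = idx[r]
                ar, br, cr, cpr, *_ = _ols_paths(x[i], m[i], y[i])
                a_s[r], b_s[r], c_s[r], cp_s[r] = ar, br, cr, cpr
                ab[r] = ar * br
            ci = {
                "a": _pctl(a_s), "b": _pctl(b_s), "c": _pctl(c_s),
                "c_prime": _pctl(cp_s), "indirect": _pctl(ab),
            }
        else:  # montecarlo on (a, b); analytic normal CIs for the others
            a_s = rng.normal(a, se_a, R)
            b_s = rng.normal(b, se_b, R)
            ab = a_s * b_s
            zc = 1.959963984540054
            ci = {
                "a": (a - zc * se_a, a + zc * se_a),
                "b": (b - zc * se_b, b + zc * se_b),
                "c": (c - zc * se_c, c + zc * se_c),
                "c_prime": (cp - zc * se_cp, cp + zc * se_cp),
                "indirect": _pctl(ab),
            }
        dfree = n - 3
        pvals = {
            "a": 2 * stats.t.sf(abs(a / se_a), n - 2),
            "b": 2 * stats.t.sf(abs(b / se_b), dfree),
            "c": 2 * stats.t.sf(abs(c / se_c), n - 2),
            "c_prime": 2 * stats.t.sf(abs(cp / se_cp), dfree),
        }
        self.result_ = MediationResult(
            a=a, b=b, c=c, c_prime=cp, indirect=a * b, ci=ci,
            se={"a": se_a, "b": se_b, "c": se_c, "c_prime": se_cp},
            pvalues=pvals, n=n, method=self.method, n_resamples=R,
        )
        return self


def _pctl(v, lo=2.5, hi=97.5):
    return (float(np.percentile(v, lo)), float(np.percentile(v, hi)))


def mediation_fit(x, m, y, n_resamples: int = 5000,
                  method: str = "bootstrap", seed: int = 0) -> MediationResult:
    """Functional wrapper over :class:`Mediation`."""
    est = Mediation(n_resamples=n_resamples, method=method, seed=seed)
    return est.fit(x, m, y).result_
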