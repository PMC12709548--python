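"""Hierarchical MCMC for the diffusion-model family.

Subjects are exchangeable draws from group-level normal distributions on
the link scale (identity for drift weights, log for the threshold
intercept/slope handled inside the likelihood, logistic for bias, natural
scale for t0).  Sampling is adaptive Metropolis-within-Gibbs:

* subject parameters update in three blocks (drift weights; threshold and
  bias coefficients; t0) with random-walk proposals whose per-subject,
  per-block scales adapt toward a 30% acceptance rate during burn-in and
  are frozen afterwards;
* group means have conjugate normal full conditionals;
* group SDs (half-normal priors) update by Metropolis on the log scale.

The whole chain runs inside one numba-compiled function; a fit of 20
subjects x 180 trials takes seconds per chain.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .wfpt import wiener_logpdf

__all__ = ["run_chain", "subject_loglik_arrays"]

_NEG_INF = -np.inf


@njit(cache=True)
def _subject_ll(full, R, C, S, H, RT, CH, lo, hi):
    ll = 0.0
    t0 = full[10]
    for i in range(lo, hi):
        s = S[i]
        h = H[i]
        v = (full[0] + full[2] * s) * R[i] + (full[1] + full[3] * s) * C[i] \
            + full[4] * h
        loga = full[5] + full[6] * s
        if loga < -10.0 or loga > 10.0:  # degenerate threshold proposal
            return _NEG_INF
        a = math.exp(loga)
        z = 1.0 / (1.0 + math.exp(-(full[7] + full[8] * s + full[9] * h)))
        if z < 1e-10 or z > 1.0 - 1e-10:
            return _NEG_INF
        lp = wiener_logpdf(RT[i], CH[i] == 1, v, a, z, t0)
        if lp == _NEG_INF:
            return _NEG_INF
        ll += lp
    return ll


def subject_loglik_arrays(full, data, j):
    """Python-side access to the compiled subject log-likelihood."""
    R, C, S, H, RT, CH, starts = data
    return float(_subject_ll(full, R, C, S, H, RT, CH, starts[j], starts[j + 1]))


@njit(cache=True)
def run_chain(R, C, S, H, RT, CH, starts, act, blk, pm, ps,
              n_iter, burn, thin, seed, theta0, mu0, sig0):
    """One MCMC chain; returns (group draws, subject draws, acceptance)."""
    np.random.seed(seed)
    J = starts.size - 1
    K = act.size
    theta = theta0.copy()          # (J, 11) full parameter vectors
    mu = mu0.copy()
    sig = sig0.copy()
    n_blocks = 3
    scale = np.full((J, n_blocks), 0.5)
    asis_scale = np.full(K, 0.1)
    asis_lscale = np.full(K, 0.25)
    acc = np.zeros((J, n_blocks))
    tries = np.zeros((J, n_blocks))

    ll = np.empty(J)
    for j in range(J):
        ll[j] = _subject_ll(theta[j], R, C, S, H, RT, CH,
                            starts[j], starts[j + 1])

    n_keep = max(0, (n_iter - burn + thin - 1) // thin)
    g_draws = np.empty((n_keep, 2 * K))
    s_draws = np.empty((n_keep, J, K))
    keep = 0
    prop = np.empty(11)

    for it in range(n_iter):
        adapt = it < burn
        step = min(0.25, 3.0 / math.sqrt(10.0 + it)) if adapt else 0.0
        for j in range(J):
            for b in range(n_blocks):
                has = False
                for k in range(K):
                    if blk[k] == b:
                        has = True
                        break
                if not has:
                    continue
                for q in range(11):
                    prop[q] = theta[j, q]
                for k in range(K):
                    if blk[k] == b:
                        sd = sig[k] if sig[k] > 0.05 else 0.05
                        prop[act[k]] = theta[j, act[k]] + \
                            scale[j, b] * sd * np.random.standard_normal()
                llp = _subject_ll(prop, R, C, S, H, RT, CH,
                                  starts[j], starts[j + 1])
                accepted = False
                if llp > _NEG_INF:
                    dlp = llp - ll[j]
                    for k in range(K):
                        if blk[k] == b:
                            s2 = 2.0 * sig[k] * sig[k] + 1e-12
                            old = theta[j, act[k]] - mu[k]
                            new = prop[act[k]] - mu[k]
                            dlp += (old * old - new * new) / s2
                    if math.log(np.random.random()) < dlp:
                        for q in range(11):
                            theta[j, q] = prop[q]
                        ll[j] = llp
                        accepted = True
                tries[j, b] += 1.0
                if accepted:
                    acc[j, b] += 1.0
                if adapt:
                    a_ind = 1.0 if accepted else 0.0
                    scale[j, b] *= math.exp(step * (a_ind - 0.3))
                    if scale[j, b] < 1e-3:
                        scale[j, b] = 1e-3
                    elif scale[j, b] > 10.0:
                        scale[j, b] = 10.0

        # group means: conjugate normal; group SDs: Metropolis on log scale
        for k in range(K):
            s2 = sig[k] * sig[k] + 1e-12
            tot = 0.0
            for j in range(J):
                tot += theta[j, act[k]]
            prec = J / s2 + 1.0 / (ps[k] * ps[k])
            mean = (tot / s2 + pm[k] / (ps[k] * ps[k])) / prec
            mu[k] = mean + np.random.standard_normal() / math.sqrt(prec)

            ss = 0.0
            for j in range(J):
                d = theta[j, act[k]] - mu[k]
                ss += d * d
            lam = math.log(sig[k])
            lam_p = lam + 0.3 * np.random.standard_normal()
            sp = math.exp(lam_p)
            if sp < 1e-4:
                sp = 1e-4
                lam_p = math.log(sp)
            # half-normal(1) prior on sigma; +lambda Jacobian for log scale
            lp_old = -J * lam - ss / (2.0 * sig[k] * sig[k]) \
                - sig[k] * sig[k] / 2.0 + lam
            lp_new = -J * lam_p - ss / (2.0 * sp * sp) - sp * sp / 2.0 + lam_p
            if math.log(np.random.random()) < lp_new - lp_old:
                sig[k] = sp

        # interweaved non-centered moves: with the subjects' standardized
        # deviations held fixed, (1) translate the group mean together with
        # every subject value, and (2) rescale every subject's deviation
        # together with the group SD.  These break the funnel that traps
        # the centered sampler when a parameter is weakly identified at
        # the subject level and its group SD is small.  Each move adapts
        # its own proposal scale toward 30% acceptance during burn-in.
        for k in range(K):
            for move in range(it % 2, it % 2 + 1):
                if move == 0:  # translate mu and all theta by delta
                    delta = asis_scale[k] * np.random.standard_normal()
                    ratio = 1.0
                    lam_p = math.log(sig[k])
                    sp = sig[k]
                    mu_p = mu[k] + delta
                else:          # rescale deviations and sigma by e^eps
                    lam = math.log(sig[k])
                    lam_p = lam + asis_lscale[k] * np.random.standard_normal()
                    if lam_p < math.log(1e-4):
                        lam_p = math.log(1e-4)
                    ratio = math.exp(lam_p - lam)
                    sp = math.exp(lam_p)
                    mu_p = mu[k]
                dll = 0.0
                ok = True
                new_ll = np.empty(J)
                for j in range(J):
                    old_val = theta[j, act[k]]
                    theta[j, act[k]] = mu_p + (old_val - mu[k]) * ratio
                    new_ll[j] = _subject_ll(theta[j], R, C, S, H, RT, CH,
                                            starts[j], starts[j + 1])
                    theta[j, act[k]] = old_val
                    if new_ll[j] == _NEG_INF:
                        ok = False
                        break
                    dll += new_ll[j] - ll[j]
                accepted_nc = False
                if ok:
                    # normal prior on mu, half-normal(1) prior on sigma plus
                    # the log-scale Jacobian; the standardized deviations are
                    # held fixed so their N(0,1) density cancels.
                    dmu = ((mu[k] - pm[k]) ** 2 - (mu_p - pm[k]) ** 2) \
                        / (2.0 * ps[k] * ps[k])
                    dlp = dll + dmu - (sp * sp - sig[k] * sig[k]) / 2.0 \
                        + (lam_p - math.log(sig[k]))
                    if math.log(np.random.random()) < dlp:
                        for j in range(J):
                            theta[j, act[k]] = mu_p + (theta[j, act[k]] - mu[k]) * ratio
                            ll[j] = new_ll[j]
                        sig[k] = sp
                        mu[k] = mu_p
                        accepted_nc = True
                if adapt:
                    a_ind = 1.0 if accepted_nc else 0.0
                    if move == 0:
                        asis_scale[k] *= math.exp(step * (a_ind - 0.3))
                        if asis_scale[k] < 1e-3:
                            asis_scale[k] = 1e-3
                        elif asis_scale[k] > 10.0:
                            asis_scale[k] = 10.0
                    else:
                        asis_lscale[k] *= math.exp(step * (a_ind - 0.3))
                        if asis_lscale[k] < 0.02:
                            asis_lscale[k] = 0.02
                        elif asis_lscale[k] > 3.0:
                            asis_lscale[k] = 3.0

        if it >= burn and (it - burn) % thin == 0 and keep < n_keep:
            for k in range(K):
                g_draws[keep, k] = mu[k]
                g_draws[keep, K + k] = sig[k]
            for j in range(J):
                for k in range(K):
                    s_draws[keep, j, k] = theta[j, act[k]]
            keep += 1

    return g_draws[:keep], s_draws[:keep], acc / np.maximum(tries, 1.0)
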