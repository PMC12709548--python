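"""Synthetic neural data with plantable inter-subject structure.

``simulate_roi_patterns`` plants a representational geometry: subjects
close in diffusion-parameter space (weight of relative CR, weight of
relative reward) receive correlated voxel patterns.  The mechanism is a
random-Fourier-feature embedding of the 2-D parameter vector — for voxel
k the signal is cos(omega_k . p + b_k) with omega_k ~ N(0, 1/l^2) — whose
expected inter-subject correlation is the Gaussian kernel
exp(-||dp||^2 / (2 l^2)), i.e. decreasing in parameter distance.  The
``signal`` proportion mixes this embedding with independent voxel noise;
at signal = 0 patterns are pure noise and any inter-subject analysis is
exactly null.

``simulate_roi_timeseries`` draws per-run multivariate Gaussian ROI time
series with a specified latent coupling structure, optionally increasing
specific edges across runs.
"""

from __future__ import annotations

import numpy as np

from .._utils import check_proportion, substream

__all__ = ["simulate_roi_patterns", "simulate_roi_timeseries"]


def simulate_roi_patterns(subject_params: np.ndarray, n_voxels: int = 200,
                          signal: float = 0.8, length_scale: float | None = None,
                          seed: int = 0) -> np.ndarray:
    """Subject x voxel pattern matrix with planted parameter geometry.

    ``subject_params`` is (n_subjects, 2): per subject the fitted weight
    of relative CR and of relative reward.  ``length_scale`` sets the
    kernel width in parameter units; by default it adapts to the
    root-mean-square pairwise distance so the geometry is informative at
    any parameter spread.
    """
    P = np.asarray(subject_params, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("subject_params must be (n_subjects, 2)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    check_proportion(signal=signal)
    rng = substream(seed, "neural-patterns")
    if length_scale is None:
        d = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
        rms = np.sqrt((d ** 2)[np.triu_indices(len(P), 1)].mean())
        length_scale = max(rms, 1e-6)
    omega = rng.standard_normal((2, n_voxels)) / length_scale
    phase = rng.uniform(0, 2 * np.pi, n_voxels)
    shared = np.sqrt(2.0) * np.cos(P @ omega + phase)
    noise = rng.standard_normal((P.shape[0], n_voxels))
    return signal * shared + (1.0 - signal) * noise


def simulate_roi_timeseries(n_rois: int = 9, n_timepoints: int = 200,
                            n_runs: int = 9,
                            coupling: np.ndarray | None = None,
                            coupling_trend: dict | None = None,
                            seed: int = 0) -> np.ndarray:
    """Run x ROI x time array of correlated Gaussian series.

    ``coupling`` is a base latent correlation matrix (identity by
    default); ``coupling_trend`` maps an edge (i, j) to a per-run
    increment added to that edge's latent correlation, so positive
    increments yield a rising sample correlation across runs.
    """
    if n_timepoints < 20:
        raise ValueError("need at least 20 timepoints per run")
    rng = substream(seed, "neural-timeseries")
    base = np.eye(n_rois) if coupling is None else np.asarray(coupling, float)
    if base.shape != (n_rois, n_rois):
        raise ValueError("coupling must be (n_rois, n_rois)")
    out = np.empty((n_runs, n_rois, n_timepoints))
    for r in range(n_runs):
        cov = base.copy()
        if coupling_trend:
            for (i, j), inc in coupling_trend.items():
                cov[i, j] += inc * r
                cov[j, i] += inc * r
        np.fill_diagonal(cov, 1.0)
        eigmin = np.linalg.eigvalsh(cov).min()
        if eigmin <= 1e-10:
            raise ValueError(
                f"target covariance not positive definite at run {r + 1} "
                f"(min eigenvalue {eigmin:.3g})")
        L = np.linalg.cholesky(cov)
        out[r] = L @ rng.standard_normal((n_rois, n_timepoints))
    return out
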