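"""Functional-connectivity graphs and their topological summaries.

Per run, the ROI-by-ROI connectivity matrix is the pairwise Pearson
correlation of the (denoised) ROI time courses, Fisher z-transformed.
For graph metrics the z matrix becomes a weighted undirected graph:
negative edges are zeroed by default (absolute-value weighting is
available), edge length for shortest paths is 1 / weight, global
efficiency is the mean inverse shortest-path length over ordered node
pairs, and betweenness centrality is the normalized fraction of shortest
paths through each node.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import StatResult
from .neural import similarity_trend

__all__ = [
    "ROI_DEFAULT",
    "fc_matrix", "global_efficiency", "betweenness", "run_trend",
    "fc_behavior_correlation",
]

# the nine-region default node set: cognitive control (DLPFC, IFG, ACC),
# self-referential (PCC, bilateral TPJ, precuneus), reward (NAcc, caudate)
ROI_DEFAULT = ["DLPFC", "IFG", "ACC", "PCC", "lTPJ", "rTPJ",
               "NAcc", "caudate", "precuneus"]

_Z_CAP = np.arctanh(1.0 - 1e-7)


def fc_matrix(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity matrix from an ROI x time array."""
    X = np.asarray(timeseries, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (n_rois >= 2, n_time) array")
    if X.shape[1] < 20:
        raise ValueError("need at least 20 timepoints")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"constant series at rows {np.where(sd == 0)[0].tolist()}")
    r = np.corrcoef(X)
    r = np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12)
    z = np.arctanh(r)
    z = np.clip(z, -_Z_CAP, _Z_CAP)
    np.fill_diagonal(z, 0.0)
    return z


def _weights_for_graph(adjacency: np.ndarray, negative: str) -> np.ndarray:
    W = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    if negative == "zero":
        W[W < 0] = 0.0
    elif negative == "abs":
        W = np.abs(W)
    else:
        raise ValueError("negative must be 'zero' or 'abs'")
    return W


def _shortest_paths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with edge length = 1 / weight."""
    import networkx as nx

    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i, dists in nx.all_pairs_dijkstra_path_length(G, weight="length"):
        for j, d in dists.items():
            D[i, j] = d
    return D


def global_efficiency(adjacency: np.ndarray, negative: str = "zero") -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Disconnected pairs contribute zero; with unit edge weights on a
    complete graph the value is 1.
    """
    W = _weights_for_graph(adjacency, negative)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    D = _shortest_paths(W)
    iu = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(D)
    finite = np.isfinite(D) & (D > 0)
    inv[finite] = 1.0 / D[finite]
    return float(inv[iu].mean())


def betweenness(adjacency: np.ndarray, negative: str = "zero") -> np.ndarray:
    """Normalized weighted betweenness centrality per node.

    Shortest paths use edge length 1 / weight; ties split path counts
    equally; normalization is by (n - 1)(n - 2) / 2 for undirected
    graphs.  Fewer than 3 nodes gives all zeros.
    """
    import networkx as nx

    W = _weights_for_graph(adjacency, negative)
    n = W.shape[0]
    if n < 3:
        return np.zeros(n)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(n)])


def run_trend(metric: np.ndarray | pd.DataFrame) -> StatResult:
    """Linear run-trend F-test plus a paired first-vs-last comparison."""
    arr = np.asarray(metric, dtype=float)
    res = similarity_trend(arr)
    first, last = arr[:, 0], arr[:, -1]
    d = last - first
    t, p = stats.ttest_rel(last, first)
    sd = d.std(ddof=1)
    n = len(d)
    zc = stats.t.ppf(0.975, n - 1)
    res.extra["first_vs_last"] = {
        "t": float(t), "p": float(p),
        "mean_diff": float(d.mean()),
        "ci": (float(d.mean() - zc * sd / np.sqrt(n)),
               float(d.mean() + zc * sd / np.sqrt(n))),
    }
    return res


def fc_behavior_correlation(edge_fc: np.ndarray, behavior: np.ndarray) -> dict:
    """Pearson correlation with its Fisher-z 95% confidence interval."""
    x = np.asarray(edge_fc, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need matched vectors with at least 5 subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return {"r": float(r), "p": float(p), "ci": (float(lo), float(hi)), "n": n}
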