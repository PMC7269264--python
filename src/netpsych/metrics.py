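"""Centrality and clustering indices for weighted partial-correlation networks.

Conventions (standard in network psychometrics): edge weights may be
negative, and all indices below use absolute weights — strength sums |w|,
path lengths are 1/|w|, and the weighted clustering formulas are evaluated
on |w|.  Betweenness and closeness operate on shortest paths with edge
length 1/|w| (stronger edges are shorter); closeness is the inverse sum of
distances to reachable nodes, and isolated nodes get closeness 0.

Local clustering is provided in the four classical weighted variants
(Watts-Strogatz on the binarized graph; Barrat; Zhang; Onnela), and the
global coefficient uses the minimum method: each triplet centred on a node
contributes the smaller of its two edge weights, and the coefficient is the
weight of closed triplets over all triplets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.sparse import csr_matrix

__all__ = [
    "strength",
    "shortest_distances",
    "betweenness",
    "closeness",
    "z_standardise",
    "clustering_local",
    "clustering_global_min",
    "node_metrics_table",
    "CENTRALITY_INDICES",
    "CLUSTERING_METHODS",
]

CENTRALITY_INDICES = ("strength", "betweenness", "closeness")
CLUSTERING_METHODS = ("ws", "barrat", "zhang", "onnela")


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


def strength(W: np.ndarray, node: int | None = None):
    """Node strength: sum of absolute edge weights incident to the node."""
    W = _check_weights(W)
    s = np.abs(W).sum(axis=1)
    return s if node is None else float(s[node])


def shortest_distances(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances with edge length 1/|w|.

    Unreachable pairs get +inf; the diagonal is 0.
    """
    W = _check_weights(W)
    A = np.abs(W)
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, 1.0 / A, 0.0)
    return dijkstra(csr_matrix(L), directed=False)


def betweenness(W: np.ndarray) -> np.ndarray:
    """Brandes betweenness with 1/|w| lengths and fractional credit for ties.

    Counts, for each node v, the fraction of shortest s-t paths through v,
    summed over unordered pairs s != t != v.
    """
    import networkx as nx

    W = _check_weights(W)
    p = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0.0:
                G.add_edge(i, j, length=1.0 / abs(W[i, j]))
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[i] for i in range(p)])


def closeness(W: np.ndarray) -> np.ndarray:
    """Inverse sum of shortest distances to all reachable nodes (else 0)."""
    D = shortest_distances(W)
    p = D.shape[0]
    out = np.zeros(p)
    for i in range(p):
        d = D[i]
        reach = np.isfinite(d) & (np.arange(p) != i)
        tot = d[reach].sum()
        out[i] = 1.0 / tot if tot > 0 else 0.0
    return out


def z_standardise(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z-scores with the sample (ddof=1) standard deviation.

    Returns (z, degenerate); an all-equal input yields zeros with the
    degenerate flag set.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardise")
    sd = x.std(ddof=1)
    if sd == 0.0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def clustering_local(W: np.ndarray, method: str = "barrat") -> np.ndarray:
    """Local weighted clustering coefficient, one of ws/barrat/zhang/onnela.

    All variants coincide with the Watts-Strogatz coefficient on 0/1
    weights, and nodes with fewer than two neighbours score 0.
    """
    W = _check_weights(W)
    Wa = np.abs(W)
    A = (Wa > 0).astype(float)
    k = A.sum(axis=1)
    denom_k = k * (k - 1)
    out = np.zeros(W.shape[0])
    valid = k >= 2

    if method == "ws":
        t2 = np.diag(A @ A @ A)  # twice the triangle count per node
        out[valid] = t2[valid] / denom_k[valid]
    elif method == "onnela":
        m = Wa.max(initial=0.0)
        if m > 0:
            C = (Wa / m) ** (1.0 / 3.0)
            t2 = np.diag(C @ C @ C)
            out[valid] = t2[valid] / denom_k[valid]
    elif method == "zhang":
        m = Wa.max(initial=0.0)
        if m > 0:
            Wh = Wa / m
            num = np.diag(Wh @ Wh @ Wh)
            den = Wh.sum(axis=1) ** 2 - (Wh**2).sum(axis=1)
            ok = valid & (den > 0)
            out[ok] = num[ok] / den[ok]
    elif method == "barrat":
        s = Wa.sum(axis=1)
        A2 = A @ A
        contrib = (Wa * A * A2).sum(axis=1)  # sum_j w_ij a_ij (# common nbrs)
        ok = valid & (s > 0)
        out[ok] = contrib[ok] / (s[ok] * (k[ok] - 1))
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return out


def clustering_global_min(W: np.ndarray) -> tuple[float, bool]:
    """Global clustering by the minimum method on absolute weights.

    Every triplet centred at i with edges (i, j), (i, k) contributes
    ``min(|w_ij|, |w_ik|)``; the coefficient is the contribution of closed
    triplets (j-k edge present) over all triplets. Returns (value,
    degenerate); a graph with no triplets scores 0 with the flag set.
    """
    W = _check_weights(W)
    Wa = np.abs(W)
    p = W.shape[0]
    total = 0.0
    closed = 0.0
    for i in range(p):
        nbrs = np.nonzero(Wa[i])[0]
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                j, k = nbrs[a], nbrs[b]
                v = min(Wa[i, j], Wa[i, k])
                total += v
                if Wa[j, k] > 0:
                    closed += v
    if total == 0.0:
        return 0.0, True
    return closed / total, False


def node_metrics_table(W: np.ndarray, labels: list[str] | None = None) -> pd.DataFrame:
    """Per-node centrality and clustering table, raw and z-standardised.

    Columns: the three centralities, their z-scores, and the four local
    clustering variants. The global minimum-method coefficient is attached
    as ``df.attrs["global_clustering_min"]``.
    """
    W = _check_weights(W)
    p = W.shape[0]
    if labels is None:
        labels = [f"V{i + 1}" for i in range(p)]
    data = {
        "strength": strength(W),
        "betweenness": betweenness(W),
        "closeness": closeness(W),
    }
    for name in CENTRALITY_INDICES:
        z, _ = z_standardise(data[name])
        data[f"z_{name}"] = z
    for m in CLUSTERING_METHODS:
        data[f"clustering_{m}"] = clustering_local(W, method=m)
    df = pd.DataFrame(data, index=pd.Index(labels, name="node"))
    g, degenerate = clustering_global_min(W)
    df.attrs["global_clustering_min"] = g
    df.attrs["global_clustering_degenerate"] = degenerate
    return df
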