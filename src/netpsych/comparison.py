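"""Permutation-based comparison of two independently estimated networks (NCT).

Participants are pooled and randomly reassigned to two groups of the
original sizes; both networks are re-estimated per permutation.  Three
invariance statistics are supported:

* structure — M, the maximum absolute edge-weight difference;
* global strength — S, the absolute difference of the summed absolute edge
  weights of each network;
* edges — per-edge absolute weight differences, tested against their own
  permutation distributions and Holm-adjusted across the edges that are
  nonzero in either observed network.

P-values use the add-one convention ``(1 + #{perm >= observed}) / (1 + P)``
and are therefore bounded below by ``1 / (P + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

__all__ = ["NCTResult", "median_split", "global_strength", "nct"]


def median_split(scores: np.ndarray) -> np.ndarray:
    """Labels ``low`` / ``high`` by the sample median (ties go low)."""
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("need a 1-d vector of at least 2 scores")
    med = float(np.median(s))
    if np.all(s == s[0]):
        raise ValueError("all scores identical: median split is degenerate")
    return np.where(s <= med, "low", "high")


def global_strength(W: np.ndarray) -> float:
    """Sum of absolute edge weights over the upper triangle."""
    W = np.asarray(W, dtype=float)
    iu = np.triu_indices(W.shape[0], 1)
    return float(np.abs(W[iu]).sum())


@dataclass
class NCTResult:
    """Observed statistics, permutation nulls and p-values of the NCT."""

    observed_M: float
    observed_S: float
    global_strength_1: float
    global_strength_2: float
    p_M: float
    p_S: float
    perm_M: np.ndarray
    perm_S: np.ndarray
    P: int
    seed: int
    n_dropped: int = 0
    edge_tests: pd.DataFrame | None = None  # per-edge p-values, Holm-adjusted
    weights_1: np.ndarray | None = None
    weights_2: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "observed_M": self.observed_M,
            "observed_S": self.observed_S,
            "global_strength_1": self.global_strength_1,
            "global_strength_2": self.global_strength_2,
            "p_M": self.p_M,
            "p_S": self.p_S,
            "P": self.P,
            "seed": self.seed,
            "n_dropped": self.n_dropped,
        }
        if self.edge_tests is not None:
            d["edge_tests"] = self.edge_tests.to_dict(orient="records")
        return d


def _holm(pvals: np.ndarray) -> np.ndarray:
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def nct(
    X_a: np.ndarray,
    X_b: np.ndarray,
    estimator,
    P: int = 1000,
    seed: int = 0,
    tests: tuple[str, ...] = ("structure", "global_strength"),
    labels: list[str] | None = None,
) -> NCTResult:
    """Network comparison test between two participant groups.

    ``estimator`` is any clone-able object with ``fit(X)`` exposing
    ``partials_`` (typically :class:`~netpsych.ggm.EBICGraphicalLasso`).
    Permutations whose re-estimation fails are dropped and counted; a
    warning is emitted when more than 10% are lost.
    """
    X_a = np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError("both groups must share the same variables")
    if P < 100:
        warnings.warn("P < 100 permutations gives coarse p-values", stacklevel=2)
    n_a, n_b = X_a.shape[0], X_b.shape[0]
    p = X_a.shape[1]
    rng = np.random.default_rng(seed)

    W_a = clone(estimator).fit(X_a).partials_
    W_b = clone(estimator).fit(X_b).partials_
    iu = np.triu_indices(p, 1)
    obs_edge_diff = np.abs(W_a - W_b)[iu]
    obs_M = float(obs_edge_diff.max(initial=0.0))
    gs_a, gs_b = global_strength(W_a), global_strength(W_b)
    obs_S = abs(gs_a - gs_b)

    do_edges = "edges" in tests
    # canonical pooled order + smaller-group-first assignment make the
    # permutation null invariant to which group is passed first
    pooled = np.vstack([X_a, X_b])
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    n = n_a + n_b
    n_first = min(n_a, n_b)
    perm_M = []
    perm_S = []
    perm_edges = [] if do_edges else None
    dropped = 0
    for _ in range(P):
        idx = rng.permutation(n)
        try:
            Wa = clone(estimator).fit(pooled[idx[:n_first]]).partials_
            Wb = clone(estimator).fit(pooled[idx[n_first:]]).partials_
        except Exception:
            dropped += 1
            continue
        diff = np.abs(Wa - Wb)[iu]
        perm_M.append(float(diff.max(initial=0.0)))
        perm_S.append(abs(global_strength(Wa) - global_strength(Wb)))
        if do_edges:
            perm_edges.append(diff)
    if dropped > 0.1 * P:
        warnings.warn(
            f"{dropped}/{P} permutations dropped due to degenerate estimation",
            stacklevel=2,
        )
    perm_M = np.asarray(perm_M)
    perm_S = np.asarray(perm_S)
    P_eff = perm_M.size
    p_M = float((1 + np.sum(perm_M >= obs_M)) / (1 + P_eff))
    p_S = float((1 + np.sum(perm_S >= obs_S)) / (1 + P_eff))

    edge_df = None
    if do_edges:
        perm_edges = np.asarray(perm_edges)  # (P_eff, n_pairs)
        tested = np.nonzero((np.abs(W_a[iu]) > 0) | (np.abs(W_b[iu]) > 0))[0]
        if labels is None:
            labels = [f"V{i + 1}" for i in range(p)]
        rows = []
        praw = np.array(
            [
                (1 + np.sum(perm_edges[:, t] >= obs_edge_diff[t])) / (1 + P_eff)
                for t in tested
            ]
        )
        padj = _holm(praw) if praw.size else praw
        for t, pr, pa in zip(tested, praw, padj):
            rows.append(
                {
                    "source": labels[iu[0][t]],
                    "target": labels[iu[1][t]],
                    "diff": float(obs_edge_diff[t]),
                    "p": float(pr),
                    "p_holm": float(pa),
                }
            )
        edge_df = pd.DataFrame(
            rows, columns=["source", "target", "diff", "p", "p_holm"]
        )

    return NCTResult(
        observed_M=obs_M,
        observed_S=obs_S,
        global_strength_1=gs_a,
        global_strength_2=gs_b,
        p_M=p_M,
        p_S=p_S,
        perm_M=perm_M,
        perm_S=perm_S,
        P=P,
        seed=seed,
        n_dropped=dropped,
        edge_tests=edge_df,
        weights_1=W_a,
        weights_2=W_b,
    )
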