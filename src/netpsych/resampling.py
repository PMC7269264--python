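"""Bootstrap assessment of network stability and edge-weight accuracy.

Centrality stability uses the case-dropping bootstrap: for a grid of drop
proportions, random subsamples of participants are re-estimated end-to-end
and each centrality index is correlated (Pearson) with its full-sample
counterpart.  The CS-coefficient summarizes the result per index: the
largest drop proportion at which — and at every smaller grid proportion —
the empirical 5% quantile of those correlations stays at or above 0.7
(i.e. with 95% confidence the correlation is at least 0.7).  Values below
0.25 flag an unstable index; above 0.5 is considered good.

Edge-weight accuracy uses the ordinary nonparametric bootstrap: rows are
resampled with replacement, the network re-estimated, and per-edge 2.5% /
97.5% percentile bounds reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .metrics import CENTRALITY_INDICES, betweenness, closeness, strength

__all__ = [
    "StabilityResult",
    "EdgeCIResult",
    "DEFAULT_DROP_GRID",
    "case_drop_bootstrap",
    "cs_coefficient",
    "edge_ci_bootstrap",
    "centrality_vectors",
]

DEFAULT_DROP_GRID = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75)


def centrality_vectors(W: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "strength": strength(W),
        "betweenness": betweenness(W),
        "closeness": closeness(W),
    }


@dataclass
class StabilityResult:
    """Case-dropping bootstrap output.

    ``correlations`` is long-format: one row per (proportion, replicate,
    index) holding the Pearson correlation between the subsample and
    full-sample centrality vectors. ``skipped`` lists grid proportions whose
    retained subsample was too small to estimate.
    """

    correlations: pd.DataFrame
    drop_proportions: tuple[float, ...]
    B: int
    seed: int
    n: int
    skipped: tuple[float, ...] = ()
    n_failed: int = 0

    def cs(self, threshold: float = 0.7, confidence: float = 0.95) -> dict[str, float]:
        return cs_coefficient(self, threshold=threshold, confidence=confidence)


@dataclass
class EdgeCIResult:
    """Nonparametric bootstrap percentile intervals for edge weights."""

    edges: pd.DataFrame  # columns: source, target, estimate, boot_mean, lower, upper
    B: int
    seed: int
    n_redrawn: int = 0


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_bootstrap(
    X: np.ndarray,
    estimator,
    grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B: int = 100,
    seed: int = 0,
    min_retained: int | None = None,
) -> StabilityResult:
    """Correlate subsample centralities with the full-sample ones.

    For each drop proportion pi, ``B`` subsamples of ``n - floor(pi n)``
    rows are drawn without replacement, the estimator refit, and each
    centrality index correlated with the full-sample index.  Replicates
    whose estimation fails or yields a constant index are recorded as NaN
    and counted in ``n_failed``; grid points whose retained size falls below
    ``p + 5`` are skipped and flagged.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if min_retained is None:
        min_retained = p + 5
    rng = np.random.default_rng(seed)
    full = clone(estimator).fit(X)
    ref = centrality_vectors(full.partials_)

    rows = []
    skipped = []
    n_failed = 0
    for pi in grid:
        keep = n - int(np.floor(pi * n))
        if keep < min_retained:
            skipped.append(pi)
            continue
        for b in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                est = clone(estimator).fit(X[idx])
                cent = centrality_vectors(est.partials_)
            except Exception:
                n_failed += 1
                for name in CENTRALITY_INDICES:
                    rows.append((pi, b, name, np.nan))
                continue
            for name in CENTRALITY_INDICES:
                r = _safe_corr(ref[name], cent[name])
                if np.isnan(r):
                    n_failed += 1
                rows.append((pi, b, name, r))
    df = pd.DataFrame(rows, columns=["proportion", "replicate", "index", "correlation"])
    return StabilityResult(
        correlations=df,
        drop_proportions=tuple(g for g in grid if g not in skipped),
        B=B,
        seed=seed,
        n=n,
        skipped=tuple(skipped),
        n_failed=n_failed,
    )


def cs_coefficient(
    result: StabilityResult, threshold: float = 0.7, confidence: float = 0.95
) -> dict[str, float]:
    """CS-coefficient per centrality index (monotone-prefix rule).

    The largest grid proportion pi such that at every grid proportion up to
    and including pi the empirical ``1 - confidence`` quantile of the
    replicate correlations is >= ``threshold``; 0 when the smallest grid
    proportion already fails.  Failed replicates (NaN) count against
    stability by being treated as correlation -1.
    """
    df = result.correlations
    if df.empty:
        raise ValueError("empty stability result")
    out: dict[str, float] = {}
    grid = sorted(result.drop_proportions)
    for name in CENTRALITY_INDICES:
        cs = 0.0
        for pi in grid:
            vals = df.loc[
                (df["index"] == name) & (df["proportion"] == pi), "correlation"
            ].to_numpy()
            if vals.size == 0:
                break
            vals = np.where(np.isnan(vals), -1.0, vals)
            q = float(np.quantile(vals, 1.0 - confidence))
            if q >= threshold:
                cs = pi
            else:
                break
        out[name] = cs
    return out


def edge_ci_bootstrap(
    X: np.ndarray,
    estimator,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_redraws: int | None = None,
    labels: list[str] | None = None,
) -> EdgeCIResult:
    """Percentile bootstrap confidence intervals for every edge weight.

    Resamples whose estimation fails (e.g. a constant column) are redrawn,
    up to ``max_redraws`` (default ``10 * B``) in total.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if B < 100:
        warnings.warn("B < 100 gives unreliable percentile intervals", stacklevel=2)
    if max_redraws is None:
        max_redraws = 10 * B
    rng = np.random.default_rng(seed)
    full = clone(estimator).fit(X)
    W0 = full.partials_
    if labels is None:
        labels = [f"V{i + 1}" for i in range(p)]

    iu = np.triu_indices(p, 1)
    boots = np.empty((B, iu[0].size))
    n_redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            est = clone(estimator).fit(X[idx])
        except Exception:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        boots[b] = est.partials_[iu]
        b += 1

    lower = np.quantile(boots, alpha / 2, axis=0)
    upper = np.quantile(boots, 1 - alpha / 2, axis=0)
    df = pd.DataFrame(
        {
            "source": [labels[i] for i in iu[0]],
            "target": [labels[j] for j in iu[1]],
            "estimate": W0[iu],
            "boot_mean": boots.mean(axis=0),
            "lower": lower,
            "upper": upper,
        }
    )
    return EdgeCIResult(edges=df, B=B, seed=seed, n_redrawn=n_redrawn)
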