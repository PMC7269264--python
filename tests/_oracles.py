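"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (exhaustive enumeration, triple
loops, grid searches) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def kendall_tau_b_brute(x, y) -> float:
    """Tau-b by enumerating all pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


def floyd_warshall_brute(W) -> np.ndarray:
    """All-pairs shortest paths on 1/|w| lengths by Floyd-Warshall."""
    W = np.asarray(W, float)
    p = W.shape[0]
    D = np.full((p, p), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(p):
        for j in range(p):
            if i != j and W[i, j] != 0:
                D[i, j] = 1.0 / abs(W[i, j])
    for k in range(p):
        for i in range(p):
            for j in range(p):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def _all_shortest_paths(W, s, t, tol=1e-12):
    """All node sequences realizing the shortest s-t distance (small p only)."""
    W = np.asarray(W, float)
    p = W.shape[0]
    D = floyd_warshall_brute(W)
    if not np.isfinite(D[s, t]):
        return []
    best = D[s, t]
    paths = []

    def length(path):
        return sum(1.0 / abs(W[a, b]) for a, b in zip(path, path[1:]))

    # enumerate simple paths depth-first
    def extend(path):
        u = path[-1]
        if u == t:
            if abs(length(path) - best) <= tol * max(1.0, best):
                paths.append(tuple(path))
            return
        for v in range(p):
            if W[u, v] != 0 and v not in path:
                if length(path) + 1.0 / abs(W[u, v]) <= best * (1 + tol) + tol:
                    extend(path + [v])

    extend([s])
    return paths


def betweenness_brute(W) -> np.ndarray:
    """Fractional-credit betweenness by enumerating all shortest paths."""
    W = np.asarray(W, float)
    p = W.shape[0]
    out = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = _all_shortest_paths(W, s, t)
            if not paths:
                continue
            for v in range(p):
                if v in (s, t):
                    continue
                through = sum(1 for path in paths if v in path)
                out[v] += through / len(paths)
    return out


def closeness_brute(W) -> np.ndarray:
    D = floyd_warshall_brute(W)
    p = D.shape[0]
    out = np.zeros(p)
    for i in range(p):
        d = [D[i, j] for j in range(p) if j != i and np.isfinite(D[i, j])]
        out[i] = 1.0 / sum(d) if d else 0.0
    return out


def strength_brute(W) -> np.ndarray:
    W = np.asarray(W, float)
    p = W.shape[0]
    out = np.zeros(p)
    for i in range(p):
        for j in range(p):
            if i != j:
                out[i] += abs(W[i, j])
    return out


def clustering_brute(W, method) -> np.ndarray:
    """Triple-loop weighted clustering in all four variants."""
    W = np.abs(np.asarray(W, float))
    p = W.shape[0]
    A = (W > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    mx = W.max() if W.max() > 0 else 1.0
    Wh = W / mx
    out = np.zeros(p)
    for i in range(p):
        k = int(A[i].sum())
        if method == "zhang":
            num = den = 0.0
            for j in range(p):
                for h in range(p):
                    if j != i and h != i and j != h:
                        num += Wh[i, j] * Wh[j, h] * Wh[h, i]
                        den += Wh[i, j] * Wh[i, h]
            if den > 0 and k >= 2:
                out[i] = num / den
            continue
        if k < 2:
            continue
        if method == "ws":
            tri = 0.0
            for j in range(p):
                for h in range(p):
                    if j != i and h != i and j != h:
                        tri += A[i, j] * A[i, h] * A[j, h]
            out[i] = tri / (k * (k - 1))
        elif method == "onnela":
            tri = 0.0
            for j in range(p):
                for h in range(p):
                    if j != i and h != i and j != h:
                        tri += (Wh[i, j] * Wh[i, h] * Wh[j, h]) ** (1.0 / 3.0)
            out[i] = tri / (k * (k - 1))
        elif method == "barrat":
            s = W[i].sum()
            acc = 0.0
            for j in range(p):
                for h in range(p):
                    if j != i and h != i and j != h:
                        acc += (W[i, j] + W[i, h]) / 2.0 * A[i, j] * A[i, h] * A[j, h]
            out[i] = acc / (s * (k - 1))
        else:
            raise ValueError(method)
    return out


def global_min_brute(W) -> float:
    W = np.abs(np.asarray(W, float))
    p = W.shape[0]
    total = closed = 0.0
    for i in range(p):
        for j, h in itertools.combinations(range(p), 2):
            if j == i or h == i:
                continue
            if W[i, j] > 0 and W[i, h] > 0:
                v = min(W[i, j], W[i, h])
                total += v
                if W[j, h] > 0:
                    closed += v
    return closed / total if total > 0 else 0.0


def polychoric_grid_oracle(x, y, step=0.01):
    """Grid search over rho maximizing the contingency likelihood."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def thresholds(v):
        vals, counts = np.unique(v, return_counts=True)
        cum = np.cumsum(counts)[:-1] / v.size
        return vals, stats.norm.ppf(cum)

    xv, xt = thresholds(x)
    yv, yt = thresholds(y)
    xi = np.searchsorted(xv, x)
    yi = np.searchsorted(yv, y)
    counts = np.zeros((xv.size, yv.size))
    np.add.at(counts, (xi, yi), 1.0)
    big = 8.5
    a = np.concatenate([[-big], xt, [big]])
    b = np.concatenate([[-big], yt, [big]])

    def loglik(rho):
        mvn = stats.multivariate_normal([0, 0], [[1, rho], [rho, 1]])
        A, B = np.meshgrid(a, b, indexing="ij")
        F = mvn.cdf(np.column_stack([A.ravel(), B.ravel()])).reshape(A.shape)
        P = np.clip(F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1], 1e-300, 1)
        return float(np.sum(counts[counts > 0] * np.log(P[counts > 0])))

    grid = np.arange(-0.99, 0.991, step)
    lls = [loglik(r) for r in grid]
    return float(grid[int(np.argmax(lls))])


def random_weighted_graph(rng, p_max=8, allow_negative=True, density=0.5):
    """Random symmetric weight matrix with zero diagonal, |w| in (0, 1)."""
    p = int(rng.integers(3, p_max + 1))
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                w = rng.uniform(0.05, 0.95)
                if allow_negative and rng.random() < 0.3:
                    w = -w
                W[i, j] = W[j, i] = w
    return W
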