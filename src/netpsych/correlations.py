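"""Correlation estimation for mixed ordinal/continuous/binary variables.

Two routes to a latent correlation matrix are provided:

* ``skeptic`` — the nonparanormal SKEPTIC: Kendall's tau-b for every pair,
  mapped through ``rho = sin(pi * tau / 2)``.  Under a Gaussian copula this
  consistently estimates the latent correlation without any normality
  assumption on the margins, and it is invariant to the monotone
  discretization used for ordinal items.
* ``auto_mixed`` — classical mixed-type dispatch: Pearson for
  continuous-continuous pairs, polychoric for ordinal-ordinal (binary counts
  as 2-level ordinal), polyserial for continuous-ordinal.

Pairwise estimates need not form a positive-definite matrix, so results are
passed through an eigenvalue-clipping repair (:func:`nearest_pd`) before any
graphical-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CorrelationResult",
    "kendall_tau_b",
    "skeptic_transform",
    "polychoric",
    "polyserial",
    "mixed_matrix",
    "nearest_pd",
]

_MIN_EIG = 1e-8
_RHO_BOUND = 0.999


@dataclass
class CorrelationResult:
    """Correlation matrix plus per-pair provenance.

    ``method_map`` holds, for each pair (i, j), the estimator used:
    ``pearson``, ``polychoric``, ``polyserial`` or ``skeptic``.
    ``pd_adjusted`` records whether eigenvalue repair changed the matrix.
    """

    R: np.ndarray
    method_map: np.ndarray  # p x p array of strings, '' on diagonal
    pd_adjusted: bool
    n_effective: int
    labels: list[str] | None = None


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input: tau undefined")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def skeptic_transform(tau):
    """SKEPTIC map ``rho = sin(pi * tau / 2)``, elementwise.

    For a matrix input the diagonal is forced to exactly 1.
    """
    t = np.asarray(tau, dtype=float)
    if np.any(np.abs(t) > 1 + 1e-12):
        raise ValueError("|tau| must not exceed 1")
    r = np.sin(np.pi * np.clip(t, -1.0, 1.0) / 2.0)
    if r.ndim == 2:
        np.fill_diagonal(r, 1.0)
    return r if r.ndim else float(r)


def tau_b_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Kendall tau-b matrix.

    For moderate n the numerator and tie corrections for all pairs come from
    one sign-matrix product (tau_b(i,j) = sum_{a<b} sgn(x_a-x_b)sgn(y_a-y_b)
    / sqrt(U_i U_j) with U the untied pair counts); larger n falls back to
    per-pair O(n log n) estimation.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= 1200:
        S = np.empty((p, n * n), dtype=np.float32)
        for k in range(p):
            S[k] = np.sign(np.subtract.outer(X[:, k], X[:, k])).ravel()
        U = (S != 0).sum(axis=1) / 2.0  # untied pair count per variable
        if np.any(U == 0):
            j = int(np.argmin(U))
            raise ValueError(f"constant column {j}: tau undefined")
        G = (S @ S.T) / 2.0
        T = G / np.sqrt(np.outer(U, U))
        np.fill_diagonal(T, 1.0)
        return np.clip((T + T.T) / 2.0, -1.0, 1.0)
    T = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            T[i, j] = T[j, i] = kendall_tau_b(X[:, i], X[:, j])
    return T


# ---------------------------------------------------------------------------
# polychoric / polyserial


def _ordinal_thresholds(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed categories and interior latent thresholds from the margins."""
    vals, counts = np.unique(codes, return_counts=True)
    if vals.size < 2:
        raise ValueError("ordinal variable with a single observed category")
    cum = np.cumsum(counts)[:-1] / codes.size
    return vals, stats.norm.ppf(cum)


def _bvn_cdf_grid(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate standard normal CDF on the grid a x b (finite entries)."""
    A, B = np.meshgrid(a, b, indexing="ij")
    pts = np.column_stack([A.ravel(), B.ravel()])
    mvn = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True
    )
    return mvn.cdf(pts).reshape(A.shape)


def _cell_probs(a_in: np.ndarray, b_in: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the latent bivariate normal.

    ``a_in`` / ``b_in`` are the interior thresholds of each margin; the grid
    is padded with +-inf (evaluated at +-8.5, beyond double-precision mass).
    """
    big = 8.5
    a = np.concatenate([[-big], np.clip(a_in, -big, big), [big]])
    b = np.concatenate([[-big], np.clip(b_in, -big, big), [big]])
    F = _bvn_cdf_grid(a, b, rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 1e-300, 1.0)


def _contingency(x: np.ndarray, y: np.ndarray):
    xv, xt = _ordinal_thresholds(x)
    yv, yt = _ordinal_thresholds(y)
    xi = np.searchsorted(xv, x)
    yi = np.searchsorted(yv, y)
    counts = np.zeros((xv.size, yv.size))
    np.add.at(counts, (xi, yi), 1.0)
    return counts, xt, yt


def polychoric(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step polychoric correlation between two ordinal variables.

    Thresholds are fixed from the marginal cumulative proportions via the
    inverse normal CDF; rho then maximizes the bivariate-normal contingency
    likelihood on (-0.999, 0.999). Zero-count cells contribute nothing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    counts, xt, yt = _contingency(x, y)

    def nll(rho: float) -> float:
        P = _cell_probs(xt, yt, rho)
        with np.errstate(divide="ignore"):
            logP = np.log(P)
        return -float(np.sum(counts[counts > 0] * logP[counts > 0]))

    res = optimize.minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-5},
    )
    return float(res.x)


def polyserial(
    x: np.ndarray, y: np.ndarray, return_fallback_flag: bool = False
) -> float | tuple[float, bool]:
    """Polyserial correlation between continuous x and ordinal y (ML).

    Thresholds are fixed from y's margins. The conditional likelihood
    ``P(y = k | x)`` of the latent bivariate normal is maximized over rho;
    if the optimization fails, a two-step moment estimator
    (``r_xy * sd(y) / sum(phi(threshold))``) is used instead and flagged
    when ``return_fallback_flag`` is set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("constant continuous variable")
    yv, yt = _ordinal_thresholds(y)
    z = (x - x.mean()) / x.std()
    yi = np.searchsorted(yv, y)
    big = 30.0
    lo = np.concatenate([[-big], yt])[yi]  # lower threshold per observation
    hi = np.concatenate([yt, [big]])[yi]

    def nll(rho: float) -> float:
        s = np.sqrt(1.0 - rho * rho)
        pu = stats.norm.cdf((hi - rho * z) / s)
        pl = stats.norm.cdf((lo - rho * z) / s)
        return -float(np.sum(np.log(np.clip(pu - pl, 1e-300, 1.0))))

    try:
        res = optimize.minimize_scalar(
            nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
            options={"xatol": 1e-5},
        )
        if np.isfinite(res.fun):
            rho = float(res.x)
            return (rho, False) if return_fallback_flag else rho
    except (ValueError, FloatingPointError):  # pragma: no cover - fallback
        pass
    r = np.corrcoef(z, yi)[0, 1]  # two-step moment fallback
    rho = float(
        np.clip(r * np.std(yi) / np.sum(stats.norm.pdf(yt)), -_RHO_BOUND, _RHO_BOUND)
    )
    return (rho, True) if return_fallback_flag else rho


# ---------------------------------------------------------------------------
# full-matrix estimation


def _pair_kind(ki: str, kj: str) -> str:
    cat = ("ordinal", "binary")
    if ki in cat and kj in cat:
        return "polychoric"
    if ki not in cat and kj not in cat:
        return "pearson"
    return "polyserial"


def mixed_matrix(table, mode: str = "skeptic") -> CorrelationResult:
    """Estimate the full correlation matrix of a complete ResponseTable.

    ``skeptic`` applies tau-b + sine transform to every pair; ``auto_mixed``
    dispatches pearson / polychoric / polyserial by the schema kinds. The
    result is always passed through :func:`nearest_pd`.
    """
    if table.missing_mask.any():
        raise ValueError("correlation estimation requires a complete (imputed) table")
    X = table.values
    p = table.p
    kinds = [v.kind for v in table.schema]
    R = np.eye(p)
    methods = np.full((p, p), "", dtype=object)

    if mode == "skeptic":
        R = skeptic_transform(tau_b_matrix(X))
        off = ~np.eye(p, dtype=bool)
        methods[off] = "skeptic"
    elif mode == "auto_mixed":
        for i in range(p):
            for j in range(i + 1, p):
                kind = _pair_kind(kinds[i], kinds[j])
                try:
                    if kind == "pearson":
                        r = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
                    elif kind == "polychoric":
                        r = polychoric(X[:, i], X[:, j])
                    else:
                        xi, yi = (i, j) if kinds[j] in ("ordinal", "binary") else (j, i)
                        r = polyserial(X[:, xi], X[:, yi])
                except ValueError as exc:
                    raise ValueError(
                        f"pair ({table.names[i]}, {table.names[j]}): {exc}"
                    ) from exc
                R[i, j] = R[j, i] = r
                methods[i, j] = methods[j, i] = kind
    else:
        raise ValueError(f"unknown correlation mode {mode!r}")

    R_pd, adjusted = nearest_pd(R, return_adjusted=True)
    return CorrelationResult(
        R=R_pd,
        method_map=methods,
        pd_adjusted=adjusted,
        n_effective=table.n,
        labels=table.names,
    )


def nearest_pd(R: np.ndarray, min_eig: float = _MIN_EIG, return_adjusted: bool = False):
    """Eigenvalue-clipped positive-definite repair with unit diagonal.

    Already-PD input is returned unchanged. Otherwise eigenvalues are clipped
    at ``min_eig`` and the matrix rescaled to unit diagonal, iterating until
    the smallest eigenvalue clears the floor.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    R = (R + R.T) / 2.0
    w = np.linalg.eigvalsh(R)
    if w.min() >= min_eig:
        return (R, False) if return_adjusted else R
    A = R.copy()
    for _ in range(100):
        w, V = np.linalg.eigh(A)
        A = (V * np.clip(w, min_eig, None)) @ V.T
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
        A = (A + A.T) / 2.0
        np.fill_diagonal(A, 1.0)
        if np.linalg.eigvalsh(A).min() >= min_eig * 0.999:
            break
    return (A, True) if return_adjusted else A
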