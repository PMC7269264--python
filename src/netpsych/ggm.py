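"""Sparse Gaussian graphical model estimation: glasso + EBIC selection.

The graphical lasso maximizes the penalized Gaussian log-likelihood

    log det(K) - tr(R K) - lambda * sum_{i != j} |K_ij|

over positive-definite precision matrices K, for a correlation matrix R.
The solver is the Friedman-style block coordinate descent: each column of
the working covariance W is updated by solving a lasso subproblem with
coordinate descent (jit-compiled, warm-started along the penalty path).
The diagonal is not penalized.

Model selection follows the EBIC convention: the penalty lambda runs over a
log-spaced path from the smallest value that empties the network down to
``lambda_min_ratio`` times that value, and the model minimizing

    EBIC = -n [log det K - tr(R K)] + E log n + 4 E gamma log p

is selected, where E counts nonzero upper-triangle precision entries and
gamma (default 0.5) is the sparsity-favouring hyperparameter.  Edge weights
are the partial correlations ``-K_ij / sqrt(K_ii K_jj)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from .correlations import mixed_matrix, nearest_pd

__all__ = [
    "NetworkModel",
    "GlassoConvergenceError",
    "lambda_path",
    "glasso_fit",
    "ebic_score",
    "estimate_network",
    "precision_to_partials",
    "EBICGraphicalLasso",
]

#: absolute partial correlations below this are numerical zeros
EDGE_ZERO_TOL = 1e-10


class GlassoConvergenceError(RuntimeError):
    pass


@dataclass
class NetworkModel:
    """Selected sparse partial-correlation network.

    ``weights`` (W) is the symmetric partial-correlation matrix with zero
    diagonal; ``precision`` the selected precision matrix K; ``edge_count``
    the number of nonzero upper-triangle weights.
    """

    weights: np.ndarray
    precision: np.ndarray
    lambda_selected: float
    gamma: float
    ebic_value: float
    n: int
    labels: list[str] | None = None
    lambdas: np.ndarray | None = None
    ebic_path: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.count_nonzero(self.weights[iu]))


def lambda_path(
    R: np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01
) -> np.ndarray:
    """Descending log-spaced penalty path.

    Starts at ``lambda_max = max |R_ij| (i != j)``, the smallest penalty at
    which the glasso screening rule empties the network, and ends at
    ``lambda_max * min_ratio``.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    off = np.abs(R - np.diag(np.diag(R)))
    lam_max = float(off.max(initial=0.0))
    if lam_max <= 0.0:
        warnings.warn(
            "all off-diagonal correlations are zero: degenerate single-point path",
            stacklevel=2,
        )
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


@njit(cache=True)
def _glasso_cd(S, lam, W, B, max_sweeps, tol, inner_tol):  # pragma: no cover - jit
    """Friedman block coordinate descent. Updates W, B in place.

    W is the working covariance (diagonal fixed at S diagonal, unpenalized);
    B[:, j] holds the lasso coefficients of column j's subproblem.  Returns
    the number of outer sweeps used (max_sweeps + 1 if not converged).
    """
    p = S.shape[0]
    # scale for the convergence criterion: mean |off-diagonal of S|
    s_off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                s_off += abs(S[i, j])
    s_off /= p * (p - 1)
    if s_off <= 0.0:
        s_off = 1.0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            # inner lasso on W11 beta = s12 with L1 penalty
            for _ in range(1000):
                inner_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[l, j]
                    if r > lam:
                        bnew = (r - lam) / W[k, k]
                    elif r < -lam:
                        bnew = (r + lam) / W[k, k]
                    else:
                        bnew = 0.0
                    d = bnew - B[k, j]
                    if d != 0.0:
                        B[k, j] = bnew
                        if abs(d) > inner_delta:
                            inner_delta = abs(d)
                if inner_delta < inner_tol:
                    break
            # w12 = W11 @ beta
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l != j:
                        w += W[k, l] * B[l, j]
                d = w - W[k, j]
                if abs(d) > max_delta:
                    max_delta = abs(d)
                W[k, j] = w
                W[j, k] = w
        if max_delta < tol * s_off:
            return sweep + 1
    return max_sweeps + 1


def _recover_precision(S, W, B):
    p = S.shape[0]
    K = np.zeros_like(W)
    for j in range(p):
        beta = B[:, j].copy()
        beta[j] = 0.0
        denom = W[j, j] - float(W[:, j] @ beta)
        K[j, j] = 1.0 / denom
        K[:, j] -= beta * K[j, j]  # beta_j is 0, so the diagonal is untouched
    # enforce symmetry; supports may disagree by convergence jitter
    K = (K + K.T) / 2.0
    return K


def kkt_residual(K: np.ndarray, R: np.ndarray, lam: float) -> float:
    """Max violation of the glasso stationarity conditions at K."""
    Sigma = np.linalg.inv(K)
    G = Sigma - R
    p = K.shape[0]
    res = np.abs(np.diag(G)).max()
    off = ~np.eye(p, dtype=bool)
    nz = off & (K != 0.0)
    z = off & (K == 0.0)
    if nz.any():
        res = max(res, np.abs(G[nz] - lam * np.sign(K[nz])).max())
    if z.any():
        res = max(res, max(0.0, np.abs(G[z]).max() - lam))
    return float(res)


def glasso_fit(
    R: np.ndarray,
    lam: float,
    *,
    max_sweeps: int = 500,
    tol: float = 1e-6,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    kkt_tol: float = 1e-4,
) -> np.ndarray:
    """Solve the graphical lasso at one penalty value.

    Returns the precision matrix K; raises :class:`GlassoConvergenceError`
    if the KKT residual exceeds ``kkt_tol`` after ``max_sweeps`` sweeps.
    ``warm`` optionally carries (W, B) state from a nearby penalty.
    """
    R = np.asarray(R, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    p = R.shape[0]
    if lam == 0.0:
        # unpenalized limit: exact inverse (R is PD-repaired upstream)
        return np.linalg.inv(nearest_pd(R))
    if warm is None:
        W = R.copy()
        B = np.zeros((p, p))
    else:
        W, B = warm
    _glasso_cd(R, float(lam), W, B, max_sweeps, tol, tol * 1e-2)
    K = _recover_precision(R, W, B)
    if kkt_residual(K, R, lam) > kkt_tol:
        raise GlassoConvergenceError(
            f"glasso did not reach KKT tolerance {kkt_tol} at lambda={lam:.6g}"
        )
    return K


def ebic_score(K: np.ndarray, R: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC of a fitted precision matrix (gamma = 0 gives BIC)."""
    K = np.asarray(K, dtype=float)
    R = np.asarray(R, dtype=float)
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    loglik = logdet - float(np.trace(R @ K))
    iu = np.triu_indices(p, 1)
    E = int(np.count_nonzero(np.abs(K[iu]) > EDGE_ZERO_TOL))
    return float(-n * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def precision_to_partials(K: np.ndarray) -> np.ndarray:
    """Partial correlation weights ``-K_ij / sqrt(K_ii K_jj)``, zero diagonal."""
    K = np.asarray(K, dtype=float)
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("precision matrix must be positive definite")
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < EDGE_ZERO_TOL] = 0.0
    return (W + W.T) / 2.0


def estimate_network(
    R: np.ndarray,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    labels: list[str] | None = None,
) -> NetworkModel:
    """Fit the full penalty path and select the EBIC-minimizing network.

    Ties on the EBIC are resolved toward the sparser (larger-penalty) model,
    which is encountered first on the descending path.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lams = lambda_path(R, n_lambda=n_lambda, min_ratio=lambda_min_ratio)
    W = R.copy()
    B = np.zeros((p, p))
    best = None
    ebics = np.full(lams.size, np.nan)
    for t, lam in enumerate(lams):
        if lam == 0.0:
            K = np.linalg.inv(nearest_pd(R))
        else:
            _glasso_cd(R, float(lam), W, B, 500, 1e-6, 1e-8)
            K = _recover_precision(R, W, B)
            if kkt_residual(K, R, lam) > 1e-4:
                raise GlassoConvergenceError(
                    f"glasso did not converge at lambda={lam:.6g}"
                )
        ebics[t] = ebic_score(K, R, n, gamma)
        if best is None or ebics[t] < best[0]:
            best = (ebics[t], float(lam), K.copy())
    ebic_val, lam_sel, K_sel = best
    return NetworkModel(
        weights=precision_to_partials(K_sel),
        precision=K_sel,
        lambda_selected=lam_sel,
        gamma=gamma,
        ebic_value=float(ebic_val),
        n=n,
        labels=labels,
        lambdas=lams,
        ebic_path=ebics,
    )


class EBICGraphicalLasso(BaseEstimator):
    """EBIC-selected graphical lasso on a mixed-type response matrix.

    A scikit-learn style estimator: ``fit(X)`` computes the configured
    correlation matrix (SKEPTIC by default) and selects the sparse
    partial-correlation network along a log-spaced penalty path by EBIC.

    Parameters
    ----------
    gamma : float, default 0.5
        EBIC sparsity hyperparameter; 0 recovers the plain BIC.
    n_lambda, lambda_min_ratio :
        Penalty-path resolution and lower endpoint (relative to the
        empty-network penalty).
    correlation : {"skeptic", "auto_mixed", "pearson"}
        Input correlation estimator. ``auto_mixed`` requires ``schema``.
    schema : list of VariableSchema, optional
        Variable declarations, needed for ``auto_mixed`` dispatch.

    Attributes
    ----------
    partials_ : ndarray
        Selected partial-correlation weight matrix (zero diagonal).
    precision_ : ndarray
        Selected precision matrix.
    correlation_ : ndarray
        The (PD-repaired) input correlation matrix.
    lambda_, ebic_, edge_count_, lambdas_, ebics_ :
        Selection metadata.
    """

    def __init__(
        self,
        gamma: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        correlation: str = "skeptic",
        schema=None,
    ):
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.correlation = correlation
        self.schema = schema

    def _correlation_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.correlation == "pearson":
            return nearest_pd(np.corrcoef(X, rowvar=False))
        if self.correlation == "skeptic":
            # SKEPTIC is schema-free: rank correlations only
            from .correlations import skeptic_transform, tau_b_matrix

            return nearest_pd(skeptic_transform(tau_b_matrix(X)))
        if self.correlation == "auto_mixed":
            from .schema import ResponseTable

            if self.schema is None:
                raise ValueError("auto_mixed correlation requires a schema")
            table = ResponseTable(
                values=X,
                missing_mask=np.zeros(X.shape, dtype=bool),
                schema=list(self.schema),
            )
            return mixed_matrix(table, mode="auto_mixed").R
        raise ValueError(f"unknown correlation mode {self.correlation!r}")

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("X must be 2-d with at least 3 rows")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute first")
        self.n_features_in_ = X.shape[1]
        R = self._correlation_matrix(X)
        model = estimate_network(
            R,
            n=X.shape[0],
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
        )
        self.correlation_ = R
        self.partials_ = model.weights
        self.precision_ = model.precision
        self.lambda_ = model.lambda_selected
        self.ebic_ = model.ebic_value
        self.edge_count_ = model.edge_count
        self.lambdas_ = model.lambdas
        self.ebics_ = model.ebic_path
        self.model_ = model
        return self

    def fit_correlation(self, R: np.ndarray, n: int) -> "EBICGraphicalLasso":
        """Fit directly from a precomputed correlation matrix."""
        R = nearest_pd(np.asarray(R, dtype=float))
        model = estimate_network(
            R,
            n=n,
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
        )
        self.n_features_in_ = R.shape[0]
        self.correlation_ = R
        self.partials_ = model.weights
        self.precision_ = model.precision
        self.lambda_ = model.lambda_selected
        self.ebic_ = model.ebic_value
        self.edge_count_ = model.edge_count
        self.lambdas_ = model.lambdas
        self.ebics_ = model.ebic_path
        self.model_ = model
        return self
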