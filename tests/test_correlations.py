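from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpsych import (
    ResponseTable,
    VariableSchema,
    kendall_tau_b,
    mixed_matrix,
    nearest_pd,
    polychoric,
    polyserial,
    skeptic_transform,
)
from _oracles import kendall_tau_b_brute, polychoric_grid_oracle


# --- kendall tau-b ----------------------------------------------------------


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 2, 3), (1, 2, 3), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 4.0 / 6.0),  # 5 concordant, 1 discordant
    ],
)
def test_tau_b_examples(x, y, expected):
    assert kendall_tau_b(np.array(x, float), np.array(y, float)) == pytest.approx(
        expected, abs=1e-12
    )


def test_tau_b_matches_brute_force_with_ties(rng):
    for _ in range(25):
        n = int(rng.integers(5, 30))
        x = rng.integers(0, 4, size=n).astype(float)
        y = rng.integers(0, 5, size=n).astype(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            continue
        assert kendall_tau_b(x, y) == pytest.approx(
            kendall_tau_b_brute(x, y), abs=1e-10
        )
        assert kendall_tau_b(x, y) == pytest.approx(kendall_tau_b(y, x))


def test_tau_b_constant_input_errors():
    with pytest.raises(ValueError):
        kendall_tau_b(np.ones(5), np.arange(5.0))


# --- skeptic transform ------------------------------------------------------


@pytest.mark.parametrize("tau, rho", [(0.0, 0.0), (1.0, 1.0), (1.0 / 3.0, 0.5)])
def test_skeptic_identities(tau, rho):
    assert skeptic_transform(tau) == pytest.approx(rho, abs=1e-12)


def test_skeptic_rejects_out_of_range():
    with pytest.raises(ValueError):
        skeptic_transform(1.2)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=-1, max_value=1),
    b=st.floats(min_value=-1, max_value=1),
)
def test_skeptic_is_odd_and_increasing(a, b):
    assert skeptic_transform(-a) == pytest.approx(-skeptic_transform(a), abs=1e-12)
    if a < b:
        assert skeptic_transform(a) < skeptic_transform(b)


def test_skeptic_matrix_diagonal_forced_to_one():
    T = np.array([[0.999, 0.2], [0.2, 0.999]])
    R = skeptic_transform(T)
    assert R[0, 0] == 1.0 and R[1, 1] == 1.0


def test_skeptic_consistency_bivariate_normal():
    """|rho_hat - rho| <= 0.02 at n = 20,000 for rho in {0.3, 0.6, 0.9}."""
    rng = np.random.default_rng(5)
    for rho in (0.3, 0.6, 0.9):
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        Z = rng.standard_normal((20_000, 2)) @ L.T
        est = skeptic_transform(kendall_tau_b(Z[:, 0], Z[:, 1]))
        assert abs(est - rho) <= 0.02


# --- polychoric -------------------------------------------------------------


def _discretize(z, cuts):
    return np.searchsorted(np.asarray(cuts), z)


def test_polychoric_independence_near_zero(rng):
    x = rng.integers(0, 4, size=8000).astype(float)
    y = rng.integers(0, 3, size=8000).astype(float)
    assert abs(polychoric(x, y)) < 0.02 + 3 / np.sqrt(8000)


def test_polychoric_recovers_median_split_normal():
    rng = np.random.default_rng(11)
    rho = 0.5
    L = np.linalg.cholesky([[1, rho], [rho, 1]])
    Z = rng.standard_normal((5000, 2)) @ L.T
    x = _discretize(Z[:, 0], [0.0])
    y = _discretize(Z[:, 1], [0.0])
    est = polychoric(x, y)
    assert 0.45 <= est <= 0.55


def test_polychoric_agrees_with_grid_oracle():
    rng = np.random.default_rng(13)
    rho = -0.4
    L = np.linalg.cholesky([[1, rho], [rho, 1]])
    Z = rng.standard_normal((800, 2)) @ L.T
    x = _discretize(Z[:, 0], [-1.0, 0.0, 1.0])
    y = _discretize(Z[:, 1], [-0.5, 0.5])
    assert abs(polychoric(x, y) - polychoric_grid_oracle(x, y)) <= 0.01


def test_polychoric_single_category_errors():
    with pytest.raises(ValueError):
        polychoric(np.zeros(20), np.tile([0.0, 1.0], 10))


# --- polyserial -------------------------------------------------------------


def test_polyserial_perfect_latent_association():
    rng = np.random.default_rng(17)
    x = rng.standard_normal(5000)
    y = (x > np.median(x)).astype(float)
    assert polyserial(x, y) >= 0.95


def test_polyserial_independence():
    rng = np.random.default_rng(19)
    x = rng.standard_normal(5000)
    y = rng.integers(0, 3, size=5000).astype(float)
    assert abs(polyserial(x, y)) <= 0.05


def test_polyserial_agrees_with_grid_oracle():
    rng = np.random.default_rng(23)
    rho = 0.6
    L = np.linalg.cholesky([[1, rho], [rho, 1]])
    Z = rng.standard_normal((1000, 2)) @ L.T
    x = Z[:, 0]
    y = _discretize(Z[:, 1], [-0.8, 0.2, 1.1]).astype(float)

    def nll(r):
        from scipy import stats

        yv, counts = np.unique(y, return_counts=True)
        cum = np.cumsum(counts)[:-1] / y.size
        yt = stats.norm.ppf(cum)
        z = (x - x.mean()) / x.std()
        yi = np.searchsorted(yv, y)
        lo = np.concatenate([[-30.0], yt])[yi]
        hi = np.concatenate([yt, [30.0]])[yi]
        s = np.sqrt(1 - r * r)
        pr = np.clip(
            __import__("scipy.stats", fromlist=["norm"]).norm.cdf((hi - r * z) / s)
            - __import__("scipy.stats", fromlist=["norm"]).norm.cdf((lo - r * z) / s),
            1e-300,
            1,
        )
        return -np.sum(np.log(pr))

    grid = np.arange(-0.99, 0.991, 0.01)
    oracle = grid[int(np.argmin([nll(r) for r in grid]))]
    assert abs(polyserial(x, y) - oracle) <= 0.01


# --- mixed matrix dispatch --------------------------------------------------


def _table(values, kinds):
    schema = []
    for j, k in enumerate(kinds):
        levels = int(np.nanmax(values[:, j])) + 1 if k == "ordinal" else None
        schema.append(VariableSchema(f"v{j}", k, levels=levels if k == "ordinal" else None))
    return ResponseTable(
        values=values, missing_mask=np.zeros_like(values, bool), schema=schema
    )


def test_all_continuous_dispatches_pearson(rng):
    X = rng.standard_normal((50, 3))
    res = mixed_matrix(_table(X, ["continuous"] * 3), mode="auto_mixed")
    off = ~np.eye(3, dtype=bool)
    assert set(res.method_map[off]) == {"pearson"}


def test_mixed_dispatch_matches_kind_pairs(rng):
    n = 120
    X = np.column_stack(
        [
            rng.standard_normal(n),
            rng.integers(0, 4, n).astype(float),
            rng.integers(0, 2, n).astype(float),
        ]
    )
    t = ResponseTable(
        values=X,
        missing_mask=np.zeros_like(X, bool),
        schema=[
            VariableSchema("c", "continuous"),
            VariableSchema("o", "ordinal", levels=4),
            VariableSchema("b", "binary"),
        ],
    )
    res = mixed_matrix(t, mode="auto_mixed")
    assert res.method_map[0, 1] == "polyserial"
    assert res.method_map[0, 2] == "polyserial"
    assert res.method_map[1, 2] == "polychoric"  # binary = 2-level ordinal
    assert np.allclose(np.diag(res.R), 1.0)


def test_skeptic_matrix_on_multivariate_normal(rng):
    A = rng.standard_normal((6, 6))
    R_true = nearest_pd(np.corrcoef(A @ A.T))
    L = np.linalg.cholesky(R_true)
    X = rng.standard_normal((5000, 6)) @ L.T
    res = mixed_matrix(_table(X, ["continuous"] * 6), mode="skeptic")
    assert np.abs(res.R - R_true).max() <= 0.05
    off = ~np.eye(6, dtype=bool)
    assert set(res.method_map[off]) == {"skeptic"}


def test_mixed_matrix_rejects_missing(tiny_table):
    with pytest.raises(ValueError, match="complete"):
        mixed_matrix(tiny_table)


def test_pair_error_names_variables():
    X = np.column_stack([np.zeros(30), np.tile([0.0, 1.0], 15)])
    t = ResponseTable(
        values=X,
        missing_mask=np.zeros_like(X, bool),
        schema=[
            VariableSchema("allzero", "ordinal", levels=3),
            VariableSchema("ok", "binary"),
        ],
    )
    with pytest.raises(ValueError, match="allzero"):
        mixed_matrix(t, mode="auto_mixed")


# --- PD repair --------------------------------------------------------------


def test_nearest_pd_identity_untouched():
    R, adjusted = nearest_pd(np.eye(4), return_adjusted=True)
    assert not adjusted and np.array_equal(R, np.eye(4))


def test_nearest_pd_repairs_indefinite_matrix():
    R = np.full((3, 3), 0.9)
    np.fill_diagonal(R, 1.0)
    R[0, 1] = R[1, 0] = -0.9
    assert np.linalg.eigvalsh(R).min() < 0
    out, adjusted = nearest_pd(R, return_adjusted=True)
    assert adjusted
    assert np.linalg.eigvalsh(out).min() >= 1e-8 * 0.999
    assert np.allclose(np.diag(out), 1.0)


def test_nearest_pd_keeps_pd_input_exactly(rng):
    A = rng.standard_normal((5, 5))
    S = A @ A.T + 5 * np.eye(5)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    out = nearest_pd(R)
    assert np.abs(out - R).max() < 1e-12


def test_nearest_pd_rejects_asymmetric():
    with pytest.raises(ValueError):
        nearest_pd(np.array([[1.0, 0.2], [0.3, 1.0]]))
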