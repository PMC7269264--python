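from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator

from netpsych import (
    EBICGraphicalLasso,
    case_drop_bootstrap,
    cs_coefficient,
    default_item_spec,
    edge_ci_bootstrap,
    sample_responses,
)
from netpsych.resampling import DEFAULT_DROP_GRID, StabilityResult


class FixedNetworkEstimator(BaseEstimator):
    """Ignores the data; always returns the same weight matrix."""

    def __init__(self, W=None):
        self.W = W

    def fit(self, X, y=None):
        self.partials_ = np.asarray(self.W, dtype=float)
        return self


def fast_estimator(**kw):
    kw.setdefault("n_lambda", 20)
    kw.setdefault("lambda_min_ratio", 0.05)
    return EBICGraphicalLasso(**kw)


@pytest.fixture(scope="module")
def strong_signal_X():
    spec = dataclasses.replace(default_item_spec(n=800, seed=41), missing_rate=0.0)
    return sample_responses(spec).table.values


# --- case-dropping bootstrap ------------------------------------------------


def test_identity_estimator_gives_perfect_correlations(strong_signal_X):
    W = np.zeros((14, 14))
    W[0, 1] = W[1, 0] = 0.5
    W[1, 2] = W[2, 1] = 0.3
    res = case_drop_bootstrap(
        strong_signal_X, FixedNetworkEstimator(W), grid=(0.05, 0.45), B=3, seed=0
    )
    assert np.allclose(res.correlations["correlation"], 1.0)
    assert cs_coefficient(res) == {
        "strength": 0.45,
        "betweenness": 0.45,
        "closeness": 0.45,
    }


def test_zero_drop_proportion_reproduces_original(strong_signal_X):
    res = case_drop_bootstrap(
        strong_signal_X, fast_estimator(), grid=(0.0,), B=2, seed=3
    )
    assert np.allclose(res.correlations["correlation"], 1.0)


def test_bootstrap_is_deterministic(strong_signal_X):
    a = case_drop_bootstrap(strong_signal_X, fast_estimator(), grid=(0.25,), B=2, seed=5)
    b = case_drop_bootstrap(strong_signal_X, fast_estimator(), grid=(0.25,), B=2, seed=5)
    pd.testing.assert_frame_equal(a.correlations, b.correlations)


def test_too_small_retained_sample_is_skipped():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((24, 14))
    res = case_drop_bootstrap(
        X, FixedNetworkEstimator(np.zeros((14, 14))), grid=(0.05, 0.75), B=1, seed=0
    )
    assert 0.75 in res.skipped
    assert res.drop_proportions == (0.05,)


def test_stability_degrades_with_drop_proportion(strong_signal_X):
    res = case_drop_bootstrap(
        strong_signal_X, fast_estimator(), grid=(0.25, 0.75), B=10, seed=7
    )
    df = res.correlations
    mean_at = lambda pi: df.loc[
        (df["index"] == "strength") & (df["proportion"] == pi), "correlation"
    ].mean()
    assert mean_at(0.25) > mean_at(0.75)


# --- CS coefficient ---------------------------------------------------------


def _stability_fixture(corr_by_prop, B=20):
    rows = []
    for pi, c in corr_by_prop.items():
        for b in range(B):
            for name in ("strength", "betweenness", "closeness"):
                rows.append((pi, b, name, c))
    df = pd.DataFrame(rows, columns=["proportion", "replicate", "index", "correlation"])
    return StabilityResult(
        correlations=df,
        drop_proportions=tuple(sorted(corr_by_prop)),
        B=B,
        seed=0,
        n=400,
    )


def test_cs_all_perfect_reaches_grid_maximum():
    res = _stability_fixture({pi: 1.0 for pi in DEFAULT_DROP_GRID})
    assert cs_coefficient(res)["strength"] == 0.75


def test_cs_always_below_threshold_is_zero():
    res = _stability_fixture({pi: 0.5 for pi in DEFAULT_DROP_GRID})
    assert cs_coefficient(res)["strength"] == 0.0


def test_cs_monotone_prefix_rule():
    corr = {pi: (0.9 if pi <= 0.25 else 0.6) for pi in DEFAULT_DROP_GRID}
    res = _stability_fixture(corr)
    assert cs_coefficient(res)["strength"] == 0.25


def test_cs_prefix_rule_ignores_later_recovery():
    # passes at 0.05, fails at 0.15, "passes" again later: CS stays 0.05
    corr = dict.fromkeys(DEFAULT_DROP_GRID, 0.9)
    corr[0.15] = 0.2
    res = _stability_fixture(corr)
    assert cs_coefficient(res)["strength"] == 0.05


def test_failed_replicates_count_against_stability():
    res = _stability_fixture({0.05: 1.0})
    res.correlations.loc[
        res.correlations["proportion"] == 0.05, "correlation"
    ] = np.nan
    assert cs_coefficient(res)["strength"] == 0.0


# --- edge-weight bootstrap --------------------------------------------------


def test_single_replicate_bounds_equal_that_replicate(strong_signal_X):
    with pytest.warns(UserWarning, match="B < 100"):
        res = edge_ci_bootstrap(strong_signal_X[:100], fast_estimator(), B=1, seed=11)
    assert np.allclose(res.edges["lower"], res.edges["upper"])
    assert np.allclose(res.edges["lower"], res.edges["boot_mean"])


def test_edge_ci_deterministic(strong_signal_X):
    X = strong_signal_X[:150]
    with pytest.warns(UserWarning):
        a = edge_ci_bootstrap(X, fast_estimator(), B=5, seed=13)
        b = edge_ci_bootstrap(X, fast_estimator(), B=5, seed=13)
    pd.testing.assert_frame_equal(a.edges, b.edges)


def test_edge_ci_orders_bounds_and_covers_strong_edges(strong_signal_X):
    res = edge_ci_bootstrap(
        strong_signal_X,
        fast_estimator(),
        B=120,
        seed=17,
        labels=default_item_spec().item_names,
    )
    assert (res.edges["lower"] <= res.edges["upper"] + 1e-12).all()
    # the understanding-domain edge (true partial 0.89) is far from zero
    row = res.edges.query("source == 'UND1' and target == 'UND2'")
    assert float(row["lower"].iloc[0]) > 0.4


def test_cs_non_decreasing_in_sample_size():
    """Doubling n on synthetic data never lowers the median strength-CS."""
    from netpsych import SyntheticSpec

    def median_cs(n):
        vals = []
        for seed in range(5):
            spec = SyntheticSpec(
                p_items=6,
                domains=((0, 1), (2, 3), (4, 5)),
                within_domain_partial=(0.6, 0.7, 0.5),
                item_kind="continuous",
                missing_rate=0.0,
                n=n,
                seed=300 + seed,
            )
            X = sample_responses(spec).table.values
            res = case_drop_bootstrap(
                X, fast_estimator(correlation="pearson"), B=10, seed=seed
            )
            vals.append(cs_coefficient(res)["strength"])
        return np.median(vals)

    assert median_cs(300) >= median_cs(150)


class UnregularizedPartials(BaseEstimator):
    """Partial correlations from the inverted Pearson correlation matrix."""

    def fit(self, X, y=None):
        from netpsych import precision_to_partials

        R = np.corrcoef(np.asarray(X, float), rowvar=False)
        self.partials_ = precision_to_partials(np.linalg.inv(R))
        return self


def _coverage_spec():
    from netpsych import SyntheticSpec

    return SyntheticSpec(
        p_items=6,
        domains=((0, 1), (2, 3), (4, 5)),
        within_domain_partial=(0.7, 0.4, 0.5),
        item_kind="continuous",
        missing_rate=0.0,
        n=1000,
    )


def test_edge_ci_covers_truth_for_unbiased_estimator():
    """Percentile CIs around an unregularized partial-correlation estimator
    cover a true 0.7 partial in most outer replications (the bootstrap
    machinery is estimator-agnostic)."""
    spec = _coverage_spec()
    covered = 0
    outer = 8
    for seed in range(outer):
        s = sample_responses(dataclasses.replace(spec, seed=100 + seed))
        res = edge_ci_bootstrap(s.table.values, UnregularizedPartials(), B=150, seed=seed)
        row = res.edges.query("source == 'V1' and target == 'V2'")
        if float(row["lower"].iloc[0]) <= 0.7 <= float(row["upper"].iloc[0]):
            covered += 1
    assert covered >= int(0.8 * outer)


def test_edge_ci_of_regularized_estimator_reflects_shrinkage():
    """Under EBIC-glasso the bootstrap interval tracks the penalized
    estimator and therefore sits at or below the generating partial: the
    interval must not lie wholly above the truth."""
    spec = _coverage_spec()
    s = sample_responses(dataclasses.replace(spec, seed=200))
    res = edge_ci_bootstrap(
        s.table.values, fast_estimator(correlation="pearson"), B=100, seed=0
    )
    row = res.edges.query("source == 'V1' and target == 'V2'")
    assert float(row["lower"].iloc[0]) <= 0.7
    assert float(row["upper"].iloc[0]) <= 0.75  # shrinkage keeps it near/below
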