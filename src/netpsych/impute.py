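"""Nonparametric single imputation for mixed-type response tables.

The default is an iterative random-forest scheme in the missForest style:
initialize missing cells with the column mode (categorical) or median
(continuous), then cycle through columns in order of increasing
missingness, re-predicting each column's missing cells from all others with
a random forest (classifier for ordinal/binary, regressor for continuous).
Iteration stops when the change criterion — scaled sum of squared changes
over continuous cells plus disagreement fraction over categorical cells —
first increases, returning the previous iteration's values, or when
``max_iter`` is reached.

Simpler alternatives: k-nearest-neighbour imputation (continuous-space,
rounded back to valid codes for categorical columns) and plain mode/median
fill.  Observed cells are never modified by any method.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.impute import KNNImputer

from .schema import ResponseTable

__all__ = ["impute"]


def _mode(values: np.ndarray) -> float:
    vals, counts = np.unique(values, return_counts=True)
    return float(vals[np.argmax(counts)])  # smallest code wins ties


def _init_fill(table: ResponseTable) -> np.ndarray:
    X = table.values.copy()
    for j, var in enumerate(table.schema):
        miss = table.missing_mask[:, j]
        if not miss.any():
            continue
        obs = X[~miss, j]
        X[miss, j] = _mode(obs) if var.is_categorical else float(np.median(obs))
    return X


def _clip_codes(X: np.ndarray, table: ResponseTable) -> np.ndarray:
    for j, var in enumerate(table.schema):
        if var.is_categorical:
            miss = table.missing_mask[:, j]
            X[miss, j] = np.clip(np.round(X[miss, j]), 0, var.levels - 1)
    return X


def _forest_impute(
    table: ResponseTable, max_iter: int, seed: int, n_estimators: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    mask = table.missing_mask
    X = _init_fill(table)
    cols = [j for j in range(table.p) if mask[:, j].any()]
    cols.sort(key=lambda j: mask[:, j].sum())  # least missing first
    cont = [j for j in cols if not table.schema[j].is_categorical]
    cat = [j for j in cols if table.schema[j].is_categorical]

    prev = X.copy()
    prev_crit = np.inf
    for _ in range(max_iter):
        for j in cols:
            miss = mask[:, j]
            other = [k for k in range(table.p) if k != j]
            Xo = X[:, other]
            y = X[~miss, j]
            rs = int(rng.integers(0, 2**31 - 1))
            if table.schema[j].is_categorical:
                if np.unique(y).size < 2:
                    X[miss, j] = y[0]
                    continue
                model = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=rs, n_jobs=1
                )
                model.fit(Xo[~miss], y.astype(int))
                X[miss, j] = model.predict(Xo[miss])
            else:
                model = RandomForestRegressor(
                    n_estimators=n_estimators, random_state=rs, n_jobs=1
                )
                model.fit(Xo[~miss], y)
                X[miss, j] = model.predict(Xo[miss])
        # change criterion between successive iterations
        crit = 0.0
        if cont:
            num = sum(float(((X[mask[:, j], j] - prev[mask[:, j], j]) ** 2).sum()) for j in cont)
            den = sum(float((X[mask[:, j], j] ** 2).sum()) for j in cont)
            crit += num / den if den > 0 else 0.0
        if cat:
            chg = sum(int((X[mask[:, j], j] != prev[mask[:, j], j]).sum()) for j in cat)
            tot = sum(int(mask[:, j].sum()) for j in cat)
            crit += chg / tot if tot > 0 else 0.0
        if crit >= prev_crit:
            return prev  # criterion rose: keep the previous iteration
        prev = X.copy()
        prev_crit = crit
        if crit == 0.0:
            break
    return X


def impute(
    table: ResponseTable,
    method: str = "forest",
    max_iter: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
    n_neighbors: int = 5,
) -> ResponseTable:
    """Return a complete copy of ``table`` with missing cells filled.

    ``method`` is one of ``forest`` (iterative random forest), ``knn`` or
    ``mode_median``. Deterministic given ``seed``; ordinal imputations are
    always valid codes; observed cells are returned untouched.
    """
    mask = table.missing_mask
    for j in range(table.p):
        if mask[:, j].all():
            raise ValueError(f"column {table.names[j]!r} is fully missing")
    if not mask.any():
        return table.copy()

    if method == "mode_median":
        X = _init_fill(table)
    elif method == "knn":
        if table.n < 10:
            raise ValueError("knn imputation needs n >= 10")
        X = KNNImputer(n_neighbors=n_neighbors).fit_transform(table.values)
        X = _clip_codes(X, table)
    elif method == "forest":
        if table.n < 10:
            raise ValueError("forest imputation needs n >= 10")
        X = _forest_impute(table, max_iter=max_iter, seed=seed, n_estimators=n_estimators)
    else:
        raise ValueError(f"unknown imputation method {method!r}")

    # observed cells are authoritative
    X[~mask] = table.values[~mask]
    return ResponseTable(
        values=X, missing_mask=np.zeros_like(mask), schema=list(table.schema)
    )
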