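"""Typed questionnaire data model and file I/O.

Questionnaire variables are declared as ``ordinal`` (integer codes
``0 .. levels-1``), ``continuous``, or ``binary`` (treated as a 2-level
ordinal for correlation dispatch).  A :class:`ResponseTable` couples the
numeric response matrix with its schema and an explicit missingness mask,
so that every downstream stage (imputation, correlation dispatch, network
estimation) can rely on validated types.

File conventions: comma-separated UTF-8 CSV with ``.`` decimal separator and
empty string for missing; the schema is a JSON list of variable records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableSchema",
    "ResponseTable",
    "NetworkGraph",
    "SchemaError",
    "ValidationError",
    "read_responses",
    "write_responses",
    "read_schema",
    "write_schema",
    "read_network",
    "write_network",
    "auto_kind",
]

VariableKind = Literal["ordinal", "continuous", "binary"]

#: distinct integer values at or below which a column is auto-detected ordinal
ORDINAL_AUTO_MAX_LEVELS = 7


class SchemaError(ValueError):
    """A variable declaration is inconsistent or does not match the data."""


class ValidationError(ValueError):
    """Response values violate their declared variable schema."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one questionnaire variable.

    Parameters
    ----------
    name : str
        Unique column label.
    kind : {"ordinal", "continuous", "binary"}
        Measurement type. Binary variables behave as 2-level ordinals.
    levels : int, optional
        Number of ordered categories; required for ordinal (>= 2), forced to
        2 for binary, and must be omitted for continuous variables.
    role : str
        Free tag, conventionally ``item``, ``covariate`` or ``grouping``.
    """

    name: str
    kind: VariableKind
    levels: int | None = None
    role: str = "item"

    def __post_init__(self) -> None:
        if self.kind not in ("ordinal", "continuous", "binary"):
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "ordinal":
            if self.levels is None or self.levels < 2:
                raise SchemaError(f"{self.name}: ordinal variables need levels >= 2")
        elif self.kind == "binary":
            if self.levels not in (None, 2):
                raise SchemaError(f"{self.name}: binary variables have exactly 2 levels")
            object.__setattr__(self, "levels", 2)
        elif self.levels is not None:
            raise SchemaError(f"{self.name}: continuous variables take no levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind in ("ordinal", "binary")

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "role": self.role}
        if self.levels is not None:
            d["levels"] = self.levels
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        return cls(
            name=d["name"],
            kind=d["kind"],
            levels=d.get("levels"),
            role=d.get("role", "item"),
        )


def _check_unique_names(schema: Sequence[VariableSchema]) -> None:
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate variable names: {dupes}")


@dataclass
class ResponseTable:
    """Participant x variable response matrix with typed columns.

    ``values`` is float, with ``nan`` at masked (missing) cells; the mask is
    authoritative: ``missing_mask[i, j]`` is True iff the value is absent.
    Ordinal/binary codes are integers in ``[0, levels - 1]`` where observed.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    schema: list[VariableSchema]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-dimensional")
        if self.values.shape != self.missing_mask.shape:
            raise ValidationError("values and missing_mask shapes differ")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValidationError(f"need n >= 2 and p >= 2, got {n} x {p}")
        if p != len(self.schema):
            raise ValidationError(
                f"schema declares {len(self.schema)} variables, data has {p} columns"
            )
        _check_unique_names(self.schema)
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan
        self._validate_codes()

    def _validate_codes(self) -> None:
        bad: list[str] = []
        for j, var in enumerate(self.schema):
            if not var.is_categorical:
                continue
            col = self.values[:, j]
            obs = ~self.missing_mask[:, j]
            vals = col[obs]
            off = obs.nonzero()[0]
            not_int = vals != np.round(vals)
            out_of_range = (vals < 0) | (vals > var.levels - 1)
            for i in off[(not_int | out_of_range)][:5]:
                bad.append(f"row {i}, column {var.name!r}: {col[i]!r}")
        if bad:
            raise ValidationError(
                "ordinal codes outside [0, levels-1]: " + "; ".join(bad)
            )
        if np.isnan(self.values[~self.missing_mask]).any():
            raise ValidationError("NaN present at cells not flagged missing")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.schema]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def select(self, names: Sequence[str]) -> "ResponseTable":
        """Sub-table restricted to the given variables, in the given order."""
        idx = [self.names.index(n) for n in names]
        return ResponseTable(
            values=self.values[:, idx],
            missing_mask=self.missing_mask[:, idx],
            schema=[self.schema[i] for i in idx],
        )

    def take_rows(self, rows: np.ndarray) -> "ResponseTable":
        return ResponseTable(
            values=self.values[rows],
            missing_mask=self.missing_mask[rows],
            schema=list(self.schema),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def copy(self) -> "ResponseTable":
        return ResponseTable(
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            schema=list(self.schema),
        )


def read_schema(path: str | Path) -> list[VariableSchema]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    schema = [VariableSchema.from_dict(d) for d in raw]
    _check_unique_names(schema)
    return schema


def write_schema(schema: Sequence[VariableSchema], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([v.to_dict() for v in schema], fh, indent=2)
        fh.write("\n")


def read_responses(path_csv: str | Path, path_schema: str | Path) -> ResponseTable:
    """Read a response CSV against a JSON variable schema.

    Every CSV column must be declared in the schema and vice versa; empty
    cells become missing; ordinal codes are validated against their declared
    level count with offending row/column reported.
    """
    schema = read_schema(path_schema)
    df = pd.read_csv(path_csv, sep=",", encoding="utf-8")
    declared = [v.name for v in schema]
    unknown = [c for c in df.columns if c not in declared]
    if unknown:
        raise SchemaError(f"CSV columns absent from schema: {unknown}")
    absent = [n for n in declared if n not in df.columns]
    if absent:
        raise SchemaError(f"schema variables absent from CSV: {absent}")
    df = df[declared]
    values = df.to_numpy(dtype=float)
    mask = np.isnan(values)
    return ResponseTable(values=values, missing_mask=mask, schema=schema)


def write_responses(
    table: ResponseTable, path_csv: str | Path, path_schema: str | Path | None = None
) -> None:
    """Write a ResponseTable as CSV (empty string at missing cells)."""
    df = table.to_dataframe().copy()
    for j, var in enumerate(table.schema):
        if var.is_categorical:
            col = df.iloc[:, j]
            df.isetitem(j, col.astype("Int64"))
    df.to_csv(path_csv, index=False, na_rep="")
    if path_schema is not None:
        write_schema(table.schema, path_schema)


# ---------------------------------------------------------------------------
# network graph view


@dataclass
class NetworkGraph:
    """Serializable weighted-network view.

    ``weights`` is the symmetric partial-correlation matrix with zero
    diagonal and entries in [-1, 1]. ``display_min`` / ``display_max`` are
    visualization metadata only: the minimum absolute weight drawn and the
    weight mapped to maximum line thickness. They never affect estimation or
    metrics.
    """

    labels: list[str]
    weights: np.ndarray
    display_min: float = 0.04
    display_max: float = 0.76
    layout: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValidationError("weight matrix must be square")
        if W.shape[0] != len(self.labels):
            raise ValidationError("labels do not match weight matrix size")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValidationError("weight matrix must be symmetric")
        if np.abs(np.diag(W)).max(initial=0.0) != 0.0:
            raise ValidationError("weight matrix diagonal must be exactly zero")
        if np.abs(W).max(initial=0.0) > 1.0 + 1e-12:
            raise ValidationError("edge weights must lie in [-1, 1]")
        self.weights = (W + W.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)
        if self.layout is not None:
            self.layout = np.asarray(self.layout, dtype=float)
            if self.layout.shape != (len(self.labels), 2):
                raise ValidationError("layout must be p x 2")

    @property
    def p(self) -> int:
        return len(self.labels)

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero edges as (source, target, weight), i < j order."""
        out = []
        W = self.weights
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if W[i, j] != 0.0:
                    out.append((self.labels[i], self.labels[j], float(W[i, j])))
        return out


def write_network(graph: NetworkGraph, path: str | Path, format: str = "json") -> None:
    """Write a network in ``edge_list_csv``, ``graphml`` or ``json`` format."""
    path = Path(path)
    if format == "edge_list_csv":
        rows = graph.edges()
        df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "graphml":
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(graph.labels)
        for s, t, w in graph.edges():
            G.add_edge(s, t, weight=float(w))
        G.graph["display_min"] = float(graph.display_min)
        G.graph["display_max"] = float(graph.display_max)
        nx.write_graphml(G, path)
    elif format == "json":
        doc = {
            "labels": graph.labels,
            "weights": [[float(w) for w in row] for row in graph.weights],
            "display_min": float(graph.display_min),
            "display_max": float(graph.display_max),
            "layout": None
            if graph.layout is None
            else [[float(x) for x in row] for row in graph.layout],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
            fh.write("\n")
    else:
        raise ValueError(f"unsupported network format: {format!r}")


def read_network(
    path: str | Path, format: str = "json", labels: Sequence[str] | None = None
) -> NetworkGraph:
    """Read a network written by :func:`write_network`.

    ``edge_list_csv`` and ``graphml`` store only nonzero edges, so ``labels``
    may be passed to recover isolated nodes and node order; GraphML keeps
    node order of insertion.
    """
    path = Path(path)
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return NetworkGraph(
            labels=list(doc["labels"]),
            weights=np.asarray(doc["weights"], dtype=float),
            display_min=doc.get("display_min", 0.04),
            display_max=doc.get("display_max", 0.76),
            layout=None if doc.get("layout") is None else np.asarray(doc["layout"]),
        )
    if format == "edge_list_csv":
        df = pd.read_csv(path)
        if labels is None:
            labels = sorted(set(df["source"]) | set(df["target"]))
        labels = list(labels)
        idx = {l: i for i, l in enumerate(labels)}
        W = np.zeros((len(labels), len(labels)))
        for s, t, w in df.itertuples(index=False):
            W[idx[s], idx[t]] = W[idx[t], idx[s]] = float(w)
        return NetworkGraph(labels=labels, weights=W)
    if format == "graphml":
        import networkx as nx

        G = nx.read_graphml(path)
        if labels is None:
            labels = list(G.nodes())
        labels = list(labels)
        idx = {l: i for i, l in enumerate(labels)}
        W = np.zeros((len(labels), len(labels)))
        for s, t, data in G.edges(data=True):
            w = float(data["weight"])
            W[idx[s], idx[t]] = W[idx[t], idx[s]] = w
        return NetworkGraph(
            labels=labels,
            weights=W,
            display_min=float(G.graph.get("display_min", 0.04)),
            display_max=float(G.graph.get("display_max", 0.76)),
        )
    raise ValueError(f"unsupported network format: {format!r}")


def auto_kind(column: np.ndarray) -> str:
    """Classify a numeric column as ordinal or continuous.

    A column is ordinal iff all observed values are integers and there are at
    most 7 distinct observed values (the convention of automatic mixed
    correlation routines); otherwise continuous. An explicit schema
    declaration always overrides this detection.
    """
    col = np.asarray(column, dtype=float)
    vals = np.unique(col[~np.isnan(col)])
    if vals.size < 2:
        raise ValidationError("constant column: no correlation defined")
    all_int = bool(np.all(vals == np.round(vals)))
    if all_int and vals.size <= ORDINAL_AUTO_MAX_LEVELS:
        return "ordinal"
    return "continuous"
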