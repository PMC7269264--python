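"""End-to-end four-network analysis pipeline.

Given a mixed-type response table whose items carry role ``item``, the
pipeline (1) imputes missing cells, (2) estimates the items-only network,
(3) the items-plus-covariates network, and (4)-(5) the networks of the
participant groups below/above the median total item score, then runs the
permutation comparison between the two group networks.  Per network it
writes the metrics table (centralities raw and z-scored, the four local
clustering variants, the global minimum-method coefficient), graph exports
(JSON / GraphML / edge-list CSV) and a force-directed layout.  Stability
and edge-accuracy bootstraps run on request.

All randomness flows from a single seed via ``numpy.random.SeedSequence``
spawning, so identical configuration gives byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .comparison import median_split, nct
from .ggm import EBICGraphicalLasso
from .impute import impute
from .metrics import node_metrics_table
from .resampling import case_drop_bootstrap, cs_coefficient, edge_ci_bootstrap
from .schema import NetworkGraph, ResponseTable, write_network

logger = logging.getLogger("netpsych")

__all__ = [
    "AnalysisConfig",
    "cronbach_alpha",
    "fruchterman_reingold",
    "run_four_networks",
]


@dataclass
class AnalysisConfig:
    """Settings of the four-network pipeline.

    ``display_min`` / ``display_max`` (defaults 0.04 / 0.76) are attached to
    the exported graphs as visualization metadata: the minimum absolute
    weight drawn and the weight mapped to maximum edge thickness. They never
    affect estimation or metrics.
    """

    correlation: str = "skeptic"  # skeptic | auto_mixed | pearson
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    imputation: str = "forest"  # forest | knn | mode_median | none
    impute_max_iter: int = 10
    stability_B: int = 0  # 0 disables the case-dropping bootstrap
    stability_grid: tuple[float, ...] = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75)
    edge_accuracy_B: int = 0  # 0 disables the edge bootstrap
    nct_P: int = 1000
    nct_tests: tuple[str, ...] = ("structure", "global_strength", "edges")
    seed: int = 0
    display_min: float = 0.04
    display_max: float = 0.76

    def __post_init__(self) -> None:
        if self.nct_P < 1:
            raise ValueError("nct_P must be >= 1")
        if self.stability_B < 0 or self.edge_accuracy_B < 0:
            raise ValueError("bootstrap replicate counts must be >= 0")

    def estimator(self, schema=None) -> EBICGraphicalLasso:
        return EBICGraphicalLasso(
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            correlation=self.correlation,
            schema=schema,
        )


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an items matrix (rows = participants).

    ``alpha = k/(k-1) * (1 - sum var(item_i) / var(total))`` with sample
    (ddof=1) variances.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two items")
    if np.isnan(X).any():
        raise ValueError("complete rows required")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def fruchterman_reingold(
    W: np.ndarray, iterations: int = 200, seed: int = 0
) -> np.ndarray:
    """Force-directed layout with |w| as attraction strengths.

    Deterministic given the seed; coordinates are centred at the origin.
    """
    import networkx as nx

    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    if p == 1:
        return np.zeros((1, 2))
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0.0:
                G.add_edge(i, j, weight=float(abs(W[i, j])))
    pos = nx.spring_layout(G, weight="weight", iterations=iterations, seed=seed)
    coords = np.array([pos[i] for i in range(p)])
    coords = coords - coords.mean(axis=0)
    if not np.isfinite(coords).all():  # pragma: no cover - safety net
        coords = np.nan_to_num(coords)
    return coords


def _stage(log: list[dict], name: str, t0: float, **info) -> None:
    rec = {"stage": name, "wall_seconds": round(time.time() - t0, 3), **info}
    log.append(rec)
    logger.info("%s", rec)


def _export_network(
    name: str,
    W: np.ndarray,
    labels: list[str],
    outdir: Path,
    config: AnalysisConfig,
    layout_seed: int,
) -> dict:
    layout = fruchterman_reingold(W, seed=layout_seed)
    graph = NetworkGraph(
        labels=list(labels),
        weights=W,
        display_min=config.display_min,
        display_max=config.display_max,
        layout=layout,
    )
    files = {}
    for fmt, suffix in [
        ("json", ".json"),
        ("graphml", ".graphml"),
        ("edge_list_csv", ".edges.csv"),
    ]:
        path = outdir / f"network_{name}{suffix}"
        write_network(graph, path, format=fmt)
        files[fmt] = str(path)
    metrics = node_metrics_table(W, labels=list(labels))
    mpath = outdir / f"metrics_{name}.csv"
    metrics.to_csv(mpath, float_format="%.12g")
    files["metrics"] = str(mpath)
    files["global_clustering_min"] = metrics.attrs["global_clustering_min"]
    files["edge_count"] = int(np.count_nonzero(np.triu(W, 1)))
    return files


def run_four_networks(
    table: ResponseTable,
    config: AnalysisConfig | None = None,
    outdir: str | Path = "netpsych_run",
) -> dict:
    """Run the full four-network analysis; returns the manifest dict.

    The manifest records, per network, the exported files, edge count and
    global clustering, plus the NCT result, optional bootstrap outputs, the
    Cronbach's alpha of the items, and a structured per-stage log.
    """
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed).spawn(8)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    log: list[dict] = []
    manifest: dict = {"seed": config.seed, "n": table.n, "p": table.p, "stages": log}

    item_names = [v.name for v in table.schema if v.role == "item"]
    if len(item_names) < 2:
        raise ValueError("pipeline requires at least two variables with role 'item'")

    # stage 1: imputation
    t0 = time.time()
    if config.imputation == "none":
        if table.missing_mask.any():
            raise ValueError("missing data present but imputation disabled")
        complete = table.copy()
    else:
        complete = impute(
            table,
            method=config.imputation,
            max_iter=config.impute_max_iter,
            seed=seeds[0],
        )
    _stage(log, "impute", t0, method=config.imputation,
           n_missing=int(table.missing_mask.sum()), seed=seeds[0])

    # stage 2: descriptives
    t0 = time.time()
    items_X = complete.select(item_names).values
    alpha = cronbach_alpha(items_X)
    manifest["cronbach_alpha_items"] = alpha
    _stage(log, "descriptives", t0, cronbach_alpha=round(alpha, 4))

    networks: dict[str, dict] = {}

    def estimate(name: str, sub: ResponseTable, layout_seed: int) -> np.ndarray:
        t0 = time.time()
        est = config.estimator(schema=sub.schema).fit(sub.values)
        files = _export_network(name, est.partials_, sub.names, outdir, config, layout_seed)
        files["lambda"] = float(est.lambda_)
        files["ebic"] = float(est.ebic_)
        networks[name] = files
        _stage(log, f"network_{name}", t0, n=sub.n, p=sub.p,
               edges=files["edge_count"], lam=round(est.lambda_, 6))
        return est.partials_

    # stage 3/4: items-only and full networks
    estimate("items", complete.select(item_names), seeds[1])
    estimate("full", complete, seeds[2])

    # stage 5: median split on the item total score, group networks + NCT
    t0 = time.time()
    totals = items_X.sum(axis=1)
    groups = median_split(totals)
    _stage(log, "median_split", t0, median=float(np.median(totals)),
           n_low=int((groups == "low").sum()), n_high=int((groups == "high").sum()))

    low = complete.take_rows(np.nonzero(groups == "low")[0])
    high = complete.take_rows(np.nonzero(groups == "high")[0])
    estimate("low", low, seeds[3])
    estimate("high", high, seeds[4])
    manifest["networks"] = networks

    t0 = time.time()
    result = nct(
        low.values,
        high.values,
        config.estimator(schema=complete.schema),
        P=config.nct_P,
        seed=seeds[5],
        tests=config.nct_tests,
        labels=complete.names,
    )
    nct_path = outdir / "nct.json"
    with open(nct_path, "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")
    pd.DataFrame({"perm_M": result.perm_M, "perm_S": result.perm_S}).to_csv(
        outdir / "nct_permutations.csv", index=False, float_format="%.12g"
    )
    manifest["nct"] = {
        k: result.to_dict()[k]
        for k in ("observed_M", "observed_S", "global_strength_1",
                  "global_strength_2", "p_M", "p_S")
    }
    manifest["nct"]["file"] = str(nct_path)
    _stage(log, "nct", t0, P=config.nct_P, p_M=result.p_M, p_S=result.p_S,
           seed=seeds[5])

    # optional bootstraps (on the full network's data)
    if config.stability_B > 0:
        t0 = time.time()
        stab = case_drop_bootstrap(
            complete.values,
            config.estimator(schema=complete.schema),
            grid=config.stability_grid,
            B=config.stability_B,
            seed=seeds[6],
        )
        stab.correlations.to_csv(
            outdir / "stability_correlations.csv", index=False, float_format="%.12g"
        )
        cs = cs_coefficient(stab)
        pd.Series(cs).rename_axis("index").to_frame("cs").to_csv(outdir / "cs.csv")
        manifest["cs"] = cs
        _stage(log, "stability", t0, B=config.stability_B, seed=seeds[6], **cs)
    if config.edge_accuracy_B > 0:
        t0 = time.time()
        acc = edge_ci_bootstrap(
            complete.values,
            config.estimator(schema=complete.schema),
            B=config.edge_accuracy_B,
            seed=seeds[7],
            labels=complete.names,
        )
        acc.edges.to_csv(outdir / "edge_ci.csv", index=False, float_format="%.12g")
        manifest["edge_ci_file"] = str(outdir / "edge_ci.csv")
        _stage(log, "edge_accuracy", t0, B=config.edge_accuracy_B, seed=seeds[7])

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest
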