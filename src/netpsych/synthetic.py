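"""Synthetic questionnaire generator with known partial-correlation truth.

The generator emulates a mixed-type oral-health-literacy questionnaire: 14
five-level ordinal items organised in 7 two-item conceptual domains with
strong within-domain partial correlations (spanning 0.54-0.89), a set of
continuous / ordinal / binary covariates with specified cross-links, and
item-level missingness that is completely at random (default rate 1.1%).

The ground truth is specified directly in partial-correlation space: the
standardized precision matrix K has unit diagonal and off-diagonal entries
``K_ij = -partial_ij``, so every requested partial correlation is realized
exactly and every unrequested pair has partial exactly zero.  Latent data
are multivariate normal with correlation ``standardize(K^-1)``; ordinal
columns are obtained by cutting the latent scale at fixed thresholds
(Gaussian copula discretization), which preserves rank structure and hence
lets the SKEPTIC rank estimator recover the latent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import json
from pathlib import Path

import numpy as np
from scipy import stats

from .schema import ResponseTable, VariableSchema

__all__ = [
    "CovariateSpec",
    "SyntheticSpec",
    "SyntheticSample",
    "build_precision",
    "sample_responses",
    "make_groups",
    "default_item_spec",
    "default_study_spec",
]

#: default latent cut points for a non-degenerate 5-level ordinal marginal
DEFAULT_ORDINAL_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)

#: study domain labels, one per two-item block
DOMAIN_LABELS = (
    "communication",
    "access",
    "receptivity",
    "understanding",
    "utilisation",
    "support",
    "economic",
)

# Within-domain partial correlations. The observed range in the motivating
# study ran from 0.54 (utilisation) to 0.89 (understanding); the remaining
# domains are spread evenly across that range.
DOMAIN_PARTIALS = {
    "communication": 0.60,
    "access": 0.66,
    "receptivity": 0.72,
    "understanding": 0.89,
    "utilisation": 0.54,
    "support": 0.78,
    "economic": 0.83,
}


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: its measurement type and partial-correlation links.

    ``links`` maps variable names (items or earlier covariates) to the target
    partial correlation. ``thresholds`` are latent cut points for ordinal /
    binary covariates (binary: a single cut point controls prevalence).
    """

    name: str
    kind: str  # ordinal | continuous | binary
    levels: int | None = None
    links: tuple[tuple[str, float], ...] = ()
    thresholds: tuple[float, ...] | None = None

    def as_variable(self) -> VariableSchema:
        return VariableSchema(
            name=self.name, kind=self.kind, levels=self.levels, role="covariate"
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic questionnaire population.

    Items come in consecutive two-item domain blocks (``domains`` lists the
    item-index pairs); ``within_domain_partial`` gives the partial
    correlation of each block. ``cross_links`` and covariate links add
    off-block structure. ``group_deltas`` optionally defines a second
    population whose precision differs by the given partial-correlation
    changes, for network-comparison experiments.
    """

    p_items: int = 14
    domains: tuple[tuple[int, int], ...] = tuple(
        (2 * d, 2 * d + 1) for d in range(7)
    )
    within_domain_partial: tuple[float, ...] = tuple(
        DOMAIN_PARTIALS[d] for d in DOMAIN_LABELS
    )
    cross_links: tuple[tuple[int, int, float], ...] = ()
    covariates: tuple[CovariateSpec, ...] = ()
    item_thresholds: tuple[float, ...] = DEFAULT_ORDINAL_THRESHOLDS
    item_kind: str = "ordinal"  # "continuous" leaves items on the latent scale
    missing_rate: float = 0.011
    n: int = 400
    seed: int = 0
    group_deltas: tuple[tuple[int, int, float], ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.domains) != len(self.within_domain_partial):
            raise ValueError("one within-domain partial per domain block required")
        for r in self.within_domain_partial:
            if not -1.0 < r < 1.0:
                raise ValueError("partial correlations must lie in (-1, 1)")
        for i, j, r in self.cross_links:
            if not -1.0 < r < 1.0:
                raise ValueError("partial correlations must lie in (-1, 1)")
            if i == j:
                raise ValueError("cross link must connect distinct items")

    # -- naming ------------------------------------------------------------

    @property
    def item_names(self) -> list[str]:
        if self.p_items == 14 and len(self.domains) == 7:
            return [
                f"{DOMAIN_LABELS[d][:3].upper()}{k + 1}"
                for d in range(7)
                for k in range(2)
            ]
        return [f"item{j + 1:02d}" for j in range(self.p_items)]

    @property
    def names(self) -> list[str]:
        return self.item_names + [c.name for c in self.covariates]

    @property
    def p(self) -> int:
        return self.p_items + len(self.covariates)

    def variables(self) -> list[VariableSchema]:
        if self.item_kind == "continuous":
            items = [
                VariableSchema(name=nm, kind="continuous", role="item")
                for nm in self.item_names
            ]
        else:
            items = [
                VariableSchema(
                    name=nm,
                    kind="ordinal",
                    levels=len(self.item_thresholds) + 1,
                    role="item",
                )
                for nm in self.item_names
            ]
        return items + [c.as_variable() for c in self.covariates]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "p_items": self.p_items,
            "domains": [list(d) for d in self.domains],
            "within_domain_partial": list(self.within_domain_partial),
            "cross_links": [list(c) for c in self.cross_links],
            "covariates": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    "levels": c.levels,
                    "links": [list(l) for l in c.links],
                    "thresholds": None if c.thresholds is None else list(c.thresholds),
                }
                for c in self.covariates
            ],
            "item_thresholds": list(self.item_thresholds),
            "item_kind": self.item_kind,
            "missing_rate": self.missing_rate,
            "n": self.n,
            "seed": self.seed,
            "group_deltas": None
            if self.group_deltas is None
            else [list(d) for d in self.group_deltas],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        covs = tuple(
            CovariateSpec(
                name=c["name"],
                kind=c["kind"],
                levels=c.get("levels"),
                links=tuple((str(a), float(b)) for a, b in c.get("links", [])),
                thresholds=None
                if c.get("thresholds") is None
                else tuple(c["thresholds"]),
            )
            for c in doc.get("covariates", [])
        )
        return cls(
            p_items=doc["p_items"],
            domains=tuple(tuple(d) for d in doc["domains"]),
            within_domain_partial=tuple(doc["within_domain_partial"]),
            cross_links=tuple(
                (int(i), int(j), float(r)) for i, j, r in doc.get("cross_links", [])
            ),
            covariates=covs,
            item_thresholds=tuple(doc["item_thresholds"]),
            item_kind=doc.get("item_kind", "ordinal"),
            missing_rate=doc["missing_rate"],
            n=doc["n"],
            seed=doc.get("seed", 0),
            group_deltas=None
            if doc.get("group_deltas") is None
            else tuple(tuple(d) for d in doc["group_deltas"]),
        )


@dataclass
class SyntheticSample:
    """A drawn dataset plus its generating truth."""

    table: ResponseTable
    partials: np.ndarray  # ground-truth partial correlation matrix, zero diag
    precision: np.ndarray
    spec: SyntheticSpec


def _target_partials(spec: SyntheticSpec, deltas=None) -> np.ndarray:
    p = spec.p
    names = spec.names
    P = np.zeros((p, p))

    def put(i: int, j: int, r: float) -> None:
        P[i, j] += r
        P[j, i] += r

    for (i, j), r in zip(spec.domains, spec.within_domain_partial):
        put(i, j, r)
    for i, j, r in spec.cross_links:
        put(i, j, r)
    for c in spec.covariates:
        jc = names.index(c.name)
        for other, r in c.links:
            put(names.index(other), jc, r)
    if deltas:
        for i, j, d in deltas:
            put(int(i), int(j), float(d))
    np.fill_diagonal(P, 0.0)
    return P


def build_precision(spec: SyntheticSpec, deltas=None) -> np.ndarray:
    """Standardized precision matrix realizing the requested partials exactly.

    With unit diagonal, the partial correlation between i and j is
    ``-K_ij``; setting ``K_ij = -partial_ij`` therefore hits every target
    exactly and leaves unrequested pairs conditionally independent.  Raises
    if the requested partials are jointly incompatible with positive
    definiteness (the remedy is weaker values).
    """
    P = _target_partials(spec, deltas)
    if np.abs(P).max(initial=0.0) >= 1.0:
        raise ValueError("accumulated partial correlations left (-1, 1)")
    K = np.eye(spec.p) - P
    w = np.linalg.eigvalsh(K)
    if w.min() <= 1e-8:
        raise ValueError(
            "requested partial correlations are incompatible with a positive "
            f"definite precision matrix (min eigenvalue {w.min():.3g}); "
            "use weaker values"
        )
    return K


def partials_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial correlation matrix -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return W


def _latent_correlation(K: np.ndarray) -> np.ndarray:
    S = np.linalg.inv(K)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _thresholds_for(spec: SyntheticSpec, var: VariableSchema, cov: CovariateSpec | None):
    if var.role == "item":
        return np.asarray(spec.item_thresholds)
    if cov is not None and cov.thresholds is not None:
        return np.asarray(cov.thresholds)
    if var.kind == "binary":
        return np.asarray([0.0])
    # default equal-probability interior thresholds
    k = var.levels
    return stats.norm.ppf(np.arange(1, k) / k)


def sample_responses(
    spec: SyntheticSpec, seed: int | None = None, deltas=None
) -> SyntheticSample:
    """Draw a ResponseTable from the spec's latent Gaussian population.

    RNG consumption order is fixed (latent draws, then MCAR mask) so a seed
    fully determines the table.
    """
    if spec.n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    K = build_precision(spec, deltas)
    R = _latent_correlation(K)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((spec.n, spec.p)) @ L.T

    variables = spec.variables()
    covs = {c.name: c for c in spec.covariates}
    X = np.empty_like(Z)
    for j, var in enumerate(variables):
        if var.kind == "continuous":
            X[:, j] = Z[:, j]
        else:
            th = _thresholds_for(spec, var, covs.get(var.name))
            X[:, j] = np.searchsorted(th, Z[:, j], side="left")

    mask = rng.random(size=X.shape) < spec.missing_rate
    # a fully missing column would be unusable downstream; at the default
    # 1.1% rate this never triggers for realistic n
    for j in range(spec.p):
        if mask[:, j].all():
            mask[0, j] = False
    table = ResponseTable(values=X, missing_mask=mask, schema=variables)
    return SyntheticSample(
        table=table, partials=partials_from_precision(K), precision=K, spec=spec
    )


def make_groups(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[SyntheticSample, SyntheticSample]:
    """Two samples: group A from the spec, group B with ``group_deltas`` applied.

    Both groups share thresholds and n; an empty delta list yields two
    independent draws from the identical distribution.
    """
    if spec.group_deltas is None:
        raise ValueError("spec.group_deltas must be set to build groups")
    base = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(base).spawn(2)
    seed_a = int(ss[0].generate_state(1)[0] % (2**31))
    seed_b = int(ss[1].generate_state(1)[0] % (2**31))
    a = sample_responses(spec, seed=seed_a)
    b = sample_responses(spec, seed=seed_b, deltas=spec.group_deltas)
    return a, b


# ---------------------------------------------------------------------------
# default study regimes


def default_item_spec(n: int = 400, seed: int = 0, **kw) -> SyntheticSpec:
    """14 five-level items in 7 two-item domains, sparse cross-links.

    Within-domain partials span 0.54-0.89. Cross-links connect the domains
    (so the item network is one component) and include one negative
    communication-understanding link, mirroring the qualitative structure of
    the motivating questionnaire.
    """
    cross = (
        (0, 6, 0.15),   # COM1 - UND1
        (1, 7, -0.20),  # COM2 - UND2 (negative)
        (2, 4, 0.18),   # ACC1 - REC1
        (5, 9, 0.15),   # REC2 - UTI2
        (8, 10, 0.15),  # UTI1 - SUP1
        (11, 13, 0.15), # SUP2 - ECO2
        (3, 12, 0.12),  # ACC2 - ECO1
    )
    return SyntheticSpec(n=n, seed=seed, cross_links=cross, **kw)


def default_covariates() -> tuple[CovariateSpec, ...]:
    """Ten covariates emulating the study's psychosocial/sociodemographic set."""
    return (
        CovariateSpec("persctl", "continuous", links=(("UND1", 0.15),)),
        CovariateSpec("selfeff", "continuous", links=(("UTI1", 0.20),)),
        CovariateSpec(
            "stress",
            "continuous",
            links=(("persctl", -0.30), ("REC1", -0.15), ("REC2", -0.12)),
        ),
        CovariateSpec("ohrqol", "continuous", links=(("stress", 0.20),)),
        CovariateSpec("age", "continuous", links=(("ACC1", 0.12),)),
        CovariateSpec(
            "srh", "ordinal", levels=5, links=(("ohrqol", 0.22), ("UND2", -0.15))
        ),
        CovariateSpec(
            "educ",
            "ordinal",
            levels=5,
            links=(("COM1", 0.15), ("age", -0.12)),
            thresholds=(-1.8, -1.2, 0.6, 1.6),
        ),
        CovariateSpec(
            "sport", "binary", links=(("ACC2", 0.15), ("age", -0.15)), thresholds=(1.0,)
        ),
        CovariateSpec(
            "comgrp", "binary", links=(("sport", 0.25),), thresholds=(1.1,)
        ),
        CovariateSpec(
            "healthctr", "binary", links=(("ACC1", 0.15),), thresholds=(-0.35,)
        ),
    )


def default_study_spec(n: int = 400, seed: int = 0, **kw) -> SyntheticSpec:
    """Items plus ten mixed-type covariates at the study's sample size."""
    base = default_item_spec(n=n, seed=seed, **kw)
    return replace(base, covariates=default_covariates())


def simulate_to_files(
    spec: SyntheticSpec, outdir: str | Path, seed: int | None = None
) -> dict[str, str]:
    """Write CSV + schema + truth matrix for a drawn sample; returns paths."""
    from .schema import write_responses

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample = sample_responses(spec, seed=seed)
    paths = {
        "responses": str(outdir / "responses.csv"),
        "schema": str(outdir / "schema.json"),
        "truth": str(outdir / "true_partials.csv"),
        "spec": str(outdir / "spec.json"),
    }
    write_responses(sample.table, paths["responses"], paths["schema"])
    import pandas as pd

    pd.DataFrame(sample.partials, index=spec.names, columns=spec.names).to_csv(
        paths["truth"]
    )
    spec.to_json(paths["spec"])
    return paths
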