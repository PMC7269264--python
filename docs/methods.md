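# Methods

`netpsych` implements the network-psychometrics workflow used to study how
oral health literacy (OHL) relates to psychosocial, sociodemographic and
oral-health factors: a regularized partial-correlation network is estimated
from mixed-type questionnaire responses, summarized with weighted centrality
and clustering indices, stress-tested with bootstraps, and compared between
participant subgroups with permutation tests. This note records the models,
the defaults and why they were chosen, and the known limitations.

## Statistical model

### Latent Gaussian view of questionnaire data

Responses are modelled as discretized or direct observations of a latent
multivariate normal vector `Z ~ N(0, Σ)` with correlation matrix `Σ`. An
ordinal item with `m` levels is `X_j = k` iff `τ_{j,k} < Z_j ≤ τ_{j,k+1}`
for fixed thresholds `τ`; binary variables are 2-level ordinals; continuous
variables are observed directly. Conditional-independence structure lives in
the precision matrix `K = Σ^{-1}`: the edge weight between nodes i and j is
the partial correlation

    w_ij = -K_ij / sqrt(K_ii K_jj),

the association between i and j after controlling for every other node.

### Correlation estimation (two routes)

* **SKEPTIC** (default): Kendall's tau-b for every pair, mapped through
  `ρ = sin(π τ / 2)`. Under the Gaussian copula this estimates the latent
  correlation without assuming normal margins and is invariant to monotone
  transformations, which makes it the natural default for skewed
  questionnaire data.
* **auto_mixed**: classical dispatch by declared type — Pearson
  (continuous–continuous), polychoric (ordinal–ordinal, two-step: thresholds
  from the marginal cumulative proportions via `Φ^{-1}`, then `ρ` maximizing
  the bivariate-normal contingency likelihood on (−0.999, 0.999)), and
  polyserial (continuous–ordinal, ML with thresholds fixed from the ordinal
  margin; a two-step moment estimator is the flagged fallback).

Both routes can produce an indefinite pairwise matrix; every matrix passes
through an eigenvalue-clipping repair (clip at 1e-8, rescale to unit
diagonal, iterate) before model fitting, and the result records whether
repair was needed.

**Known bias.** Tau-b's tie correction does not fully undo coarse
discretization: on 5-level margins the SKEPTIC estimate of a latent
correlation of 0.89 is high by up to ~0.09 even as n → ∞. This affects the
scale, not the support, of strong edges; the polychoric route does not share
the bias. Edge detection, permutation tests and stability analyses are
unaffected in our simulations.

### Sparse network estimation

The graphical lasso maximizes
`log det K − tr(RK) − λ Σ_{i≠j} |K_ij|` (diagonal unpenalized). The solver
is a Friedman-style block coordinate descent written here and jit-compiled:
each column of the working covariance is updated by a coordinate-descent
lasso, warm-started along the penalty path; solutions are accepted only if
the KKT stationarity residual is ≤ 1e-4 (a convergence error reports the
offending λ otherwise). `λ = 0` short-circuits to the exact inverse.

The penalty is selected by the Extended Bayesian Information Criterion,

    EBIC(λ) = −n [log det K − tr(RK)] + E log n + 4 E γ log p,

with `E` the number of nonzero upper-triangle precision entries, over a
log-spaced path of 100 values from `λ_max = max|R_ij|` (the smallest penalty
that empties the network) down to `0.01 λ_max`. Defaults follow the
EBICglasso convention; `γ = 0.5` is the standard conservative choice. Ties
resolve toward the sparser model. Edges are the support of the selected `K`
(numerical zero 1e-10); no post-thresholding is applied — the 0.04 display
minimum and 0.76 display maximum attached to exported graphs are
visualization metadata only.

**Shrinkage caveat.** EBIC selection retains a nonzero penalty even under
strong signal (λ ≈ 0.03–0.05 in our n = 1000 regimes), so selected edge
weights are shrunk toward zero by roughly that amount. Bootstrap percentile
intervals are intervals for the *penalized* estimator: they cover its own
target, not the unshrunk generating partial. This is why the coverage test
uses an unregularized estimator while a separate test documents the
shrinkage of the regularized intervals.

### Node-level indices

All indices use absolute edge weights (the networks contain negative
edges; distances and clustering formulas require nonnegative weights, which
is the conventional treatment):

* strength `s_i = Σ_j |w_ij|`; betweenness by Brandes' algorithm with edge
  length `1/|w|` and fractional credit for tied shortest paths; closeness
  `1 / Σ_j d(i, j)` over reachable j (isolated nodes score 0).
* local clustering in four weighted variants — Watts–Strogatz (binarized),
  Barrat, Zhang, Onnela — all of which reduce to the binary coefficient on
  0/1 weights and give 0 to nodes of degree < 2; Zhang's denominator uses
  weights rescaled by the maximum, and a non-positive denominator scores 0.
* the global coefficient uses the minimum method: each triplet centred on a
  node contributes the smaller of its two edge weights; the coefficient is
  closed-triplet weight over total triplet weight (0 with a flag when no
  triplet exists).

Centralities are reported raw and as per-network z-scores (sample sd;
all-equal indices give zeros with a degenerate flag).

### Stability, accuracy, comparison

* **Case-dropping bootstrap**: for drop proportions
  {0.05, 0.15, …, 0.75}, B subsamples are re-estimated end-to-end and each
  centrality correlated with the full-sample index. The CS-coefficient per
  index is the largest grid proportion such that at every proportion up to
  it the empirical 5% quantile of those correlations is ≥ 0.7
  (monotone-prefix rule, no interpolation — conservative and exactly
  reproducible; grid points whose retained sample falls below p + 5 are
  skipped, and failed replicates count as correlation −1). Values < 0.25
  flag instability; > 0.5 is good.
* **Edge accuracy**: ordinary nonparametric bootstrap (rows resampled with
  replacement), per-edge 2.5/97.5 percentile bounds; degenerate resamples
  are redrawn with a cap.
* **Network comparison test**: groups are pooled, labels permuted
  preserving group sizes, and both networks re-estimated per permutation.
  Statistics: structure invariance `M = max |w_A − w_B|`, global-strength
  invariance `S = |gs_A − gs_B|`, and optional per-edge differences
  restricted to edges present in either observed network, Holm-adjusted.
  P-values use the add-one convention (`p ≥ 1/(P+1)`). The pooled sample is
  canonically ordered and each permutation assigns the smaller group size
  first, which makes the null distribution exactly invariant to the order
  in which the groups are passed. Degenerate permutations are dropped and
  counted (warning above 10%).

### Pipeline

`run_four_networks` imputes once, then estimates (1) the items-only
network, (2) items + covariates, (3)–(4) the networks of participants at or
below / above the median total item score (ties to the low group —
deterministic and documented), runs the NCT between (3) and (4), and writes
metrics tables, graph exports (JSON / GraphML / edge-list CSV),
Fruchterman–Reingold layouts, and a manifest with a structured per-stage
log. A single seed drives every stage through `SeedSequence` spawning, so
outputs are byte-identical across reruns.

### Missing data

Item-level missingness is filled once before correlation estimation
(single imputation, matching the workflow the pipeline reproduces). The
default is an iterative random-forest scheme (missForest-style): initialize
with mode/median, cycle columns by increasing missingness re-predicting
missing cells (classifier for ordinal/binary, regressor for continuous),
stop when the change criterion — scaled squared change on continuous cells
plus disagreement fraction on categorical cells — first rises, returning
the previous iterate. KNN and mode/median fills are provided as cheaper
alternatives. Observed cells are never modified.

## Synthetic data generator

The generator is the package's test bed and defines the regime every
simulation uses. It emulates the motivating study:

* 14 five-level ordinal items in 7 two-item conceptual domains
  (communication, access, receptivity, understanding, utilisation, support,
  economic barriers) with within-domain partial correlations spanning
  0.54–0.89 (utilisation lowest, understanding highest, remaining domains
  spread evenly — the study reports the range and endpoints, not the full
  set);
* sparse cross-domain links (±0.12–0.20), including one negative
  communication–understanding link, so the item network is connected and
  contains negative edges;
* 10 covariates (5 continuous totals, 2 five-level ordinals, 3 binaries)
  with plausible links, e.g. stress–personal-control −0.30, stress
  negatively tied to the receptivity items, binary prevalences matched to
  the study's descriptive table;
* item thresholds (−1.5, −0.5, 0.5, 1.5): symmetric, no category below 5%
  (polychoric stability); `item_kind="continuous"` leaves items on the
  latent scale for estimator-theory tests;
* 1.1% MCAR missingness; n = 400 participants.

Ground truth is specified in partial-correlation space: the standardized
precision has unit diagonal and `K_ij = −partial_ij`, so requested partials
are realized exactly and unrequested pairs are exactly conditionally
independent; jointly infeasible requests raise an error rather than being
silently repaired (a congruence rescaling cannot restore definiteness
without changing the partials). Latent draws use the Cholesky factor of the
implied correlation; the RNG order (latent draws, then MCAR mask) is fixed.
`group_deltas` rebuilds the precision with specified partial changes for a
second population, for comparison experiments.

What the generator does *not* emulate: skewed item margins (the study
population scores high on OHL; thresholds here are symmetric),
missingness that depends on responses (MNAR), non-Gaussian copulas, and
nominal covariates. Passing tests therefore show correctness of the
machinery and calibration under a Gaussian-copula MCAR world, not
robustness to those features.

## Problem sizes used in tests

Simulation-based checks run at sizes chosen to make the claimed properties
detectable with comfortable margins: edge recovery and sparsistency use 50
seeds at n = 400 (the study's size) and n = 1000; permutation-test
calibration uses 100 null repetitions (n = 150 per group, P = 200) and 50
power repetitions (n = 300 per group) on a 6-node, 3-domain regime with a
reduced penalty path (12 λ values); the stability ordering check uses 10
seeds with B = 12 replicates per grid point. The acceptance script runs the
full pipeline at the study dimensions (n = 400, p = 24) with P = 200
permutations and B = 25 stability replicates.

## Design choices that were genuinely open

* Which correlation fed the network in the motivating workflow is
  ambiguous (both a SKEPTIC step and automatic mixed correlations are
  described); both are implemented, SKEPTIC is the default, and
  `--correlation` switches routes.
* "Penalty parameter 0.5" is read as the EBIC hyperparameter γ = 0.5 with λ
  chosen by EBIC over the path — the standard procedure; a literal λ = 0.5
  would empty every network here.
* Ordinal auto-detection (≤ 7 distinct integer values) mirrors the common
  automatic-dispatch convention; explicit schema declarations always win.
  Nominal covariates are out of scope: users must encode them as binary
  sets or declare an ordinal reading.
* Median-split ties go to the low group; the CS grid is the 8-point
  {0.05…0.75} grid with the monotone-prefix rule (published CS values such
  as 0.13 or 0.21 imply other grids exist; the grid is configurable).
* Betweenness keeps fractional credit for tied shortest paths; ties are
  measure-zero for continuous weights but matter for hand-built fixtures.

## Limitations

* SKEPTIC tie bias on coarse ordinals (above) inflates the strongest edge
  weights slightly; use `auto_mixed` when unbiased weights matter more than
  robustness.
* EBIC-glasso edge weights are shrunk; bootstrap CIs quantify sampling
  variability of the penalized estimator, not unbiased uncertainty about
  the generating partial.
* The NCT's permutation null assumes exchangeability of participants across
  groups under the null; covariate-stratified nulls are not implemented.
* Single imputation understates imputation uncertainty (by design, matching
  the reproduced workflow); at 1.1% missingness the effect is negligible.
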