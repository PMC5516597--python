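# Methods

This note documents the statistical model behind `recallnet`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## Data model

A study consists of *n* subjects, each with a symmetric R × R matrix of
connection probabilities `w_ij ∈ [0, 1]` (diagonal zero; a weight of
exactly 0 means the edge is absent), a recall phenotype (count of freely
recalled pictures, optionally split by emotional valence), and nuisance
covariates: age, gender, and intracranial volume (ICV). The default atlas
has R = 82 nodes (34 Desikan–Killiany cortical gyri per hemisphere plus 7
subcortical structures per hemisphere). Matrices are stored fully but every
edge-level computation iterates the strict upper triangle, so each
undirected edge has a single source of truth. Raw directed tractography
matrices must be symmetrized explicitly (`symmetrize`, the mean of the two
directed probabilities); asymmetric input to the reader is an error, never
silently repaired.

## Population-level edge filtering

Edge (i, j) is retained iff `mean(w_ij) + 2·sd(w_ij) ≥ floor` across
subjects, with `floor = 0.01` by default; the mask is applied identically
to every subject. The standard deviation uses the n−1 (sample) denominator
— a choice the filtering rule's usual statement leaves open; with
hundreds of subjects the two conventions are indistinguishable in practice.

## Graph metrics

* **Cost / degree.** κ = Σ_{i<j} w_ij / (R(R−1)/2); nodal degree
  k_i = Σ_{j≠i} w_ij / (R−1). The mean of k over nodes equals κ exactly;
  the test suite asserts this identity on random connectomes.
* **Lengths.** Path-based metrics map weight to length as 1/w, the
  standard convention for probabilistic connection weights. Characteristic
  path length averages *finite* distances only (masked connectomes can be
  disconnected); the count of unreachable pairs is available separately.
  Global efficiency uses 1/∞ = 0 and is therefore robust to
  disconnection. Nodal efficiency of node i is the global efficiency of
  the subgraph induced by i's neighbours.
* **Clustering.** Onnela geometric-mean-of-triangles form on weights
  scaled by the maximum weight; nodes with binary degree < 2 get 0. For
  binary graphs this reduces to the triangle fraction (asserted in tests).
* **Betweenness.** Brandes on 1/w lengths, all shortest paths counted
  with multiplicity, normalized by (R−1)(R−2) ordered endpoint pairs.
* **Random references.** Maslov–Sneppen double-edge swaps on the binary
  topology with weights carried along with their edge; the binary degree
  sequence, edge count, and weight multiset are preserved exactly. The
  target is 20 successful swaps per edge; if no legal swap can be found a
  warning is raised and the graph returned as-is.
* **Cost integration.** A metric is integrated by binarizing the graph at
  each density of an equispaced grid (default 50 points) from the minimal
  density 1/(R(R−1)/2) to the largest density attainable by *all* subjects,
  and averaging. Binarization keeps the round(κ·R(R−1)/2) strongest edges,
  ties broken lexicographically by (i, j) for determinism; zero-weight
  edges are never promoted, and a grid point requesting more edges than a
  subject has is recorded as missing and excluded from that subject's
  average (with a count). Integration on binarized graphs at fixed density
  — rather than re-weighted subgraphs — is the convention of the
  cost-integration framework this analysis follows. The normalized
  characteristic path length is integrated on a strided sub-grid (default
  every 5th point) because every grid point needs its own set of rewired
  surrogates.

## Inference

Recall is residualized on age and gender; every network measure (and every
grey-matter volume) additionally on ICV. Residualization precedes ranking.
Associations are Spearman correlations (average ranks for ties), two-sided
p from the t approximation `t = r·sqrt((n−2)/(1−r²))`, df = n−2, and a 95%
percentile bootstrap CI over case resampling (default B = 2000, seeded).

The hierarchical cascade tests three levels, each gated on rejection of
the level below, with Benjamini–Hochberg step-up control within level:

1. **Global** — network cost plus the four cost-integrated global metrics
   (efficiency, clustering, normalized path length, betweenness) form one
   five-test BH family; the cascade proceeds iff the *cost* test's
   BH-adjusted p ≤ q.
2. **Nodal** — the R nodal degrees, BH over nodes.
3. **Edge** — every retained edge incident to at least one rejected node,
   each undirected edge tested once, BH over that edge set.

Plain BH step-up is used at every level and q (default .05) is exposed as
a parameter; hierarchical FDR variants that adjust q per level exist, and
the per-level critical p-values of a given dataset will depend on that
choice. A measure that is constant across subjects (possible in degenerate
simulated data, e.g. the binarized path length when the grid has a single
low cost) is recorded with r = NaN, p = 1 so the family size stays fixed.

**Robust regression.** The joint variance explained by a set of edges is
the unweighted-residual R² of an iteratively reweighted least-squares fit
with Tukey bisquare weights: tuning constant c = 4.685, scale re-estimated
each iteration as MAD/0.6745 of the current residuals (MAD about zero —
appropriate for residuals of a model with an intercept), iterated until
the maximum coefficient change is below 1e−8 or 100 iterations (flagged if
unconverged). The implementation is cross-checked against statsmodels RLM
in the test suite.

**Network-based statistic.** Per-edge t statistics come from the OLS fit
recall ~ intercept + edge + age + gender + ICV (df = n − 5), computed via
the Frisch–Waugh–Lovell identity for speed. The cluster-forming threshold
is one-sided t ≥ T by default (T = 2.5 corresponds to a tail of ≈ .0063 at
df ≈ 660, matching the design this pipeline re-implements, whose threshold
was quoted one-sided); a two-sided mode is a flag. Components of the
suprathreshold graph are scored by edge count ("extent"), and FWE p-values
are `(1 + #{null max ≥ size}) / (n_perm + 1)` under permutation of the
covariate-residualized phenotype across subjects (covariates stay with
their subjects; the per-edge statistics are re-derived from the permuted
residual at every one of the default 10 000 permutations). Presets T = 2
and T = 3 mirror the lenient/stringent supplementary analyses. Fewer than
100 permutations is rejected unless explicitly overridden.

## Synthetic cohorts

The generator emulates the data-generating structure the analysis assumes,
with defaults fixed at the study conditions: n = 664 subjects, R = 82,
age ~ N(22.85, 3.37²), 59.5% female, ICV ~ N(1.55·10⁶, 1.3·10⁵²) mm³ with
a gender offset.

* **Template.** One connected symmetric template per cohort: a random
  spanning tree plus uniformly sampled extra edges up to density 0.30
  (the retained-edge fraction implied by the original study's edge
  bookkeeping is ≈ 170/551 ≈ 0.31), lognormal weights with median 0.02 and
  log-sd 1, clipped to (0, 1].
* **Recall.** A latent memory trait m ~ N(0, 1) drives three binomial
  counts (24 pictures per valence) through a logistic link with slope
  0.35 and per-valence intercepts set so expected recall is 5.5 (negative),
  3.5 (neutral), 4.5 (positive) out of 24 — emotional material is
  remembered better than neutral, and totals land in a realistic 10–20
  range. Age and gender load on the logit (−0.05, +0.15 per SD).
* **Global effect.** Subject i's weights are the template times
  exp(σ_s·z_i + covariate loadings) times per-edge lognormal noise
  (σ_edge = 0.25), with σ_s = 0.12 and (z, m) a Gaussian copula. Because
  the target rank correlation between cost and recall survives a chain of
  monotone transforms but is attenuated by binomial discretization and
  covariate residualization, the copula parameter is found by root-finding
  (Brent) on a cached 10⁶-subject Monte-Carlo map of the full transform
  chain. The map estimates the quantity a study actually reports — the
  *expected within-cohort* correlation at the configured n, with
  residualization and ranking done inside blocks of n subjects and the
  per-block correlations averaged (the population rank correlation differs
  from this at order 1/n). The map uses a fixed internal seed: the
  calibrated parameter is part of the cohort's planted truth and must be
  reproducible from (config, seed) alone.
* **Planted edges.** Each of k effect edges is multiplied by
  exp(γ·g_i) with γ = 0.16 and g a second latent factor correlated with m
  (per-edge correlation with g ≈ .5, giving per-edge associations around
  r ≈ .15). The g–m correlation is solved in closed form from lognormal
  moment formulas for the equicorrelated k-predictor linear model, so the
  k edges jointly explain a requested share of recall variance. The
  requested share is interpreted as the *in-sample* robust R² at the
  configured n, so the solved population value folds in (a) the
  degrees-of-freedom inflation R²_pop = 1 − (1 − target)(n−1)/(n−k−1) and
  (b) a Monte-Carlo estimate of the small systematic gap between the
  bisquare and OLS in-sample R² (the bisquare coefficients are not the
  SSE minimizer). Unreachable targets raise with the achievable bound.
  Planted edges are drawn from template edges with weight ≥ 0.01 so they
  survive population filtering.
* **Volumes.** Per-node lognormal volumes with ICV and age loadings
  (vol–ICV correlation ≈ 0.7, CV ≈ 15%) and, by default, *no* dependence
  on memory — the volumetry control analysis should come up empty. A
  per-node volume effect of chosen strength can be planted for power
  checks.

**What the generator does not emulate:** spatial structure (no geometry or
hemispheric symmetry in the template), heterogeneous per-edge effect sizes
(all planted edges share one factor), non-stationary weight distributions
across the brain, and any form of tractography artefact. Passing
parameter-recovery tests therefore shows the *inference machinery* is
unbiased and calibrated under the assumed generating process; it does not
validate tractography or the anatomical interpretation of real effects.

## Problem sizes in the shipped checks

The test suite exercises the cascade and pipeline on reduced cohorts
(R = 16–25 nodes, n = 120–664, 4–6 cost-grid points, a few hundred NBS
permutations) and the oracle suites on ≤ 7-node graphs, sizes chosen so
the whole suite completes in a couple of minutes while keeping every
statistical assertion at conventional power. The acceptance script runs
the two parameter-recovery studies at full study scale (n = 664, R = 82;
200 and 100 replicates). NBS FWE calibration is checked at 200 null
datasets × 500 permutations.

## Known limitations

* The exact hierarchical-FDR variant behind the original per-level
  critical p-values is not reproducible from published tables; plain BH is
  documented and used throughout.
* Betweenness and clustering conventions (normalization, max-weight
  scaling) follow the dominant toolbox conventions; alternatives would
  shift nodal values but not the inference structure.
* The robust R² is reported from unweighted residuals; other definitions
  (weighted SSE, deviance-based) would give slightly different values.
* The NBS permutation scheme permutes the residualized phenotype, which
  assumes exchangeability after covariate adjustment; heteroscedastic
  covariate effects would require a different scheme.
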