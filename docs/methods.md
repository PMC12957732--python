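# Methods

This note documents the statistical models implemented in `reefdiet`, the
generative model behind the synthetic data, the numerical choices that
matter, and the limits of what the test suite demonstrates.

## Study design being emulated

Two reef-associated benthic invertivores — a browsing corallivore
("C_capistratus") and an active predator ("H_puella") — sampled at 20 adult
fish per species from each of nine reefs, grouped into three habitat zones
(outer bay, inner bay, inner bay disturbed) along a live-coral-cover
gradient of roughly 33 %, 12 % and 0.3 %. Each fish carries total length
(mm), wet weight (g) and an integer otolith age (yr); its gut content is a
vector of OTU read counts from COI metabarcoding. Reef habitat is described
by photo-quadrat point counts (100 points per quadrat, 10 quadrats per
transect, 3 transects per reef), invertebrate quadrat counts (0.25 m²) and
belt-transect fish counts (100 m²).

## Synthetic data generator

All tables are produced by `reefdiet.simulate` from a single `SimConfig`.
Randomness flows from one global seed through named substreams
(CRC-32-keyed `SeedSequence` children), so each stage — fish, diets,
surveys — can be regenerated independently and still reproduce the
full-pipeline draws exactly.

* **Ages** are integer uniform on the species range (3–9 yr for the
  browser, 3–8 yr for the predator): annuli are integer counts.
* **Lengths** are the zone-specific von Bertalanffy prediction at age plus
  Gaussian noise (default SD 3 mm). The per-zone growth parameters in the
  default configuration are the published per-zone fits (e.g. browser inner
  bay L∞ = 110.47 mm, K = 0.19 yr⁻¹, t0 = −2.00 yr), so the generator's
  truth block doubles as the reference table for recovery checks.
* **Weights** follow W = a L^b exp(ε), ε ~ N(0, σ_z²), with b = 3 and a
  chosen so mean weights sit near the reported species means. The browser's
  σ_z is 0.06 / 0.05 / 0.10 across outer / inner / disturbed zones: the
  disturbed zone carries twice the inner-bay SD, a designed ~4-fold
  condition-variance inflation matching the magnitude reported for the real
  browser population. The predator has σ = 0.05 everywhere.
* **Diets** are Dirichlet-multinomial: per fish a composition is drawn from
  a species-by-zone Dirichlet (total concentration 25, floor 0.05 per
  taxon) and reads are multinomial at a lognormal depth (medians 25,000 and
  6,000 reads; log-SD 0.5). The paper reports no per-taxon proportions, so
  the zone profiles are illustrative: anthozoan-dominated (outer) to
  annelid-dominated (disturbed) for the browser; benthic macrocrustaceans
  (outer) to planktonic copepods (inner zones) for the predator. The
  concentration of 25 gives visible fish-to-fish compositional
  overdispersion, as metabarcoding read tables show.
* **Benthos**: the expected live-coral fraction for a reef is drawn from
  the zone's Normal(mean, SD) — 33.46 ± 3.41, 12.06 ± 2.3, 0.34 ± 0.39 % —
  and each quadrat annotates 100 points multinomially across three coral
  genera and six other categories. Coral-genus evenness declines along the
  gradient so Shannon diversity falls with cover. Invertebrate and fish
  counts are Poisson with zone-specific rates.

What the generator does **not** emulate: sequence-level artefacts (chimeras,
PCR bias, index hopping), spatial autocorrelation between reefs, tag
switching, or fish-level covariance between condition and diet. Passing
tests therefore demonstrate that the estimators recover the generating
parameters and hold their nominal error rates under this idealized
structure, not that the field estimates themselves are correct.

## Body condition

`fit_length_weight` is OLS of ln W on ln L (natural logs). `compute_kn`
evaluates K_n = W / (a L^b) on the raw measurement scale with
a = exp(intercept). This is deliberate: Le Cren's factor is a ratio of raw
weights, its displayed scale is ≈ 1, and because OLS log-residuals sum to
zero the geometric mean of K_n over the fitting sample is exactly 1 (a
tested invariant).

`fit_condition_interaction` fits K_n ~ logL * zone by OLS with sequential
(Type I) ANOVA in the order zone, logL, logL:zone; partial
η² = SS_term / (SS_term + SS_resid). Marginal slopes per zone and all
pairwise slope differences come from the coefficient covariance; contrast
p-values use the studentized-range distribution with the number of zones as
the group count and the model's residual df (Tukey adjustment), which can
only raise p relative to the unadjusted t-test (tested).

`lnvr_pairwise` computes lnVR = ln(SD₁/SD₂) with the Nakagawa-style
small-sample correction 1/(2(n₁−1)) − 1/(2(n₂−1)) added by default (a flag
disables it; the terms cancel at equal n). By default it is applied to the
residuals of the interaction model — variability *after* controlling for
fish size — not to raw K_n. CIs are percentile bootstrap over
case-resampling within each group, B = 1000 by default, with an explicit
seed; a contrast is "significant" when the CI excludes zero. Under equal
generating variances the CI-excludes-zero rate measured over 500 replicates
stays within [0.02, 0.09] (nominal 5 %); percentile bootstrap intervals on
variance ratios are known to be slightly liberal or conservative depending
on kurtosis, hence the band rather than a point target.

## Growth

`fit_vbgf` minimizes Σ(L_i − L∞(1 − e^(−K(t_i−t0))))² with
Levenberg–Marquardt least squares. t0 is fixed at −2.0 yr by default —
matching reference fits in which every zone prints the same t0 — with a
free-t0 mode available (requiring ≥ 4 distinct ages). Start values form a
ladder: L∞₀ = 1.1 × max length with a Ford–Walford-flavoured K₀ from the
mean-length gradient, then progressively dispersed (L∞, K) pairs; the best
converged solution wins. Noise-free data generated from each reference
parameter row refit to ≥ 4 significant digits (tested, and recomputed by
`scripts/acceptance.py`).

`bootstrap_vbgf` case-resamples fish within zone (the paper does not state
the resampling unit; within-zone matches the comparison being made), refits
each resample warm-started at the zone's point estimate, and reports
percentile 95 % CIs. Two zones "differ" for a parameter iff the CIs are
disjoint — the simple overlap rule, intentionally conservative. If more
than 20 % of refits fail the bootstrap aborts as unstable.

## Community analysis

Bray–Curtis d = Σ|x−y| / Σ(x+y) is computed on per-sample relative
abundances by default (read depth is a nuisance), on binarized tables for
the presence–absence view (equivalent to Sørensen), or on raw counts for
toy examples. PCoA double-centers −d²/2 and eigendecomposes; axes with
negative eigenvalues (non-Euclidean input) are reported but never returned
as coordinates, and a request for more axes than exist is satisfied with
fewer plus a flag. NMDS minimizes Kruskal stress-1 by alternating isotonic
regression of disparities on the dissimilarity rank order (ties averaged)
with Guttman configuration updates; it runs 20 random starts plus a PCoA
start (defaults: k = 2, tol 1e-6, max 300 iterations) and keeps the
lowest-stress solution; the per-iteration stress trace of the winning start
is exposed and is non-increasing (tested).

PERMANOVA uses Anderson's pseudo-F on squared dissimilarities with the
(1 + #{F_perm ≥ F_obs}) / (1 + n_perm) p-value estimator, which can never
return zero. Labels are permuted freely by default — the reference analysis
does not state a restricted scheme — with an optional `strata` argument for
within-stratum permutation. The statistic matches scikit-bio's
implementation to machine precision and the p-value matches exhaustive
relabelling enumeration on small instances (both tested). Pairwise
contrasts rerun the test on each group pair's sub-matrix with Bonferroni
correction (p × number of pairs, capped at 1).

## Diet profiles

Taxonomic aggregation sums reads by lineage label at a rank, pooling
OTUs unassigned at that rank into an explicit `unassigned` column; total
reads are conserved at every rank. Sample-based rarefaction draws random
sample subsets without replacement (n_draws per subset size) and matches
exhaustive subset enumeration on toy tables (tested).

The Amundsen–Costello analysis uses relative read abundance. FO_i is the
percentage of fish containing prey i; P_i is prey i's share of the diet
summed over only those fish. Quadrant labels use FO = 50 % and P_i = 50 %
thresholds — the diagram is usually read visually, but thresholds make the
dominant / rare / BPC-leaning / WPC-leaning classification testable. The
between- and within-phenotype components are reported as quadrant counts,
not a scalar index, because no formula for WPC/BPC is established.

Prey-abundance models are negative-binomial (NB2, log link) with Gaussian
random intercepts, fit by maximum likelihood with nested one-dimensional
Gauss–Hermite quadrature (`reefdiet.glmm`): the reef-level integrals are
conditionally independent given the zone effect, so the nested zone/reef
structure needs only two 1-D grids. No installed Python package fits this
model; the implementation agrees with R's glmmTMB on fixed effects,
dispersion and log-likelihood (tested via Rscript). Two response modes are
provided because fitting count distributions to transformed counts is
statistically irregular: `offset` (recommended) models raw prey counts with
a log total-depth offset; `mimic` applies the stated transformation
(sqrt / fourth-root / log) and rounds to the nearest integer, reproducing
the transform-then-model convention, and is labelled as such in results.
Predictor significance is a likelihood-ratio χ²₁ against the same model
without the predictor. Numerical choices: 11 quadrature nodes per level
(9-node grids proved unreliable on depth-offset fits); Nelder–Mead over
(β, log θ, log σ) with log-SDs clipped at −6 so variance components can
collapse to numerical zero; the full model warm-starts at the null optimum
with slope 0, guaranteeing the nested-likelihood ordering up to optimizer
tolerance; cold fits try both a moderate (0.3) and near-zero (0.05)
variance start because few-group likelihoods hold distinct local modes.
LRT statistics are clipped at zero. The coral-cover predictor is the
reef-level mean percent cover joined to fish by reef. With only three
zones, a zone-level predictor is nearly collinear with the zone random
intercepts; information about the cover effect comes from within-zone
variation, so detection power depends on the generating random-effect SDs
(the null-calibration and power tests reflect this).

## Survey statistics

Kruskal–Wallis H is tie-corrected with ε² = H(n+1)/(n²−1). Dunn's test uses
tie-corrected pooled rank variance and two-sided normal p-values with
Benjamini–Hochberg step-up adjustment. One-way ANOVA reports Tukey HSD
intervals via the studentized range; zero residual variance with unequal
means yields a flagged F = ∞ rather than an error. Shannon H′ is in nats
(no base is canonical for cover data; nats compose with the natural-log
conventions used elsewhere) over coral-genus point counts. Percent coral
cover per reef is the two-stage mean — quadrats averaged within transect,
transects averaged within reef — which differs from the pooled mean when
quadrat counts are unbalanced. Densities are count/area per replicate with
reef mean ± SD and zone means across reefs (belt 100 m², quadrat 0.25 m²).

## Problem sizes and determinism

Every stochastic routine takes an explicit seed, and the pipeline derives
per-stage seeds from one global seed; identical configuration and seed
reproduce byte-identical output files (tested via manifest checksums).
Calibration suites use 200 replicates with compact per-replicate designs
(24-sample PERMANOVA with 199 permutations; 9 reefs × 8 fish GLMMs with
7-node quadrature), sizes at which the uniformity of null p-values is
already well resolved by a Kolmogorov–Smirnov test at α = 0.01. The lnVR
coverage check uses 500 replicates at the study's own group size (n = 60,
B = 1000).

## Known limitations

* The NB mixed model supports random intercepts only (no random slopes)
  and at most the two-level zone/reef nesting.
* Percentile bootstrap CIs (lnVR, VBGF) are first-order accurate; BCa is
  not implemented.
* NMDS convergence is local; with few samples different seeds can reach
  different embeddings of equal stress (the seed fixes the answer).
* The Amundsen quadrant thresholds (50/50) are a reporting convention, not
  an inferential boundary.
* With three zones the zone-level variance component is estimated from
  three draws and is intrinsically noisy; interpret σ_zone qualitatively.
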