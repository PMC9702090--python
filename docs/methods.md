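# Methods

This note records the models, defaults and numerical choices behind
`enviromets`, and what the synthetic-data tests do and do not demonstrate
about real trial data.

## Environmental covariables

Raw daily inputs per location are the nine variables of a standard
satellite-derived daily weather export (mean/max/min/dew-point temperature,
relative humidity, precipitation, 2 m wind speed, shortwave insolation,
downward longwave flux). Derived covariables:

- Saturation vapor pressure uses the Tetens form
  e_s(T) = 0.6108·exp(17.27T/(T+237.3)) kPa; actual vapor pressure is
  e_s(T_dew); **VPD** = ½[e_s(T_max)+e_s(T_min)] − e_a, floored at 0.
- **Δ (SVP slope)** = 4098·e_s(T_mean)/(T_mean+237.3)² kPa °C⁻¹.
- **Solar geometry**: daily extraterrestrial radiation RTA and daylight
  hours N from latitude and day-of-year via inverse relative Earth–Sun
  distance, declination and sunset hour angle (solar constant
  0.0820 MJ m⁻² min⁻¹). **Actual sunshine n** inverts the Ångström
  equation R_s/RTA = a + b·(n/N) with a = 0.25, b = 0.50, clipped to
  [0, N].
- **ETP** defaults to Priestley–Taylor (α = 1.26) on net radiation
  (albedo 0.23, FAO-56 net outgoing longwave with clear-sky ratio clipped
  to [0.3, 1]); the FAO-56 Penman–Monteith reference-crop form is available
  via `etp_method="penman_monteith"`. ETP is floored at 0. The
  psychrometric constant is computed from station elevation.
- **PETP** is fixed as precipitation − ETP (positive = water surplus).
  Descriptions of this quantity's sign convention vary in the literature;
  the package documents and tests this one.
- **GDD** = max(0, (T_max+T_min)/2 − T_base), T_base default 8 °C.
- **FRUE** is a piecewise-linear cardinal-temperature factor in [0, 1] with
  defaults (T_b, T_opt1, T_opt2, T_ceil) = (9, 26, 32, 45) °C, the usual
  maize cardinal range; both GDD base and cardinal temperatures are
  configuration knobs because published values vary by crop and author.

## Envirotype matrix, kernel and delineation

Within the May–October growing season, each covariable is aggregated per
calendar month: means for state variables, sums for fluxes/accumulations
(precipitation, ETP, PETP, GDD, n, N, RTA); the aggregator is a design
choice, as window statistics are not standardized in the literature. With
20 years × 19 covariables × 6 windows this yields 2,280 descriptors per
environment. Columns are standardized across environments using the
population SD (so a standardized column has exactly unit SD and the QC rule
is scale-exact); any column containing a |z| > 3 cell is removed whole. With
only 10 environments the maximum attainable |z| is √9 = 3, so QC removals
appear only with more environments — consistent with small-n studies
retaining all descriptors.

The kernel K_E = WW′/(trace(WW′)/n) is computed on the standardized W
(unstandardized kernels are dominated by large-magnitude covariables, and
the trace normalization presumes comparable column scales). Clustering uses
the kernel-induced Euclidean distance d(i,j) = √(K_ii+K_jj−2K_ij), which
preserves the kernel geometry, with average linkage (UPGMA). The number of
MEs `k` is user-supplied (default 4); no automatic cut criterion is applied
silently. Cluster labels are renumbered by each cluster's alphabetically
first member, making the labeling invariant to input order.

Environmental typology classifies each trial day of each covariable into
classes bounded by the global quantiles (0.01, 0.25, 0.50, 0.75, 0.975,
0.99) across all trial days, then reports relative day frequencies per
(ME, year, crop stage), with stages in days after sowing: 0–14, 15–35,
36–65, 66–90, 91–120.

## Trial model and REML

The plot-level model is y_ijkn = μ + G_i + M_j + Y_k + GM_ij + GY_ik +
MY_jk + GMY_ijk + REP_n(jk) + ε_ijkn with the intercept fixed and all other
terms independent zero-mean normals; the replicate is the location × block
combination nested in ME × year. Estimation is REML on Henderson's
mixed-model equations: three EM warm-up iterations, then average-information
(AI) Newton steps with the AI matrix projected to positive definite
(eigenvalue clipping), step-halving, non-negativity clamping, and an EM
fallback whenever a proposal fails to improve the restricted likelihood.
Components falling below 10⁻⁸·var(y) are fixed at the zero boundary.
Convergence requires both parameter movement below 10⁻⁸·var(y) and
likelihood change below 10⁻⁸; typical fits take 10–20 iterations. The
restricted log-likelihood is evaluated from the same factorization via
−2ℓ = (n−p−q)·log σ²_ε + Σ q_t log σ²_t + log|C| + y′Py + const, so
likelihood-ratio tests refit without one term and refer
2(ℓ_full − ℓ_reduced) to χ²(1) by default (conservative at the boundary;
the 50:50 χ²₀:χ²₁ mixture is available). The fitter reproduces lme4's REML
estimates and log-likelihoods to numerical precision on crossed designs,
and the closed-form ANOVA estimators on balanced one-way layouts.

Heritability uses the genotype-mean basis with σ²_P = σ²_G + σ²_GY/K +
σ²_GM/J + σ²_GMY/(JK) + σ²_ε/Σreps, where Σreps is the total number of
location×block×year combinations (60 for a 10-location, 3-block, 2-year
trial) — the only reading of the replicate divisor that is consistent with
the reference trial's published σ²_P values.

Small-sample caveat: variance components keyed by very few levels (a year
factor with K=2, ME×year with 8 cells) have extremely wide REML sampling
distributions, and truncation at zero makes their estimates biased in
moderate designs even though the estimator is correct — simulation recovery
at the default design reproduces generating values within ~10% only for
components with adequate level counts (G, GMY, REP, residual). This is a
property of the design, not of the implementation.

## Stability, MPS, MTMPS

Genotype × year means within an ME pool all of the ME's locations and
blocks (pooled and per-location-average means coincide for balanced data;
pooling is used and documented). Wricke's ecovalence is the row sum of
squared double-centered residuals of that matrix; Σ_i W_i equals the
genotype×year interaction sum of squares. Rescaling to 0–100 is linear and
direction-aware — (new max, new min) = (100, 0) for increase-desirable
traits and (0, 100) for decrease-desirable traits and for W_i (lower
ecovalence is always better); a constant vector carries no information and
maps to 50 with a warning rather than claiming a best/worst. MPS weights
default to θ_Y = 70, θ_s = 30 (performance-leaning), and the scenario scan
covers the 21 ratios 100/0, 95/5, …, 0/100 with average ranks on ties.

The factor analysis of the genotype × trait MPS table uses
principal-component extraction from the correlation matrix, retains factors
with eigenvalue > 1 (falling back to one factor, with a warning, if none
qualifies), varimax rotation with Kaiser row normalization, and regression
scores F = Z(A′R⁻¹)′ computed from the rotated loadings. The ideotype (100
for every trait) is standardized with the genotype-sample column means/SDs
and pushed through the same scoring map; MTMPS is the Euclidean distance to
its scores. This makes MTMPS consistent under any common increasing affine
transform applied jointly to the data and the ideotype target, but not
under rescaling of the data alone — the 0–100 MPS scale is part of the
definition. Selection takes the round(intensity·q) smallest distances
(0.23·26 → 6), with label-order tie-breaks for determinism. Selection
differentials ΔS% = (X_s − X_o)/X_o·100 are reported for trait means
(desired sign per trait direction) and for ecovalence (desired sign always
negative).

## Synthetic data

The weather generator emulates a temperate summer growing season: per
location-year, temperature follows a seasonal cosine peaking mid-July plus
stationary AR(1) daily noise (default SD 1.5 °C, ρ = 0.6, giving the
temporal autocorrelation that typology windows require); the diurnal range
and dew-point depression are positive AR(1) processes (guaranteeing
T_min ≤ T_mean ≤ T_max and VPD ≥ 0); RH is derived from dew point
(respecting [0, 100]); precipitation is a wet-day Bernoulli × exponential
mix; insolation is a clearness fraction times RTA. Four default archetypes
(wet-warm, hot, dry-continental, cool) are assigned to 10 locations in a
1/3/4/2 pattern; archetype offsets are constant in expectation, so
between-archetype separation versus daily noise controls delineation
difficulty. Each (location, year) stream is seeded independently from the
master seed, so outputs are byte-stable and independent of iteration order.

The trial generator draws every model effect i.i.d. normal at its factor
level with the configured variances (defaults are the nine-trait component
sets of a published maize MET, so recovery tests double as reference
checks). Traits are drawn independently; the generator does not model
cross-trait genetic correlation (tests needing correlated traits construct
them explicitly), nor real climate trajectories, spatial field trend, or
non-normal effects — the normality assumption is exposed as a hook rather
than hidden. Passing tests therefore demonstrate internal statistical
correctness of the chain under its own assumptions, not predictive validity
for any particular real dataset.

The distribution of the replicate (location×block) effects is taken as
normal, like every other term; this is an assumption of the generator, not
a claim about any particular field design.

## Numerical/degenerate-input policy

- Kernel: all-zero W is rejected (normalization undefined); PSD is enforced
  to −10⁻⁸ tolerance in tests; symmetry is restored after rounding.
- Clustering: duplicated environments merge at height 0 and always share a
  label; k outside [1, n] is rejected.
- Rescale: constant input → 50 everywhere (warning); outputs clipped to
  [0, 100] against floating-point endpoint fuzz.
- Factor analysis: constant columns are dropped with a warning; a singular
  correlation matrix falls back to the pseudo-inverse (flagged).
- REML: confounded terms (a factor with one level) are rejected by name;
  non-convergence warns and reports the iteration trace; LRT p-values are
  flagged unavailable (never fabricated) if a reduced fit fails.
- Typology: empty (ME, year, stage) groups are omitted and logged, not
  emitted as NaN.
- Selection: an intensity that selects zero genotypes is rejected.

## Problem sizes used in the test suite

Simulation-based checks run at deliberately compact sizes chosen to make
the suite quick while keeping each property's signal unambiguous: cluster
recovery uses 2–5 year archives, LRT power uses a 12-genotype × 4-location
design, REML recovery uses 200 replicates of the full 26×10×2×3 design,
and factor-retention recovery uses 200 tables at q = 100.
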