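# Methods

This note documents the statistical procedures implemented in
`panelcausal`, the choices made where the methodology is genuinely open,
the numerical conventions, and the limits of what the synthetic-data tests
establish.

## Data model

All stages consume a `BalancedPanel`: `N ≥ 2` units × `T ≥ 5` consecutive
periods × named variables, stored as dense per-variable `N×T` matrices.
Balance is a hard requirement — a missing cell is an error naming the
(unit, period, variable); no imputation is offered. Period labels are
calendar years, but only their order enters any computation. Values are
finite reals with no sign restriction (net-migration-like series are
negative for net-outflow countries). Long-format CSV/TSV I/O uses
round-trip float parsing so write→read is lossless and row order is
irrelevant.

## Cross-sectional dependence tests

All four tests are built from the pairwise Pearson correlations ρ̂ᵢⱼ of
unit-level residual series:

* Breusch–Pagan LM = T Σᵢ<ⱼ ρ̂²ᵢⱼ, χ² with N(N−1)/2 df (upper tail). Valid
  for T large relative to N; over-sized otherwise.
* Scaled LM = √(1/(N(N−1))) Σᵢ<ⱼ (T ρ̂²ᵢⱼ − 1), standard normal
  (upper tail).
* CD = √(2T/(N(N−1))) Σᵢ<ⱼ ρ̂ᵢⱼ, standard normal, **two-sided** —
  the CD statistic can take either sign; the LM variants cannot be
  negative in expectation under dependence and are tested upper-tail.
  These conventions are fixed and documented rather than configurable.
* Bias-adjusted LM standardizes (T−k) ρ̂²ᵢⱼ by its exact finite-sample
  moments under normal errors given the per-unit OLS projection
  complements Mᵢ = I − Xᵢ(Xᵢ'Xᵢ)⁻¹Xᵢ':

  E[(T−k) ρ̂²ᵢⱼ] = tr(MᵢMⱼ)/m,
  Var = a₁ tr(MᵢMⱼ)² + 2 a₂ tr((MᵢMⱼ)²),  m = T−k,
  a₂ = 3/(m+2)², a₁ = a₂ − 1/m².

  These moments follow from a sequential spherical-symmetry argument
  (conditioning on one unit's residual direction at a time) and reduce
  exactly to the Beta(1/2, (m−1)/2) moments of a squared correlation when
  the two units share a design matrix. They are exact for fixed regressors;
  with stochastic regressors they hold conditionally. The Monte Carlo size
  suite verifies nominal 5% size at 2000 replications.

**Residual model for per-variable testing.** Applying correlation-based
tests to raw levels of trending/integrated series produces degenerate
correlations (everything trends together). The default residual model
`adf1` therefore tests the residuals of a unit-wise regression of Δy on an
intercept and the lagged level; `level_demeaned` (within-unit demeaned
levels) is available as an option and the report records which was used.

## Slope homogeneity

The dispersion (delta) test compares unit-wise OLS slopes b̂ᵢ with a pooled
weighted fixed-effects slope. After within-unit demeaning: per-unit
variances σ̃²ᵢ are estimated from pooled-FE-slope residuals with divisor
T−1; the WFE estimator re-weights by 1/σ̃²ᵢ; the dispersion is
S = Σᵢ (b̂ᵢ − b̂_WFE)' (Xᵢ'Xᵢ/σ̃²ᵢ) (b̂ᵢ − b̂_WFE). Then

Δ̃ = √N (S/N − k)/√(2k),  Δ̃_adj = √N (S/N − k)/√(2k(T−k−1)/(T+1)),

both upper-tail standard normal. The adjusted version corrects the
small-sample variance and is the one whose size is enforced by the Monte
Carlo suite (N=20, T=40, homogeneous-slope null).

## CADF / CIPS unit-root testing

Per unit: OLS of Δyᵢt on an intercept (optionally a trend), yᵢ,t−1, the
cross-sectional averages ȳt−1 and Δȳt, plus p lags of Δyᵢt and Δȳt; the
CADF statistic is the t-ratio on yᵢ,t−1, truncated to [−6.19, 2.61]
(constant case; [−6.42, 1.70] with trend) so extreme draws cannot dominate
the panel average. CIPS is the arithmetic mean of the unit CADF statistics,
exactly. Rejection: CIPS below the critical value.

* **Augmentation order.** The default is p = 1 (a 21-period panel cannot
  support deep augmentation); p is recorded in results and selectable 0–3.
* **Critical values.** The embedded tables were generated by direct Monte
  Carlo simulation — independent pure random walks, unaugmented CADF
  regressions, 100 000 replications per grid point over
  N ∈ {10,15,20,27,30,50} × T ∈ {15,21,30,50,100}, both deterministic
  cases, seed recorded in `_cips_cv.py` — which is the same experiment that
  defines the reference tables for this test family. Off-grid (N, T) are
  bilinearly interpolated, clamped at the edges. A seeded
  `simulate_cips_critical_values` reproduces any entry; the test suite
  checks a fresh 10 000-replication simulation at (N=27, T=21) against the
  embedded 5% value within ±0.05.
* **Integration orders.** A variable is I(0) if level CIPS rejects at 5%,
  else I(1) if the differenced series rejects; failure after `max_diff`
  differences is an error. `dmax` is the maximum order across variables.

## Heterogeneous panel causality (lag-augmented VAR)

For each unit, a bivariate VAR in **levels** of order kᵢ + dmax with
intercept. The Wald statistic tests joint nullity of the coefficients on
the first kᵢ lags of the source variable in the target equation; the dmax
augmentation lags are never restricted, which is what keeps the statistic
asymptotically χ²(kᵢ) whatever the integration or cointegration properties
of the pair. The residual variance uses the degrees-of-freedom divisor
(n − p). The Monte Carlo suite confirms the χ²(1) null distribution at
T = 100 (KS test plus 5% rejection within binomial error, 5000 reps).

* **Lag selection.** kᵢ minimizes the bivariate VAR AIC over 1..k_max
  (default 3), all candidates fitted on the common effective sample
  t = k_max + dmax + 1..T; ties break to the smaller order. Each pair's kᵢ
  is selected once per unit and shared by both directions, so a pair's two
  tests rest on one estimated system.
* **Fisher combination.** λ = −2 Σ ln πᵢ with πᵢ floored at 1e−16 before
  logs (a literal zero would make λ infinite); reported p-values keep full
  precision and only printing rounds to 3 decimals.
* **Bootstrap panel inference.** λ ~ χ²(2N) requires independent units, so
  under cross-sectional dependence the asymptotic p-value over-rejects. The
  bootstrap: estimate every unit's target equation under the null (first kᵢ
  source lags excluded, augmentation lags kept) on the **common** effective
  sample t = maxᵢ(kᵢ) + dmax + 1..T so residual vectors share the time
  index; center residuals per unit; resample time indices i.i.d. with
  replacement, drawing whole cross-sectional residual vectors (this
  preserves the contemporaneous correlation structure); rebuild each
  pseudo-series recursively from the restricted estimates and the observed
  initial conditions; recompute λ* with the same kᵢ. The p-value is
  (1 + #{λ* ≥ λ})/(B + 1), never exactly zero. Failed replicates are
  redrawn, counted, and capped at 10% of B. Replicate streams derive from a
  single master seed, so results are bit-reproducible. The size suite
  verifies: under a one-factor null (N=10, T=50) the bootstrap holds 5%
  size within binomial error over 300 outer replications while the χ²(2N)
  asymptotic rejects at a strictly higher rate.
* **Small-panel caveat.** When N ≥ T the result carries a note that only
  the bootstrap p-value is operative; no further correction is applied.

## CS-ARDL mean group

Per unit: yᵢt on intercept, yᵢ,t−1, each regressor at lags 0 and 1, and
cross-sectional averages of (y, x…) at lags 0..pT, with pT = ⌊T^(1/3)⌋ by
default (2 for T = 21). Long-run θᵢ = (β₀+β₁)/(1−φᵢ); error-correction
coefficient −(1−φᵢ). The mean-group estimate is the simple average with
standard error √(Σ(bᵢ−b̄)²/(N(N−1))). The error-correction
re-parameterization (Δy on yₜ₋₁, Δx, xₜ₋₁, averages) spans the same column
space, so both forms give identical long-run and adjustment estimates; the
test suite enforces agreement to 1e−8 on every fit.

Conventions: `pT = 0` disables the cross-average augmentation entirely,
making the fit coincide exactly with a plain ARDL mean-group estimator
(this is the oracle used to validate the implementation). Units with
singular designs are dropped with a warning; mean-group aggregation
requires ≥ 80% of units. A mean ECT outside (−2, 0) and T < 30 each raise a
report note. The short-run block reports the ECM-form coefficients (the
contemporaneous-difference coefficients); the algebra is stated above
because published tables often print the differenced form without showing
the re-parameterization.

Known limitation: with a persistent (near-integrated) regressor and
moderate T, the per-unit lagged-dependent-variable bias (O(1/T)) pushes the
MG error-correction estimate away from zero — at T = 100 and an I(1)
regressor the measured bias on an ECT of −0.5 is about −0.06, and the
cross-average nuisance terms add to it. The recovery suite therefore uses a
stationary exogenous regressor, which isolates the algebra and aggregation
from that bias; users with highly persistent regressors and short panels
should expect adjustment speeds to be somewhat overstated.

## Typology

Labels per ordered pair from the two directional p-values at an
**inclusive** threshold (p ≤ α, default α = 0.10 — required so borderline
printed values like 0.050 count as significant): None / A→B / B→A /
Bidirectional. Classes: *bidirectional* if any pair is Bidirectional,
*none* if all labels are None, else *unidirectional*. Profiles are exact
label-triples; dominant-source groups are rule-based: any bidirectional
pair → feedback; no edges → none; a single source variable → that variable
dominant; both non-migration variables predicting migration and nothing
else → recipient; otherwise multi-linkage. An optional interpretive mapping
to narrative regime labels is provided but flagged as interpretive; the
rule-based groups are the package's output. Classification is a pure
function of the p-values and α; lowering α never moves a country up the
none → unidirectional → bidirectional ladder (property-tested).

## Synthetic data

The generator produces balanced panels with: per-variable processes
(random walk, AR(1), trend-stationary), one common factor per variable
(AR(0.5)) with loadings U(0.5, 1.5) by default, idiosyncratic normal
innovations, optional planted causal links applied at the innovation layer
(so integrated series inherit lagged dependence), optional slope
heterogeneity in AR coefficients, and migration-like series that are
sign-unrestricted and can be block-averaged over w-period windows to mimic
the artificial smoothness of five-year cumulative migration estimates (the
suite verifies this raises lag-1 autocorrelation on average). Seeding is
counter-based per (unit, variable) stream: the same seed yields the same
panel on any platform, and enlarging N does not perturb earlier units'
idiosyncratic draws. The default configuration is the study shape: N = 27,
T = 21, all variables I(1), one factor.

What the generator does **not** emulate: the actual moments of World Bank
series (levels, trends, volatilities are not calibrated), structural
breaks, heteroskedasticity, and cross-variable factor correlation. Passing
tests therefore establish the statistical properties of the procedures
under the assumed data structure — size, power, recovery — not the
empirical conclusions one would draw from any real panel.

## Packaged printed tables

`panelcausal/data/printed_pvalues.csv` and `printed_fisher.csv` transcribe
published per-country Wald statistics and p-values (27 EU countries × 6
directions among CO₂ per capita, health expenditure per capita, net
migration) and the panel Fisher statistics. These are printed,
3-decimal-rounded values: a `0.000` entry means p < 0.0005. They serve as
inputs to the classification layer and to the Fisher-combination worked
example (which reproduces the printed 90.565 as 90.351, the difference
being input rounding); they are not outputs of this package's estimators,
whose numeric replication would require the underlying World Bank panel.

## Numerical conventions

OLS uses column-equilibrated normal equations with a scale-invariant rank
guard (condition number of the equilibrated Gram matrix); exact collinearity
and zero columns raise rather than silently regularize. Chi-square and
normal tail probabilities come from scipy. All Monte Carlo utilities take
explicit seeds; the pipeline manifest records seed, configuration hash and
package versions so a run is fully reproducible from its manifest.

## Problem sizes used in the validation suites

Worked examples run on the printed 27-country tables. Monte Carlo suites:
Wald null distribution at T=100, 5000 replications; bootstrap-vs-asymptotic
size at N=10, T=50, 300 outer × 200 bootstrap replications; directional
power at N=10, T=50, 80 replications with a 0.5 coefficient planted in half
the units; dependence/homogeneity sizes at 2000 replications each; CIPS
critical-value agreement at 10 000 replications; CS-ARDL recovery at N=27,
T=100, 200 replications. These sizes give binomial standard errors small
enough for 3-sigma acceptance bands while keeping the full suite around ten
minutes on one CPU.
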