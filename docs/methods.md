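# Methods

This note records the statistical model behind `allomkit`, the numerical
choices made where several conventions exist, what the synthetic stand
generator does and does not emulate, and the package's known limitations.

## Height–diameter models and fitting

All ten candidate models are written with additive error on the natural
height scale, H = f(θ, D) + ε, including the two forms that are linear
after a log transform (the log-scale quadratic
H = exp(a + b·lnD + c·ln²D) + ε and the log-linear H = a + b·lnD + ε).
Fitting therefore always minimizes Σ(H − f(θ, D))² on untransformed
heights — the response is never exponentiated-transformed, so the error
structure assumed by the fit matches the written form exactly.

The optimizer is Levenberg–Marquardt (`scipy.optimize.least_squares`,
`method="lm"`) with finite-difference Jacobians, convergence tolerances of
1e−14 on relative parameter/objective change, and up to five restarts from
multiplicatively jittered copies of a deterministic, data-driven start.
On floating-point ties the deterministic start's optimum is kept, so fits
are reproducible bit-for-bit given the data and the jitter seed.
Starting values per model:

* asymptote parameters: a₀ = 1.05·max(H);
* Michaelis–Menten rate: Lineweaver–Burk linearization (OLS of 1/H on 1/D);
* Weibull / Gompertz / logistic / exponentials: rate and shape from the
  appropriate log-linearization, clipped into a feasible range;
* quadratic, power, modified-exponential, log-linear: OLS on the
  transformed scale.

Non-convergence is reported (`converged=False`, message retained), never
raised, so a failed form cannot silently drop out of a ranking; ranked
output flags such fits and sorts them last. Degenerate inputs (constant
heights, fewer than arity + 2 trees) raise immediately.

Parameter standard errors come from the Gauss–Newton approximation
(JᵀJ)⁻¹·s² at the optimum with s² = SSE/(n − K), K the regression
parameter count.

## Selection statistics

* RSE = √(SSE/(N − K)).
* Pseudo-R² = 1 − SSE/SST with SST about the mean height; adjusted as
  R² − ((K − 1)/(N − K))·(1 − R²).
* AIC = 2k − 2 lnL with Gaussian log-likelihood
  lnL = −N/2·(ln2π + ln(SSE/N) + 1). By default k = K + 1, counting the
  error variance as an estimated parameter — the convention of mainstream
  statistical software, and the one consistent with published
  model-selection tables of this kind (k = K is available behind a flag).
* Ranking is lexicographic: adjusted pseudo-R² descending, then RSE
  ascending, then AIC ascending.

A structural caveat: over realistic diameter ranges and ~4 m of height
noise, the leading asymptotic forms (Michaelis–Menten, Weibull,
three-parameter exponential, log-scale quadratic) approximate one another
to within hundredths of a metre of RSE. The top rank is then decided by
sampling noise; simulate-refit experiments at n ≈ 800 show the generating
form winning only about half of replicates, losing to a neighbour by
≤ 0.02 m RSE otherwise. Rankings should be read as identifying the
*leading class* of models, not a uniquely best form.

## Observed-vs-predicted diagnostics

Validation regresses observed heights on predicted heights by OLS.

* **Graybill's test**: F = (β̂ − θ)ᵀ XᵀX (β̂ − θ) / (2·MSE) with
  θ = (0, 1)ᵀ, referred to F(2, n−2).
* **Error-sum decomposition**: Σ(obs − pred)² splits *exactly* into
  n(ō − p̄)² (bias) + (b̂ − 1)²·Σ(pred − p̄)² (consistency) + SSE of the
  obs-on-pred regression (residual lack-of-fit); the cross terms vanish by
  OLS orthogonality. Bias and consistency are each tested on 1 df against
  the regression residual MS — their sum over 2·MSE is algebraically
  identical to Graybill's F, which is how a significant joint test can
  coexist with individually non-significant intercept and slope
  components. The overall model lack-of-fit tests (Σ(obs − pred)²/n)/MSE
  on (n, n−2) df. The residual component cannot be tested against its own
  mean square (that ratio is identically 1), so non-linear deviation is
  probed by the curvature F of adding a quadratic term to the obs-on-pred
  regression — the construction that actually answers the question the
  component is meant to ask.

## Species and phylogeny

The species effect is a linear mixed model of H on lnD (optionally ln²D)
with a species random intercept, fitted by REML (`statsmodels` MixedLM
with its default optimizer; L-BFGS was observed to stall on the variance
boundary for exactly the configurations used here and is deliberately not
requested). Marginal and conditional R² follow the variance-share
formulation: R²m = σ²_fixed/(σ²_fixed + σ²_species + σ²_resid), R²c adds
σ²_species to the numerator, with σ²_fixed the population variance of the
fixed-effect predictions.

PGLS regresses per-species maximum height on ln(maximum diameter) and its
square under a Brownian-motion covariance C[i,j] = shared root-to-MRCA
path length, via GLS. Its pseudo-R² is computed against the GLS
intercept-only model with the same covariance, so C = I reproduces OLS
exactly (a tested identity, as is the star phylogeny). Phylogenetic
signal is Pagel's λ, profiled by bounded ML on [0, 1] scaling the
off-diagonal covariance; Blomberg's K is out of scope. Per-trait maxima
are taken independently (Dmax and Hmax may come from different stems) and
unidentified taxa are excluded.

## Biomass

Six published equations (kg per stem; D cm, H m, ρ g cm⁻³) are evaluated
exactly as printed, including their multiplicative log-bias correction
factors CF = exp(RSE²/2). The várzea with-height equation circulates in a
dimensionally incoherent printed form (an un-exponentiated log-linear
right-hand side); the default here evaluates the exponentiated moist-forest
form, with the literal expression available behind `strict=True` for
audit. ρ enters in g cm⁻³ with no unit auto-conversion.

Biomass applies to stems ≥5 cm DBH. The filter acts at aggregation, not
at load, so sub-5 cm stems still inform height modeling; excluded counts
are reported, never silent. Wood density is resolved per stem by exact
(trimmed, case-folded) taxonomic match at species level, then genus mean,
then family mean, then — only after all taxonomic matching — the
arithmetic mean of the resolved stems in the same plot. Densities already
present are never overwritten, making assignment idempotent.

Plot totals convert to Mg ha⁻¹ with per-stem expansion factors
(1/subplot-area for the stem's size stratum) when the sampling design is
known, else with the plot area. Cumulative curves accumulate per-ha
biomass over 10-cm DBH classes and conserve the total by construction.

Carbon accounting is the closed form ΔC = area × mean AGB × proportional
correction × carbon fraction (default 0.485), reported in Pg C and
optionally priced per Mg C.

## Error metrics

For paired (est, meas): TE = √(mean(err²)), SE = mean(err),
RE = √(Σ(err − SE)²/(n−1)), and the proportional CVTE/CVSE/CVRE computed
on per-tree ratios (est − meas)/meas — per-tree first, never
ratio-of-aggregates. TE² = SE² + ((n−1)/n)·RE² holds exactly and is
enforced by property test. With n = 1, RE and CVRE are NaN markers, not
zero. Size classes are half-open intervals [low, high) over configurable
breakpoints (default one break at 30 cm); an "all" row is always present.

## The synthetic stand generator

`generate_stand` emulates what the analysis assumes about inventory data:
a right-skewed diameter distribution thinned by a size-stratified subplot
design (with the matching expansion factor recorded per stem), heights
H = f(θ, D) + species intercept + iid Gaussian noise floored at 1.2 m,
a dominance-skewed species pool, and truncated-normal wood densities. All
randomness flows from one integer seed through named `SeedSequence`
streams, so each stage is independently reproducible and repeat runs are
bit-identical.

The two presets encode contrasting Amazonian forest types. Their
parameters were fixed once, by deterministic calibration against the
stand structure each preset is meant to emulate, before any test was
written against them:

* diameter laws are truncated Weibulls solved so the (thinned) sample
  matches mean ± SD of DBH(≥5 cm) ≈ 24.5 ± 16.8 cm (terra firme, with
  the nested 0.0125/0.25/0.5 ha design) and 22.4 ± 18.6 cm (várzea), and
  so the implied height variance reproduces the target fits'
  pseudo-R² (≈0.86 and ≈0.63);
* the target residual SDs (4.018 and 4.161 m) are split into a species
  random intercept (SD 1.50 / 1.53 m, sized so the species effect
  explains ≈2% / 5% of height variance) and iid noise (3.726 / 3.867 m),
  so a fixed-effects refit recovers the target RSE while a mixed-model
  refit recovers the species share;
* species pools: 367 taxa with a Zipf-like tail (top species ≈3.6%) for
  terra firme; 65 taxa with one dominant at 36% for várzea.

What the generator deliberately does **not** emulate — and what passing
tests therefore do not demonstrate about field data:

* **Heteroscedastic height errors.** Field height-measurement error
  shrinks for short trees; the generator's noise is homoscedastic (the
  additive-ε reading of the model forms). Consequently per-tree
  proportional errors acquire a positive convexity bias
  (E[1/(f + ε)] > 1/f) concentrated in small stems: even the true
  generating curve scores a mean proportional deviation of several
  percent against its own noisy sample, and for stems of 1–5 cm the
  proportional metrics are dominated by floor-truncated outliers.
  Proportional (CV) comparisons on synthetic stands are therefore
  evaluated on stems ≥5 cm and read as signs and orderings, not as
  point replications; absolute TE/SE/RE are unaffected.
* Spatial structure, competition, growth dynamics and flooding; stems
  are exchangeable within plots.
* Real taxonomy: taxa are synthetic labels with a deterministic
  genus→family mapping, sufficient to exercise the density-fallback
  chain and mixed/PGLS machinery, not to represent any flora.

`generate_phylogeny` produces a pure-birth (Yule) ultrametric tree —
sufficient for Brownian-covariance tests; no extinction, no rate
variation.

## Problem sizes and tolerances

The test suite runs the full study scale: presets of 1,156 and 806 stems,
a 100-replicate simulate-refit recovery study (3-SE coverage and ranking
identifiability), a 30-replicate REML variance-component study at
n = 1,500, and grid-search oracles (20 points per parameter) at n = 50
per model form. Closed-form identities are asserted at 1e−8–1e−9
relative; zero-noise parameter recovery at 1e−4 relative; stochastic
quantities at the tolerances stated in each test. The acceptance script
re-runs the whole pipeline in under a minute on one CPU.

## Known limitations

* Top-rank identifiability among near-equivalent asymptotic forms is
  weak at realistic noise (see Selection statistics above); report the
  leading class.
* Mean proportional errors (CVSE) on additive-noise synthetic data are
  upward-biased by small-stem convexity; see the generator section.
* Extrapolation beyond the fitted diameter range is unguarded except for
  the monotone-domain report (the quadratic's turning point
  exp(−b/(2c)) is exposed for c < 0).
* PGLS assumes the supplied tree's branch lengths are meaningful;
  building trees from megatrees is out of scope.
* No heteroscedastic or quantile fitting; least squares is unweighted
  throughout.
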