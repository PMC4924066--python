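# Methods and design notes

## Model family and assumptions

The package models hourly crash counts on road segments as a zero-inflated
negative binomial with site-specific random effects. The two-state mixture
reflects a substantive claim about refined-temporal-scale crash data: many
segment-hours are *structurally* safe (probability q_it, logit-linear in
covariates), and the remainder produce counts from an NB2 process whose mean
λ_it is log-linear in covariates. Overdispersion α > 0 is the gamma-mixing
parameter of the NB (Poisson as α → 0): the NB count is a Poisson whose rate
is λ_it times a mean-one gamma variate with shape 1/α. Site effects σ_i
(count state) and ψ_i (zero state) are independent zero-mean normals with
standard deviations φ_σ, φ_ψ; they induce within-site correlation across the
repeated hourly observations and make the panel likelihood a per-site
integral. Observations are independent across sites and, conditional on the
site effect, across hours; there is no further temporal autocorrelation and
no spatial correlation between sites.

The panel is *unbalanced*: t_i, the number of retained hours, differs across
sites (sensor outages). Nothing in the likelihood requires balance; sites
enter through contiguous row blocks.

Three random-effect configurations are supported — σ only (default), ψ only,
both (independent, product quadrature). The default mirrors the common
reporting practice of a count-state effect only; if both were free their
correlation is taken as zero, since the model family defines them as
independent normals.

## Numerical likelihood

All density arithmetic is in log space. The y = 0 branch of the NB uses the
closed form (1/(1+αλ))^(1/α), so the dominant zero rows need no log-gamma;
log-gamma and digamma are evaluated only on the rare positive counts.
Per-site integrals use non-adaptive Gauss–Hermite quadrature (default order
15 per random dimension, product rule when both effects are free); a φ of 0
collapses the corresponding dimension to a point mass exactly.
Log-sum-exp combines nodes. Linear predictors are clamped at ±600 on the log
scale before exponentiation and the clamp count is logged. Quadrature
accuracy is test-gated (order 31 vs 63 below 1e−8; order 31 vs 10⁶-draw
Monte-Carlo integration within 1e−3).

## Estimation

Maximum marginal likelihood via L-BFGS-B on an unconstrained internal scale
(ln α, ln φ) with bound guards (ln α ≥ ln 1e−6, ln φ ≥ ln 1e−4); a parameter
ending at its guard is reported at the boundary with a flag, never an error.
The gradient of the marginal likelihood is analytic — including the
quadrature weights' dependence on φ — and is verified against central finite
differences in the test suite to ~1e−9 relative error; a numeric
(central-difference) gradient mode is retained as an option. Analytic
gradients were chosen as default because the simulation studies
(recovery, Vuong operating characteristics) require hundreds of fits and a
~27-parameter numeric gradient costs ~55 likelihood evaluations per
iteration.

For optimization only, non-binary design columns are mean-centered
(intercept/slope collinearity otherwise slows quasi-Newton convergence
badly on covariates with large means); estimates, the Hessian and the full
covariance are mapped back and reported on the original scale. Indicators
are never rescaled.

Initialization is staged along the ladder: Poisson (intercept at log mean
count) → NB (α by method of moments) → ZIP/ZINB (zero-state intercept from
the excess-zero fraction, slopes 0) → ZINB-RE (φ from the between-site
spread of site-level residual log-means, log[(Σy_i + ½)/(Σμ̂_i + ½)]).
Zero-inflated likelihoods are multi-modal; the ladder keeps each start in
the basin of the interpretable optimum, and stationarity (refit from the
optimum moves < 1e−5) is test-gated.

Standard errors are the square roots of the diagonal of the inverse observed
information (numerical Hessian of the marginal log-likelihood by central
differences of the analytic gradient, default relative step 1e−4,
step-halving stability test-gated at 0.1%), delta-method-mapped from the
internal to the reported scale for α and φ. A non-positive-definite Hessian
falls back to a flagged pseudo-inverse. AIC = −2LL + 2k and
BIC = −2LL + k ln N with N the number of rows and k the free parameters of
the configuration. (Mixed-model software sometimes uses the number of
*sites* in BIC's ln term; the row-count convention is used here and stated
so comparisons are unambiguous.)

Variable selection is deliberately not automated: the package reports
p-values and the covariate lists are user-supplied.

## Model selection

The Vuong statistic V = m̄√N / s_m is computed from per-observation
log-density ratios m_it between the zero-inflated model and its parent;
V > 1.96 favors zero-inflation, V < −1.96 the parent (threshold
overridable). For random-effects fits the per-observation density is the
*marginal single-observation* density — the site effect integrated out row
by row — because the statistic is defined per observation and the fitted
pooled densities are also exposed; the comparison used is recorded in the
result. Identical densities on every row raise a defined degenerate-
comparison error.

Because the ZINB *nests* its parent at the q ≡ 0 boundary, the two models
overlap, and the uncorrected statistic systematically favors the larger
model on data generated from the parent: the extra zero-state parameters
buy a real finite-sample log-likelihood gain that m̄ does not discount.
`correction="aic"` (subtract (k₁−k₂)/N from m̄) or `"bic"` mitigates this;
the uncorrected statistic remains the default because it is the convention
of the published crash-frequency analyses this package follows. The
operating-characteristics study in the acceptance suite documents the
behaviour: decisive power under a zero-inflated truth, but inflated
false-selection of zero-inflation under a plain-NB truth at matched designs
— a property of the statistic itself (reproduced identically by an
independent implementation), not of this optimizer.

The overdispersion decision prefers NB over Poisson when α̂'s one-sided
t-statistic clears the requested level (default 95%), and prefers Poisson
when α̂ sits at its boundary.

## Elasticities

For E[n] = (1 − q)λ: a count-state-only continuous covariate has elasticity
β·x̄ at the sample mean; a count-state-only indicator has pseudo-elasticity
1 − e^(−β) (relative change in E[n] attributable to the indicator, measured
against the indicator-on level). Covariates entering the zero state have no
closed form at the mean — their elasticity depends on the distribution of
q_it — so they are observation-averaged: mean over rows of
x_it(β_NB − β_z q_it) for continuous covariates (the exact d ln E/d ln x),
or the averaged relative change under a 0→1 toggle for indicators. The
averaged forms reduce exactly to the closed forms for count-state-only
variables, which is test-gated, as is agreement with a brute-force 0.1%
perturbation of the model-implied mean. Reports label which method produced
each value and which x̄ was used.

## Synthetic data generator

The generator emulates a one-year hourly study of a 57-segment interstate
corridor: 57 sites × 365 × 24 hours with per-site random outage blocks
(exponential block lengths, mean one week; per-site missing fractions drawn
around 34.2%, targeting ~65.8% retention ≈ 328k rows at full scale), then
counts drawn forward from the random-effects ZINB with the published
coefficient estimates as generating truth (α = 1.818, φ_σ = 0.484, count
and zero designs as published; all other surveyed covariates are generated
with zero coefficients, enabling false-positive checks).

Covariate marginals match the published summary table: truncated normals
whose *truncated* mean is calibrated to the target (bisection on the
location), a moment-matched lognormal for hourly volume (right-skewed by
its printed moments), Bernoullis for indicators, a discrete 3/4/5-lane
distribution matched to mean and variance, and a zero-spike + exponential
for precipitation. Deterministic consistency rules replace unavailable
dependence information: temporal indicators derive from a shared clock
(each site's observation window gets a random phase within the year, so
short horizons still sample all seasons); wet and chemically-wet surfaces
are mutually exclusive; the low-speed-limit (< 60 mph) and long-rutting-
life (> 99) indicators derive from their underlying site-constant
continuous variables. Everything else is drawn independently — only
marginal moments are published, and independence suffices for recovery
testing.

One deliberate calibration: with independent covariates the published
count-state constant implies a marginal mean count of ~0.0028 (measured on
a 1.4M-row pilot) rather than the study's 0.004, because real covariates
are correlated. The generator's default constant carries a fixed +0.363
offset restoring E[count] ≈ 0.004. The realized mean still varies
substantially across seeds (±30%): 57 site-level draws of large-coefficient
site-constant covariates and site effects dominate, exactly as a single
realized corridor would.

What passing tests do **not** show about real data: the generator has no
covariate cross-correlations (weather–surface–visibility dependence), no
temporal persistence in weather or traffic within a site, MCAR missingness,
and no spatial structure. Recovery results are therefore evidence about the
estimator under the model, not about robustness to real-world dependence.

## Problem sizes used in the studies

Simulation studies run at desk scale, chosen once: the recovery study uses
the reference scenario at 57 sites × 2000 hours/site (~72k rows, ~270
crashes), 20 replicates, quadrature order 9; the Vuong study uses pooled
panels of N = 20,007 (57 × 351 hours) with the count constant raised by
ln 12 so a panel carries ~900 crashes — sized a priori from the
√events scaling of V, since at the reference event rate a 20k-row panel
holds ~80 crashes and no test could have usable power — with 100
power and 50 null replicates. Generator calibration checks use 3 full-scale
panels for hour-varying covariates and 60 short-horizon seeds (57 sites
each) for site-constant ones, so every marginal is measured with adequate
effective sample size.

## Known limitations

- Non-adaptive quadrature: for extremely long site panels the integrand
  sharpens and adaptive (mode-centered) quadrature would need fewer nodes;
  order 15 with the convergence gate has been sufficient here.
- With realistic event rates (~0.004/hour), α and φ_σ are weakly identified
  at desk-scale panels; boundary fits are flagged, and SE-based inference
  on them should be read cautiously.
- The uncorrected Vuong statistic should not be used as evidence *for*
  zero-inflation on small effect margins; prefer the AIC-corrected variant
  when the zero state carries many covariates.
- Median-bias summaries of weakly identified slopes at 20 replicates are
  dominated by the sampling noise of the median (~0.28·SE), not by
  estimator bias; the coverage criterion (3 reported SEs) is the meaningful
  recovery gate at these sizes.
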