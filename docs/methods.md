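# Methods

## The yield model

For each crop separately, log yields follow a linear model of a
technology trend and three weather exposures, with county-specific
intercepts and slopes drawn from a covariate-level regression:

    log Y_it ~ N(α_i + β_i¹ t + β_i² CDI_it + β_i³ GDD_it + β_i⁴ EDD_it, σ_i²)
    α_i      ~ N(a_0 + Σ_j b_j⁰ covar_ij, σ_α²)
    β_i^k    ~ N(a_k + Σ_j b_j^k covar_ij, σ_{β^k}²)

The six covariates (annual mean temperature, isothermality, temperature
seasonality, annual precipitation, precipitation seasonality, per-crop
irrigation fraction) are z-scored over the fitted counties; predictors
are standardized per crop (CDI/GDD/EDD divided by their pooled SD, the
trend centered at the panel's first year), so coefficients read as
log-yield change per SD of exposure. The residual variance is either
shared (`variance_mode="uniform"`) or county-specific
(`variance_mode="county"`), the latter with a hierarchical lognormal
prior, log σ_i ~ N(μ_s, τ_s²), which keeps variances identified in
counties observed for few years.

Partial pooling is the point: σ_α and σ_{β^k} are estimated, so the
data decide how far county coefficients may stray from their
covariate-implied means, and a county never observed growing a crop
still gets a coefficient distribution — the covariate mean plus the full
between-county dispersion.

### Priors

The model statement above does not pin down priors; the package uses
weakly informative defaults chosen once: normal(0, 5) on hyper-intercepts and
loadings (covariates standardized), half-normal(0, 2.5) on all SDs, and
for county variances μ_s ~ N(0, 2), τ_s ~ half-normal(0, 1). At the
panel sizes used here the likelihood dominates all of them.

### Sampling

Inference is a blocked Gibbs sampler, exact for this model:

1. each hyper row γ_k = (a_k, b·^k) from its conjugate normal
   conditional given the county effects;
2. each group SD from its univariate conditional *with the county
   effects integrated out* (the marginal needs only per-county 5×5 Gram
   matrices), by slice sampling — together with step 3 this is a joint
   (σ_group, θ) block and removes the scale/effect coupling that makes
   naive centered sweeps mix slowly;
3. the county block (α_i, β_i) jointly from its 5-dimensional normal
   conditional, batched over counties;
4. an ancillary-sufficient interweaving move: re-expressing
   θ_i = W_i γ + σ_group·z_i and redrawing (γ, σ_group) jointly with z
   held fixed (scales sampled unconstrained and folded by absolute
   value), which decorrelates the hyper level from the county effects;
5. residual scale(s) by slice sampling (one slice per county in county
   mode, vectorized).

Because the county block is drawn jointly from its exact conditional,
the funnel geometry that motivates non-centered parameterizations in
gradient-based samplers does not arise at the panel sizes targeted here
(tens of years per county). The degenerate limit σ_group → 0 is instead
handled analytically: when group SDs are pinned below 1e-3 the county
level collapses and the sampler runs on the equivalent
covariate-interacted regression (35 coefficients), which is the exact
model in that limit. Pinning the SDs large simply freezes step 2.

Diagnostics (split-R̂, bulk ESS via arviz) are attached to every fit;
fits with max split-R̂ above 1.01 are flagged with a warning and
`converged=False`, never silently returned. Gibbs transitions have no
divergences; the field is reported as 0 for interface uniformity.
Typical fits here (50–200 counties, 4 chains × 1000 draws after 500
warmup) converge with hyperparameter ESS in the hundreds to thousands.

## Weather predictors

Degree-days use the single-sine method: one sine wave interpolates the
diurnal cycle between tmin and tmax, and the area between thresholds has
a closed form (arcsin/cosine); the constant-temperature day is the
analytic limit, no special case. GDD accumulates between the crop's base
and ceiling; EDD accumulates above the damage threshold with no upper
cap, the standard extreme-degree-day convention. The shipped per-crop
season windows and thresholds (e.g. corn base 8 °C, damage threshold
29 °C) are conventional values from the degree-day literature,
configuration rather than estimates, and can be replaced via a YAML
calendar file.

The crop water deficit index is the normalized seasonal shortfall
Σ max(0, PET_d − P_d) / Σ PET_d ∈ [0, 1]. Published deficit indices
differ (some track a soil-moisture bucket); this package deliberately
uses the simplest normalized-deficit form and isolates it behind one
function so an alternative accounting is a drop-in replacement. A
season with zero PET is defined as zero deficit, with a warning.

## The synthetic world

The generator (`cropshift.synth`) emulates the *structure* of a US
county panel without claiming its geography: covariates with realistic
ranges (county mean temperature ~5–25 °C, precipitation correlated 0.35
with temperature, Beta-distributed irrigation fractions), weather
predictors whose county means track climate (degree-day exposure rising
with mean temperature, deficit index falling with precipitation),
county coefficients drawn from the hierarchical model above, and an
economics table with 2010-era price/cost magnitudes. Defaults chosen
once as the study conditions: residual SD 0.10 (10% yield noise),
σ_α = 0.12, σ_β = (0.004, 0.02, 0.02, 0.03), an EDD effect of −0.10 per
SD at average covariates, 40% of counties designated with an observed
crop that is not the local profit argmax (the calibration workload),
and cultivation costs scaling with the square root of local expected
yield so that a county's best crop is typically viable — mismatch is
only designated where the runner-up crop is itself profitable, since
nobody is observed planting a money-losing crop at scale.

Two modes matter for testing. In `"faithful"` mode the joint
distribution is exactly the fitted model's likelihood, which is what
parameter-recovery and coverage checks require. In `"misspecified"`
mode additional Student-t(3) noise is added to county coefficients
beyond the covariate model. Plain extra normal noise would still lie
inside the model class (a sum of normals is normal), so heavy tails are
used to create genuine misspecification; this is the regime in which
county-intercept interacted regressions over-fit while partial pooling
stays robust, and in which the fitted group SDs are clearly positive
(little pooling applied).

Missingness mirrors why prediction into new counties is hard: a crop is
absent from counties in the bottom quantile (default 20%) of its
covariate-implied suitability, plus 3% random county-year dropout; every
county keeps at least its most suitable crop. What passing tests on this
world do *not* show: robustness to real-data features the generator
omits — spatial autocorrelation of coefficients beyond covariates,
measurement error in yields, reporting gaps correlated with bad years,
non-Gaussian weather extremes.

## Model comparison

R² is the unadjusted 1 − SSE/SST on log yields. Under the temporal
holdout all models are fit on the first 75% of years (configurable) and
evaluated on the rest; the denominator mean defaults to the evaluation
observations' own mean, with a train-mean option, since either
convention is defensible. Negative values are reported as-is — they are
the signature of an over-fitted model extrapolated forward. The four
least-squares baselines cross intercept structure (uniform / county
indicators / covariate-interacted) with slope structure (uniform /
covariate-interacted); the county-intercept + interacted-slope variant
omits covariate main effects on the intercept, which would be collinear
with the indicators. Prediction in a county absent from a
county-intercept fit errors by default; an explicit fallback to the
mean fitted intercept exists and is flagged, never silent. Bayesian
point predictions evaluate the mean function at the average of the
parameter draws (for this linear-in-parameters mean identical to
averaging per-draw predictions).

## Reallocation

Per posterior draw, expected yield is exp of the mean function — the
optimizer targets expected profit, and resampling observation noise
would only inflate switching spuriously. Yields for every county × crop
cell come from the coefficient model, so crops can be evaluated in
counties that never grew them; a crop entering a county is priced at
that county's irrigation capacity through the irrigation covariate
(`apply_irrigation_adjustment` exposes the pathway in isolation).

Hidden-cost calibration makes each county's observed crop the per-acre
profit argmax by the minimal cost adjustment plus a margin ε (default
1 USD/acre): either raising competitors' costs (default) or lowering
the observed crop's — the adjustment direction is genuinely
underdetermined, so both modes ship. Calibration is done once against
posterior-mean baseline yields, not per draw, so the cost table is a
single dataset shared by all draws.

The LP maximizes Σ (p·Ŷ − o)·A subject to A ≥ 0, county land caps (row
sums) and national crop caps (column sums); with a switching cost s the
objective subtracts s·max(0, A_ic − Ā_ic), linearized with slack
variables. The constraint matrix is a transportation-type incidence and
totally unimodular, so with integer supplies the LP optimum is integral
— which is why exhaustive integer enumeration is a valid exactness
oracle on small instances. HiGGS's primal/dual solutions give a
per-solve duality-gap audit (tolerance 1e-6 relative); constraints are
re-audited post-hoc on every Monte Carlo draw. The status-quo
comparison is paired within draw: the same draw's yields are evaluated
on baseline areas, so optimized ≥ status-quo holds draw by draw because
the status quo is feasible.

A county's "allocated crop" is its largest-area crop, ties broken
toward the baseline dominant crop (conservative: fewer spurious
switches); a county planting nothing counts as fallow, and a change to
fallow counts as a switch. Corn↔soy exchanges are excluded from the
second switching statistic as a pairwise swap (the two are commonly
rotated); any other reading of "excluding corn–soy swaps" would need
only a different filter in `summarize_switching`. The land-flow matrix
uses a min-stay rule — acres keep their crop up to min(baseline, new),
only each county's surplus flows to deficit crops proportionally or to
fallow — so an unchanged allocation is exactly diagonal. Future periods
keep the trend predictor at its baseline value: the scenarios isolate
climate shifts from technology-trend extrapolation.

Credible intervals on all outcomes are equal-tailed 2.5/97.5 empirical
quantiles across posterior-draw optimizations.

## Pipeline and problem sizes

The experiment driver expands one root seed into fixed per-stage seeds
(SeedSequence), writes every artifact as a commented CSV plus a
SHA-256 manifest, and is bit-reproducible: re-running a config
regenerates identical files, which doubles as the recovery mechanism
for deleted intermediates. Default problem sizes (tens of counties,
20–40 years, hundreds to a few thousand posterior draws, ≤100 Monte
Carlo optimizations) were chosen so a full study runs in minutes on one
CPU while keeping Monte Carlo error well inside the tolerances the
tests assert; they scale up by config only.

## Known limitations

- Coefficients are exchangeable given covariates; spatially correlated
  county effects are out of scope.
- The deficit index is a stand-in for bucket-model accounting.
- The economics are partial-equilibrium by construction: the national
  crop-total caps are the device that avoids modelling price responses.
- No agronomic constraints (rotations, field sizes) and no new-land
  expansion; integer acreage is not enforced (the LP relaxation is
  integral only when supplies are).
- The irrigation adjustment moves yields through the covariate pathway
  only; it does not model irrigation expansion or water availability.
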