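# Methods

`lepitrend` implements the full analysis chain used by Pollard-walk
butterfly monitoring schemes to turn weekly transect counts into
population trends, together with a calibrated synthetic-data generator
that provides known ground truth for every stage. This note documents the
models, the generator, the numerical choices, and what the package's
tests do and do not demonstrate.

## The monitoring design being modeled

Volunteers walk fixed transects roughly weekly through a 30-week
April–October season, counting every butterfly within ~5 m. Coverage is
incomplete (typically ~23 of 30 weeks surveyed) and surveys vary in
duration, so raw seasonal sums confound abundance with effort and
phenology. The analysis chain therefore:

1. converts calendar time to thermal time (growing degree-days),
2. fits a regional flight-curve model per species and imputes the
   missing weeks,
3. integrates completed weekly counts into a site × year × species
   population index,
4. fits an overdispersed Poisson mixed model for the log-linear trend,
5. relates species' trend coefficients to life-history traits with and
   without phylogenetic correction.

## Degree-days and flight curves

Daily growing degree-days use the simple averaging estimator
`max(0, (tmin + tmax)/2 − base)` with base 5 °C, accumulated from
January 1 within each site-year. This is the plainest of the standard
degree-day estimators; fancier interpolation (single-sine, double-sine)
changes accumulated totals by a few percent but not the relative
placement of flight curves, which is all the model uses.

The flight-curve model for a species is a penalized Poisson regression
(P-spline GAM) of weekly counts on:

- a cubic B-spline basis in accumulated degree-days (default 15 basis
  functions spanning the observed GDD range, second-difference penalty).
  Fifteen functions over a typical 0–3600 GDD support put knots ~260 GDD
  apart, enough to resolve a brood whose flight period has an SD of
  80–100 GDD; a coarser basis visibly biases early-season peak locations
  while the penalty, chosen by GCV, still suppresses unneeded wiggles;
- low-rank additive cubic smooths of site latitude and longitude
  (5 functions each, fixed moderate penalty) standing in for a full
  spatial field — adequate for a smooth regional abundance surface, and
  cheap;
- year as an unpenalized categorical term, so imputation tracks
  year-to-year abundance differences.

The degree-day smoothing weight is selected by generalized
cross-validation, `GCV(α) = n·deviance / (n − edf)²`, over the grid
{0.1, 1, 10, 100, 1000} (a coarser {1, 10, 100} grid is used inside the
end-to-end pipeline for speed). Fitting is penalized Newton/IRLS with
step-halving; the objective is log-concave so this converges to the
global optimum. One model is fitted per species pooling all sites and
years ("regional" flight curves), using site-years with ≥ 5 surveys.

Zero-anchoring (appending artificial zero counts outside the season, a
convention in some schemes) is **not** applied; with degree-day bases
spanning only the observed support it is unnecessary, and it would bias
species whose flight period abuts the season boundary.

Imputation fills only the missing weeks with model-expected counts
(real-valued, not sampled integers — the trapezoid integral consumes
expectations); observed counts pass through bit-exact. Predictions
outside the training degree-day range are clipped to the boundary and
flagged; site-years whose year has no dummy level are left unfilled with
a warning.

## Population indices and effort covariates

The population index is the trapezoid-rule integral of the completed
weekly series over the week index (unit spacing), in butterfly-weeks.
Integration is over weeks, not degree-days: the index is an
effort-standardized seasonal total, and weekly spacing is what the
monitoring design fixes.

Two covariates summarize sampling for each site-year, computed from
observed (non-imputed) surveys only so imputation cannot inflate effort:

- **mean list-length** — mean number of species recorded per survey, a
  synthetic proxy for detectability (weather, observer skill, site
  quality);
- **projected duration** — 30 × mean observed survey duration: the
  total minutes had every week been surveyed at that site-year's mean
  duration. It enters the trend model as an offset, making the response
  a rate of butterflies per minute.

Inclusion filters mirror the monitoring scheme's design: trend models
use site-years with ≥ 10 surveys at sites with ≥ 3 such years; species
qualify for species-level trends when present at ≥ 5 retained sites in
≥ 10 years; all species contribute to the total-abundance aggregation.
For the total model every retained site-year keeps a row (zero
abundance is data); species models are restricted to site-years at
sites where the species was ever recorded, keeping explicit zero rows
there.

## The trend model

For indices `N_sy` (rounded to the nearest integer to stay in the count
family — indices are sums of hundreds of counts, so rounding is
negligible):

    N_sy ~ Poisson(μ_sy)
    log μ_sy = β0 + β1·year_c + β2·listlength_c + log(duration_sy)
               + site_s + year_y + obs_sy

with independent Gaussian random intercepts for site, year (factor) and
observation (site × year). The observation-level intercept is the
standard device for extra-Poisson dispersion in a log-link count GLMM.
The annualized trend is the geometric-mean rate `100·(e^{β1} − 1)` % per
year, independent of the endpoints chosen; cumulative change over `T`
years is `100·(e^{β1·T} − 1)`. Trends are classified
positive/negative/stable by the sign of β1 at Wald p < 0.05.

### Estimation

`glmm.fit_poisson_glmm` implements the Laplace approximation with
crossed random intercepts directly (no installed Python library fits
this model by marginal maximum likelihood):

- For candidate random-effect SDs θ, penalized IRLS (Newton with
  step-halving on the joint log-density; sparse Cholesky via SuperLU)
  finds the joint mode of (β, u); convergence when the gradient ∞-norm
  falls below 1e−7 relative.
- The Laplace deviance
  `−2 log p(y|β*,u*) + ‖u*‖² + log det(Z̃'WZ̃ + I)` is minimized over
  θ ∈ [0, 10] with L-BFGS-B (finite differences, step 1e−4).
- Wald SEs come from the fixed-effect block of the inverse joint
  Hessian at the optimum, conditional on θ.

Fixed effects are profiled at the joint conditional mode (the fast
scheme lme4 exposes as nAGQ = 0) rather than optimized against the full
Laplace objective (nAGQ = 1). On a seeded reference dataset the two
agree on the trend coefficient to 1.5e−4 (≈ 0.01 SE) and on the variance
components to ~2e−3; the intercept differs by ~0.3 SE, the known
systematic difference between the schemes. The fast scheme keeps a
full-pipeline fit to ~5 s at 1 050 observations, which the replicated
recovery experiments need. SDs estimated at the zero boundary are
reported as 0 with a singular-fit warning.

Goodness of fit uses the mixed-model marginal/conditional R²
decomposition on the link scale. The distribution-specific variance is
the lognormal approximation `ln(1 + 1/λ̄)` with λ̄ = exp(β0), the
fixed-effects expected rate per offset unit (butterflies per minute) —
the convention of the established mixed-model R² implementations; using
the raw mean count instead would drive this term to zero for
total-abundance models and push conditional R² to 1 artificially.

Confidence intervals for the trend are parametric bootstrap: simulate
responses from the fitted model (fresh random effects and Poisson
noise), refit, take percentile intervals (default 500 replicates; an
error is raised if > 20 % of refits fail).

Two alternatives guard against model-choice artifacts: a plain Poisson
GLM (no random effects — on simulated data its trend agrees with the
GLMM's to a few thousandths), and a GAMM in which a penalized spline of
year replaces the linear trend. The spline uses the mixed-model
reparameterization of a second-difference-penalized cubic B-spline: the
penalized directions become iid random effects whose SD the same Laplace
machinery estimates, while the penalty null space is spanned by the
model's intercept and linear-year terms. The year-factor intercept is
dropped from the GAMM because the spline plus its wiggliness variance
absorbs interannual structure. Its endpoint-to-endpoint annualized rate
is the nonlinear analogue of the GLMM rate.

## Trait and phylogenetic models

Species trend coefficients are regressed on each life-history trait
separately (range position, voltinism, overwintering stage, host-plant
category and breadth, wing length, wetland dependence, disturbance
tolerance, migratory status), reporting adjusted R²; categorical traits
are dummy-coded against the alphabetically first level. A companion fit
excludes migratory species, whose trends are driven partly by conditions
outside the monitored region. No multiple-testing correction is applied
across the nine trait models — they are reported individually as
exploratory effect sizes.

PGLS assumes Brownian-motion residual covariance on the phylogeny:
`V_ij` is the shared root-to-MRCA path length (computed from tip depths
and patristic distances). Pagel's λ scales the off-diagonals; λ is
estimated by profile maximum likelihood over [0, 1] with bounded scalar
minimization (tolerance 1e−6), guarded by a 21-point grid so boundary
optima are never missed; a profile flatter than 2 log-likelihood units
across [0, 1] triggers a wide-profile warning. λ = 0 reproduces OLS
exactly (tested to 1e−8); λ = 1 is full Brownian covariance.
Coefficient covariance uses the GLS estimate with an n/(n−p) small-
sample variance correction and t-based p-values. Species missing from
the tree are dropped with a warning.

## The synthetic-data generator

`simdata` emulates the statistical structure the analysis assumes, with
every latent quantity returned in a truth record:

- **Sites**: ~3.5° latitudinal extent; daily temperatures are a sinusoid
  peaking in late July (annual mean 11 °C, amplitude 13 °C, diurnal
  range 10 °C, day-level noise SD 2 °C) plus a −2.5 °C per degree
  latitude offset, giving ~2 500–3 500 GDD seasons and a northeast–
  southwest thermal gradient.
- **Species**: flight curves are equal-weight Gaussian mixtures in
  accumulated degree-days, one component per brood (univoltine /
  bivoltine / multivoltine), with peaks placed where a temperate season
  puts them (first broods 250–1300 GDD) and brood SDs of 80–150 GDD.
  Gaussian mixtures are the simplest truth the phenology stage should
  recover. Seasonal totals per site-year span ~30–400 at baseline.
- **Counts**: a surveyed week's expected count is
  `exp(b0 + trend·year_c + site + year + obs) × (weekly flight-curve
  mass) × duration/85`; counts are Poisson given the log-normal
  observation effect, matching the overdispersed Poisson trend model.
  Random-effect SDs default to the calibration targets 0.417 (site),
  0.121 (year), 0.278 (observation).
- **Sampling**: weeks are dropped completely at random with probability
  7/30 (≈ 23 of 30 weeks surveyed); durations are log-normal with mean
  85 and SD 25 minutes, truncated at 10. At most one survey per week is
  emitted. All randomness flows from one seed through spawned
  substreams, so identical configs give byte-identical tables.

Defaults are 50 sites × 21 years; the emulated scheme's 104 sites are
available by argument. The generator does **not** model observer
behavior, weather-dependent detectability, spatial autocorrelation
between sites, or informative missingness — so passing tests show the
estimators are correct under the model's own assumptions, not that those
assumptions hold in any real scheme.

## What the recovery experiments show — and a known attenuation

The end-to-end experiment (`pipeline.recovery_experiment`) simulates 50
sites × 21 years × 12 species all declining at −2 %/yr with the
calibrated variance components, runs the full chain, and compares the
recovered annual rate with truth; at these conditions the truth lies
within 2 SE of the estimate in 19 of 20 seeded replicates, with a mean
recovered rate of −1.7 %/yr.

The gap between −1.7 and −2.0 is a real, diagnosable property of the
method, not an implementation error: the list-length covariate is
computed from the same counts it helps model, so when abundance falls,
the number of species recorded per survey falls too, and the covariate
absorbs part of the trend. Removing the covariate removes the bias
(mean recovered β1 then matches truth to ~3e−4); enlarging the roster
dilutes it, because with many species list-length saturates and tracks
effort rather than abundance. A 12-species roster keeps each replicate
at ~15 s; at the emulated scheme's ~100 species the effect would be
proportionally smaller. The covariate is retained because trading a
small attenuation for robustness to detectability variation is the
design's stated purpose.

Other stated problem sizes: flight-curve recovery uses 30 sites × 5
years (fitted peak within 25 GDD of a 600-GDD brood); the GLM reduction
check uses ten 12 × 10 index tables; the PGLS λ recovery uses 50-tip
birth–death trees; bootstrap behavior is exercised at 20 replicates on
small tables rather than the 500-replicate default, since each bootstrap
replicate is a full GLMM refit.

## Known limitations

- The profiled-β Laplace scheme slightly biases intercepts relative to
  full Laplace ML (trend coefficients are unaffected at the tested
  scales).
- GCV over a 3–5 point grid is coarse; the chosen α occasionally sits a
  grid step from the GCV optimum. Effective df, not α itself, is what
  matters downstream.
- The trapezoid index treats the first and last week as half-weight;
  species flying at the season boundary lose a small, trend-neutral
  fraction of their mass.
- PGLS assumes the trend coefficients are estimated without error;
  measurement-error-aware comparative models are out of scope.
- λ̄ = exp(β0) in the R² denominator is an approximation inherited from
  the lognormal method; R² values are comparative diagnostics, not
  calibrated variance fractions.
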