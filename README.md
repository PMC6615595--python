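# lepitrend

Population-trend estimation for Pollard-walk butterfly monitoring
schemes — from weekly transect counts to species and total-abundance
trends, cross-scheme standardization, and trait/phylogenetic
association. Written for quantitative ecologists who work with
systematic insect monitoring data and want every step of the standard
analysis chain as tested, composable functions, plus a calibrated
synthetic-data generator with known ground truth for validating the
whole pipeline.

## What it computes

Weekly counts from volunteer transects are incomplete (median ~23 of 30
season weeks) and effort-confounded. The pipeline:

1. **Thermal time** — daily growing degree-days, base 5 °C:
   `GDD_d = max(0, (tmin_d + tmax_d)/2 − 5)`, accumulated from Jan 1.
2. **Flight curves** — per species, a penalized Poisson spline (P-spline
   GAM) of weekly counts on accumulated GDD + low-rank spatial smooths +
   year, smoothing by GCV; missing weeks are imputed with expected
   counts.
3. **Population indices** — trapezoid integral of the completed weekly
   series per site × year × species, with mean list-length and projected
   survey duration as effort covariates.
4. **Trends** — an overdispersed Poisson GLMM on the log link,

   ```
   log E[N_sy] = β0 + β1·year + β2·listlength + log(duration)
                 + site_s + year_y + obs_sy
   ```

   with crossed Gaussian random intercepts (observation-level intercept
   for extra-Poisson dispersion), fitted by a Laplace approximation
   implemented in `lepitrend.glmm`. The annualized trend is
   `100·(e^{β1} − 1)` % per year; classification at Wald p < 0.05.
   Alternatives (plain Poisson GLM; GAMM with a year spline) and a
   parametric bootstrap CI guard the main fit.
5. **Comparison & traits** — annual ↔ cumulative rate conversion for
   cross-scheme tables, univariate trait OLS (adjusted R²), and PGLS
   with maximum-likelihood Pagel's λ on a Newick phylogeny.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study —
50 sites × 21 years × 12 species, every species declining at a true
−2 %/yr, with the calibrated variance components (site 0.417, year
0.121, observation 0.278 on the log scale):

```
$ python analysis/01_simulate_surveys.py --seed 1
simulated 50 sites x 21 years x 12 species (seed 1)
  surveys: 24056 of 31500 site-weeks (23.6% missing; target 23.3%)
  median weeks surveyed per site-year: 23 of 30
  mean survey duration: 85 min (target 85)

$ python analysis/02_flight_curves.py
fitted flight curves for 12 species (0 skipped: [])
  imputed 89328 of 378000 species-week counts (23.6%)
  median deviance explained: 0.84

$ python analysis/04_abundance_trends.py --n-boot 50
total abundance GLMM:
  beta_year = -0.0109 (SE 0.0044, p = 0.013)
  annual rate -1.1%/yr (truth -2.0%); cumulative over 20 y: -20%
  RE SDs: site 0.329, year 0.117, obs 0.216 (truth 0.417/0.121/0.278)
  alternatives: GLM rate -0.88%/yr; smooth endpoint rate -2.34%/yr
  bootstrap 95% CI for annual rate: [-1.79%, -0.11%] (50 refits)
species trends (12 eligible): 12 negative, 0 positive, 0 stable
```

Reading this: the scheme detects a significant statewide decline and
classifies all 12 truly-declining species as negative. The point
estimate for this single realization (−1.1 %/yr) sits high of truth for
two reasons documented in `docs/methods.md` — year-level random
variation (only 21 year draws) and a small attenuation from the
endogenous list-length covariate; across 20 replicate schemes the mean
recovered rate is −1.7 %/yr and truth lies within 2 SE in 19 of 20.
Script 06 standardizes published scheme summaries to annual rates:

```
$ python analysis/06_scheme_comparison.py
appended synthetic scheme: -1.1%/yr (-20% over 20 y)
                          region  cumulative  printed  recomputed
    United Kingdom (countryside)       -28.0     -0.8        -0.8
     United Kingdom (specialist)       -63.0     -2.4        -2.4
                     Netherlands       -40.0     -2.0        -2.0
                Catalonia, Spain       -44.0     -2.6        -2.6
synthetic scheme (this analysis)       -19.6     -1.1        -1.1
```

## Layout

```
src/lepitrend/     simdata, phenology, indices, glmm, trends, traits,
                   compare, pipeline — the library every script and test uses
analysis/          numbered narrative drivers (simulate → ... → compare)
tests/             pytest suite incl. acceptance checks
docs/methods.md    models, assumptions, numerical choices, limitations
```
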