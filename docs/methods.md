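# Methods

`divstab` analyses nested grassland survey data — 1 m² plots inside 8 m × 8 m
homogeneous grids inside grassland sites — to ask two linked questions: how
does the plot-level relationship between plant species richness and
productivity (peak aboveground live biomass, g m⁻²) change along a
productivity gradient, and does that change make productivity more *spatially
stable* (less variable across plots) where richness is high?

## The hierarchical mean+variance model

The central model couples the mean and the dispersion of plot productivity to
richness:

```
y_ijk      ~ Normal(α₀ⱼ + α₁ⱼ · r_ijk + α_site,  σ_k)       (plot i, grid j, level k)
log σ_k    ~ Normal(β₀ + β₁ · k,  σ_β)                       (k = integer richness value)
α₀ⱼ        ~ Normal(γ₀,₀ + γ₀,₁ Lⱼ + γ₀,₂ Pⱼ + γ₀,₃ Tⱼ,  σ_α0)
α₁ⱼ        ~ Normal(γ₁,₀ + γ₁,₁ · Ḡⱼ,  σ_α1)
α_site     ~ Normal(0, σ_site)
```

`L`, `P`, `T` are growing-season daylight hours, precipitation total (mm) and
mean temperature (°C) at the grid's site; `Ḡⱼ` is the grid's observed mean
productivity. A "richness level" is the set of plots sharing an integer
species count, so `σ_k` is the across-plot SD of productivity at richness k:
**β₁ is the biodiversity–spatial-variability effect** and **γ₁,₁ measures how
the local biodiversity–productivity slope shifts along the productivity
gradient**. A CV variant replaces `log σ_k` with `log CV_k`, coupled back to
the likelihood through `σ_k = CV_k · μ̄_k`, where `μ̄_k` is the mean
model-implied plot mean at level k, recomputed at every draw — the minimal
coupling that keeps the likelihood proper.

The likelihood is Normal on raw biomass, as the model is written; biomass is
positive but the model is not truncated, and the synthetic-data generator
retains negative draws by default so that generator and likelihood remain
conjugate for recovery tests (an opt-in resampling mode produces
strictly-positive, field-realistic tables).

### Internal standardization — and why it matters

Before fitting, productivity is divided by its global SD (not centered: the
CV variant needs positive level means), the climate covariates and the grid
productivity covariate are z-scored, and richness in the *mean structure* is
centered and scaled. The dispersion regression keeps the raw integer level k.
All transforms are linear; reported draws are mapped back to raw units
exactly.

Centering richness is not cosmetic. The grid-slope equation conditions on the
realized grid mean productivity — a quantity that is itself a function of the
slopes it predicts. With richness left raw, that self-reference tilts the
exact posterior of γ₁,₁ away from the generating value by a factor of
`∏ⱼ(1 − γ₁,₁·r̄ⱼ)` (r̄ⱼ the grid's mean richness): with r̄ ≈ 12 the tilt is
larger than the posterior standard error and no sampler can recover the
truth. Centered richness replaces r̄ⱼ by r̄ⱼ − r̄, whose sum over grids is
≈ 0, and the tilt vanishes. A side effect is that the grid "intercept" α₀ⱼ
becomes the grid's expected productivity at the survey's mean richness, so
γ₀,· and σ_α0 describe *that* quantity — a more interpretable one than the
zero-richness extrapolation, and the regression is no longer entangled with
the slope equation.

### Priors

"Diffuse" priors are made concrete on the standardized scale:
Normal(0, 10⁶) for all location parameters (γ's, β's) and Uniform(0, 100) for
all scales, including the site-effect scale. Because of the internal
standardization these are diffuse regardless of the measurement units of the
input table. Both settings are fields of `HBModelSpec`.

### Sampler

Fitting is by Metropolis-within-Gibbs (`fit_mcmc`), default 3 chains ×
20 000 sweeps, 10 000 burn-in, thinning 5 (tests and the acceptance script
use shorter chains; convergence is checked, not assumed). Design notes:

* **Partially collapsed grid-line hierarchy.** Plain conjugate Gibbs mixes
  pathologically here for two reasons: the well-known funnel between σ_α1 and
  the slopes, and — more insidiously — the within-grid intercept/slope
  correlation, which makes a slope update conditioned on the current
  intercepts reproduce ~90 % of the current slope state. Each sweep therefore
  computes per-grid GLS estimates of (intercept, slope) with their full 2×2
  sampling covariance, updates σ_α0 and σ_α1 by random-walk Metropolis on the
  *pair-marginalized* likelihood (grid effects integrated out), draws
  (γ₀, γ₁) jointly from the corresponding 6-dimensional conjugate normal, and
  only then redraws the per-grid pairs from their exact full conditionals.
* **Translation move.** Site effects and grid intercepts are additively
  confounded; an extra Gibbs step samples the likelihood-invariant direction
  (shift a site's effect, subtract it from that site's intercepts) exactly.
* **Level dispersions.** The σ_k (or CV_k) block uses vectorized random-walk
  Metropolis on the log scale, with per-level step sizes adapted toward
  ≈ 35–44 % acceptance during burn-in only; final acceptance outside
  [10 %, 90 %] raises a warning.
* **Scales.** σ_site and σ_β use truncated inverse-gamma conditionals
  (rejection against the uniform upper bound).
* **CV variant.** The dispersion feedback through μ̄_k breaks conjugacy of
  the mean-structure blocks, so the grid and site updates use the conjugate
  normal computed at the current dispersions as a Metropolis–Hastings
  proposal and accept with the exact ratio (observed acceptance ≈ 50 %).

Determinism: each chain uses `default_rng(seed + 1000·chain)`; identical
calls give identical draws.

### Diagnostics and checks

`gelman_rubin` computes the split-chain PSRF (via `arviz.rhat`,
`method="split"`) per scalar parameter element, with a 1.1 cutoff;
zero-variance parameters are reported as not-applicable rather than silently
passing or failing. `posterior_predictive_pvalues` simulates one full
replicate dataset per retained draw and reports `P_B = Pr(T(y_rep) ≥
T(y_obs))` for T ∈ {mean, SD, CV} across all plots plus the plot-level
exceedance probability; the reported triple defaults to (mean, SD,
plot-level). Values near 0.5 indicate good fit.

## Path-model engine

Observed-variable path analysis with ML estimation on the sample covariance
(denominator N−1): `Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ`, discrepancy
`F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p`, test statistic `(N−1)·F_min`. The
optimizer is BFGS with the analytic gradient of F (error variances
log-parameterized for positivity), starting from per-equation least squares —
which *is* the ML solution for recursive just-identified models, making the
single-equation oracle equivalence exact. Convergence at gradient norm 10⁻⁶
with up to three jittered restarts; standard errors from the observed
information (numerical Hessian of F, `acov = 2/(N−1)·H⁻¹`).

Twelve fit indices are computed against the closed-form independence
baseline (`F = −ln|R|`): χ², GFI, AGFI, RMSEA; NFI, RFI, IFI, TLI, CFI; NC,
AIC (χ²+2q), CAIC (χ²+q(ln N+1)). Indices undefined at df = 0 are reported as
`None`, never as zeros. Multi-group fitting estimates group-specific free
parameters with no cross-group constraints; the pooled discrepancy is
`Σ_g (N_g−1)F_g`.

Model comparison ranks *close-fitting testable* models (χ² p ≥ 0.05) by AIC
then CAIC; a saturated model carries no test of fit and can be selected only
when nothing testable fits closely. (A literal "highest p-value first" rule
would always pick a saturated candidate.)

The retained topology of the plot-level climate→richness→productivity model
is not hard-coded: `climate_richness_productivity_spec` exposes the full
candidate set and `prune_insignificant` drops non-significant paths by Wald
z-test, one at a time.

## Spatial variability

`group_by_richness` starts with one group per observed richness value and
merges deficient groups (< 3 plots by default): scanning from the top of the
richness range, the topmost deficient group absorbs the next-lower group and
any other deficient group folds into the group above it, repeated to a fixed
point. This reproduces the intended behavior on survey-like data — dense
low-richness levels stay singleton bins while the sparse high-richness tail
collapses into a single last bin — and is deterministic. The regression
abscissa of a merged bin is the plot-count-weighted mean richness of its
members (configurable to the bin midpoint). SD uses the n−1 denominator;
CV = SD/mean; an all-equal sample has SD = CV = 0. Simple linear and
quadratic OLS of SD or CV (optionally log-transformed) on bin richness use
statsmodels, reporting coefficients, R² and the regression F p-value.
"Spatial" throughout means across-plot, not geographic distance.

## Stability prediction

`build_grid_lines` turns posterior medians of (α₀ⱼ + site effect, α₁ⱼ) into
one predicted richness–productivity line per grid. `resample_sd` then samples
60 plots per grid without replacement (the survey's grids hold 60–64), scores
each sampled plot by its grid's line at the plot's richness, pools
predictions across grids, and computes the SD of predicted productivity at
each richness level; 1000 replicates give a median and 95 % interval per
level and for the slope of the SD-on-richness regression. Predictions
deliberately exclude the plot-level noise σ_k: the quantity of interest is
the dispersion generated by between-grid differences in the
richness–productivity relationship. Pooling happens across grids *before*
the per-level SD — the only reading that yields a spatial SD. When every grid
contributes equally at level k the estimate converges on
`SD_j(α₀ⱼ + α₁ⱼ·k)`, which is checked in closed form.

## Synthetic-data generator

`GeneratorConfig`/`generate` draw surveys from the model above with known
parameters. Defaults emulate the global survey's structure: 30 sites, 2–14
grids per site, 60–64 plots per grid, zero-truncated-Poisson richness with a
per-grid rate spread (support capped at 52 species), and parameter values
chosen to give grid mean biomass spanning roughly 50–1100 g m⁻², slopes
shifting from positive in unproductive grids to negative in productive ones
(γ₁,₀ = 12, γ₁,₁ = −0.02), and level SDs declining from ≈ 250 g m⁻² at one
species toward ≈ 120 at forty (β₀ = 5.5, β₁ = −0.02).

The Eq-4 covariate is circular at generation time: realized grid
productivity depends on the slopes it predicts. The generator resolves this
with a short deterministic self-consistency iteration (default 5 passes)
holding all noise draws frozen; the update map contracts by ≈ |γ₁,₁|·r̄ ≈ 0.25
per pass, so the covariate the generator conditioned on equals the realized
grid mean to ~10⁻¹³ — exactly the quantity the fitting stage uses. A single
pass would leave a systematic covariate/realization gap large enough to bias
γ₁,₁ recovery.

Richness is generated independently of climate (the Bayesian model
conditions on richness); a `dispersion_mode="cv"` switch draws log CV_k from
the β line instead of log σ_k, giving the CV variant an exact ground truth.

### What the generator does not emulate

No spatial autocorrelation within or between grids, no species composition,
no climate→richness dependence, and plot noise is exactly Normal. Passing
recovery and calibration tests therefore demonstrates the correctness of the
estimation machinery under the model's own assumptions — not robustness to
the ways real grassland data violate them (skewed biomass, measurement
error, non-linear richness effects).

## Numerical choices and degenerate inputs

Productivity-tertile splits sort by (mean productivity, grid id) so ties are
deterministic; remainders go to the higher-productivity groups (151 grids →
50/50/51). The equator takes the northern growing-season window (Jan–Aug); a
site exactly on a daylight lattice node takes the node's value (zero-distance
limit of inverse-distance weighting, Euclidean in degrees within the 1°×1°
cell). Grid-level correlations on degenerate (zero-variance) inputs are
reported as not-applicable. `log_posterior` returns −∞ for parameters outside
the support instead of raising.

## Simulation sizes used by the test suite

Parameter recovery runs 20 replicates at 30 sites × 4 grids × 60 plots with
3 × 1600-sweep chains; PPC calibration 20 replicates at 12 sites × 3 grids;
the χ² calibration 500 simulations at n = 500; the resampling-vs-closed-form
check 40 balanced grids at 1000 replicates. The acceptance script fits the
full default survey (~230 grids, ~14 000 plots) with 3 × 2400-sweep chains.

## Known limitations

* The raw-scale Normal likelihood admits negative biomass; results for very
  low-productivity, high-dispersion levels should be read with that in mind.
* The CV variant's mean-structure updates mix more slowly than the SD
  variant's (Metropolis-corrected rather than collapsed); use longer chains.
* γ₀,· and σ_α0 describe the productivity-at-mean-richness line (see
  standardization section); the zero-richness intercept regression is not
  separately identified without re-introducing the self-reference bias.
* Fit-index formulas are the conventional ML ones; no robust or
  ordinal-data corrections are provided, and no latent measurement models.
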