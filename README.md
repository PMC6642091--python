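# divstab

**Biodiversity–productivity–stability analysis for nested grassland survey
data.**

Global grassland surveys record plant species richness and peak aboveground
live biomass (the annual-productivity surrogate, g m⁻²) on 1 m² plots nested
in 8 m × 8 m homogeneous grids nested in sites. Two questions drive the
analysis this package implements:

1. **Does the local biodiversity–productivity relationship change along a
   productivity (stress) gradient?** — positive where productivity is low,
   negative where it is high, so that richness–productivity lines converge.
2. **Does that convergence make productivity more *spatially stable*** —
   less variable across plots — **where richness is high?**

`divstab` is aimed at ecologists and biostatisticians who want to run this
analysis on their own plot tables, or to study its statistical machinery on
synthetic surveys with known truth.

## What is inside

| module | contents |
| --- | --- |
| `divstab.data_core` | plot-table parsing/validation, grid summaries, productivity tertiles |
| `divstab.climate` | growing-season covariates: daylight hours (inverse-distance interpolation from an integer lon/lat lattice), precipitation total, temperature mean |
| `divstab.synth` | synthetic surveys drawn from the hierarchical generative model with known parameters |
| `divstab.sem` | observed-variable path analysis: ML estimation, standardized solutions, multi-group fits, 12 fit indices, model comparison |
| `divstab.variability` | richness-binned SD/CV spatial-variability metrics and regressions |
| `divstab.hier_bayes` | hierarchical Bayesian mean+variance model (Metropolis-within-Gibbs), split-chain Gelman–Rubin diagnostics, posterior predictive checks |
| `divstab.stability` | grid-level posterior lines → resampled richness–spatial-SD prediction |
| `divstab.cli` | `divstab` command with `simulate`, `fit-sem`, `variability`, `fit-bayes`, `stability` subcommands |

The core model writes plot productivity `y` at richness `r` (plot i, grid j,
richness level k) as

    y_ijk   ~ Normal(α₀ⱼ + α₁ⱼ·r + α_site, σ_k)
    log σ_k ~ Normal(β₀ + β₁·k, σ_β)
    α₀ⱼ     ~ Normal(γ₀,₀ + γ₀,₁Lⱼ + γ₀,₂Pⱼ + γ₀,₃Tⱼ, σ_α0)
    α₁ⱼ     ~ Normal(γ₁,₀ + γ₁,₁·Ḡⱼ, σ_α1)

so **β₁** is the biodiversity–spatial-variability effect (negative ⇒ more
diverse plot groups are less variable) and **γ₁,₁** is the shift of the local
biodiversity effect along the productivity gradient (negative ⇒ positive
effects in unproductive grids, negative in productive ones). A CV variant
regresses `log CV_k` instead. See `docs/methods.md` for the full model,
priors, sampler design and limitations.

## Worked example

Generate a 12-site synthetic survey with known truth (β₁ = −0.02,
γ₁,₁ = −0.02), fit the hierarchical model, check it, and predict the
richness–stability relationship:

```python
import numpy as np
from divstab import synth, hier_bayes, variability, stability
from divstab.hier_bayes import HBModelSpec

cfg = synth.GeneratorConfig(n_sites=12, grids_per_site=(3, 3),
                            plots_per_grid=(60, 64), seed=7)
ds, cov, truth = synth.generate(cfg)

spec = HBModelSpec()
post = hier_bayes.fit_mcmc(spec, ds, cov, chains=3, iterations=2000,
                           burn_in=1000, thin=2, seed=1)
raw = post.raw_draws()
for p in ("beta1", "gamma11"):
    lo, med, hi = np.quantile(raw[p], [.025, .5, .975])
    print(f"{p}: median {med:.4f}  95% CI [{lo:.4f}, {hi:.4f}]")

psrf, ok = hier_bayes.gelman_rubin(post)
print(f"max split-PSRF {max(v for v in psrf.values() if v is not None):.3f} "
      f"(converged={ok})")

ppc = hier_bayes.posterior_predictive_pvalues(post, spec, ds, cov,
                                              n_rep=500, seed=2)
print("Bayesian p-values:", {k: round(v, 3) for k, v in ppc.p_values.items()})

groups = variability.group_by_richness(ds, min_plots=3)
reg = variability.regress_variability(groups, response="sd", form="linear")
print(f"{len(groups)} richness groups; SD-on-richness slope "
      f"{reg.coefficients['richness']:.2f} (p={reg.p_value:.2g})")

lines = stability.build_grid_lines(post, ds)
res = stability.resample_sd(lines, ds, n_plots=60, reps=1000, seed=3)
print(f"predicted SD-richness slope {res.slope_median:.2f}  "
      f"95% [{res.slope_lo:.2f}, {res.slope_hi:.2f}]")
```

Output:

```
beta1: median -0.0239  95% CI [-0.0363, -0.0107]
gamma11: median -0.0242  95% CI [-0.0408, -0.0083]
max split-PSRF 1.015 (converged=True)
Bayesian p-values: {'mean': 0.476, 'sd': 0.636, 'cv': 0.63, 'plot': 0.5}
27 richness groups; SD-on-richness slope -4.07 (p=0.0008)
predicted SD-richness slope -2.03  95% [-2.58, -1.61]
```

Reading it: both 95 % credible intervals cover the generating values and
exclude zero — the fitted survey shows dispersion falling with richness
(β₁ < 0) and biodiversity effects turning negative as grids get more
productive (γ₁,₁ < 0). All split-chain PSRF values are below the 1.1 cutoff,
and Bayesian p-values near 0.5 say replicate surveys simulated from the
posterior look like the data. Downstream, the across-plot SD of productivity
drops by ≈ 4 g m⁻² per added species in the observed bins, and the
resampling of posterior grid lines (60 plots per grid, 1000 replicates)
predicts spatial SD falling by ≈ 2 g m⁻² per species — richness–productivity
lines converge, so productivity is more predictable where richness is high.

The same pipeline runs from the shell:

```sh
divstab simulate --seed 7 --plots plots.csv --covariates cov.csv
divstab fit-bayes --data plots.csv --covariates cov.csv --chains 3 --seed 1
divstab variability --data plots.csv --response sd --form linear
```

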