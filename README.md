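# budbird

Hierarchical Bayesian models linking roadside bird-survey counts to
insect-outbreak defoliation at two spatial and temporal scales.

## The problem

Outbreaks of defoliating forest insects (the motivating case is the
eastern spruce budworm, *Choristoneura fumiferana*, whose larvae are a
superabundant food pulse for several boreal warblers) affect bird
populations both **locally in the outbreak year** — birds settle at
higher density where larvae are abundant — and **regionally with a lag
of a few years**, as the recruits produced during the outbreak disperse
across the landscape. Estimating both responses at once from long-term
roadside survey counts (one count per species per route per year, as in
the North American Breeding Bird Survey) requires separating them from
observer effects, overdispersion, and the underlying population trend.

`budbird` implements that model as a reusable package: a generative
simulator with known ground truth, covariate construction, the survey
inclusion filters, a custom adaptive Metropolis-within-Gibbs sampler,
predicted population trajectories, and an end-to-end pipeline with a
CLI. It is aimed at quantitative ecologists who want to fit, check, or
extend this family of count models on their own data or on synthetic
data with known truth.

## The model

Counts are overdispersed Poisson: `c_{ijt} ~ Poisson(λ_{ijt})` with

```
log λ_{ijt} = γ_{it} + β1_i·b1_{ijt} + β2_i·I1(t)·b2_{it} + ω_j + ζ·I2(j,t) + ε_{ijt}
```

- `γ_{it}` — per-stratum year effect, a first-difference random walk
  `γ_{it} ~ N(γ_{i,t−1}, σ_λ²)` with a diffuse first year
  `N(0, σ_λ²·1000)`;
- `b1_{ijt}` — proportion of the area around route *j* defoliated in
  year *t* (local, same-year);
- `b2_{it}` — mean over the previous 4 years of the stratum-wide
  defoliated proportion (regional, lagged); `I1(t)` gates the term to
  years with a complete trailing window;
- `β1_i, β2_i ~ N(B1, σ_B1²), N(B2, σ_B2²)` — stratum slopes with
  common hyper-means (the headline quantities);
- `ω_j ~ N(0, σ_ω²)` — observer–route intercept; `ζ` — first-year
  observer effect, gated by `I2`; `ε_{ijt} ~ N(0, σ_ε²)` —
  observation-level overdispersion.

Effects are reported as **percent change** `exp(β)·100` (100 = no
change; a log effect of 1.1 is a 300% abundance level under full
defoliation). Predicted per-stratum trajectories average the
exponentiated predictor over the stratum's observer–route combinations
with the lognormal mean correction `+0.5σ_ε²` and scale by the
occupancy proportion `z_i`; comparing the full trajectory `N^b` with
the counterfactual `N^0` (slopes removed) isolates the outbreak's
population-level effect, and an independently fitted "naive" model
(`N^n`, no defoliation information) serves as a model check.

## Worked example

```python
from budbird import (SimulationConfig, SamplerSettings, ModelSpec, simulate_dataset,
                     filter_routes, fit, percent_change, trajectory,
                     budworm_effect_ratio, summarise)

config = SimulationConfig(seed=42)          # 6 strata x 20 routes x 30 years
counts, cov, latent = simulate_dataset(config)
filtered, report = filter_routes(counts)
spec = ModelSpec.build(filtered, cov)
draws = fit(spec, SamplerSettings(chains=2, iterations=5000, burn_in=2500, seed=42))

for name, true in (("B1", latent.truth.B1), ("B2", latent.truth.B2)):
    pc = percent_change(draws.stacked(name))
    print(f"{name}: truth={true:.2f}  percent change = {pc.mean:.0f}% "
          f"(95% CI {pc.q2_5:.0f}-{pc.q97_5:.0f}%)")

nb = trajectory(draws, spec, report, which="budworm")
n0 = trajectory(draws, spec, report, which="no_budworm")
ratio = summarise(budworm_effect_ratio(nb, n0))
print(f"peak posterior-mean N^b/N^0 ratio: {ratio['mean'].max():.1f}")
```

prints (about 10 s on one CPU):

```
B1: truth=1.10  percent change = 338% (95% CI 181-569%)
B2: truth=0.50  percent change = 170% (95% CI 128-221%)
peak posterior-mean N^b/N^0 ratio: 5.2
```

The simulated truth `B1 = 1.1` corresponds to a 300% level
(`exp(1.1)·100`), well inside the credible interval; the regional truth
`B2 = 0.5` corresponds to 165%. The peak trajectory ratio says the
simulated outbreak raised the predicted population of the
most-affected stratum about fivefold at its height.

The same pipeline runs from the shell:

```sh
budbird all --config config.json --out run/ --seed 42
```

with `config.json` holding the simulation (or data paths), prior and
sampler settings; the run directory contains the data, draws,
diagnostics, trajectory tables and a JSON report stamped with the
configuration hash.

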