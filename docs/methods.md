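# Methods

## Model

Counts `c_{ijt}` (route *j*, stratum *i*, year *t*) are Poisson with

```
log λ_{ijt} = γ_{it} + β1_i b1_{ijt} + β2_i I1(t) b2_{it} + ω_j + ζ I2(j,t) + ε_{ijt}
```

The model assumes: counts are conditionally independent given the
latent effects; abundance evolves smoothly on the log scale (the
first-difference prior `γ_{it} ~ N(γ_{i,t−1}, σ_λ²)` penalises
year-to-year jumps); detection heterogeneity is captured by a constant
intercept per observer–route combination plus a single scalar
first-year effect `ζ` shared across all strata (the model equation
uses one `ζ`, and a per-stratum version would be weakly identified);
and extra-Poisson variation is exchangeable across observations
(`ε_{ijt} ~ N(0, σ_ε²)`). The regional term is *gated*, not imputed:
years whose 4-year trailing window is incomplete carry `I1 = 0` and
contribute no regional information, which lets the earliest survey
years stay in the likelihood.

Identification of `β2` deserves a note: `b2_{it}` varies only at
stratum-year level, exactly like `γ_{it}`, so the regional slope is
identified purely through the smoothness prior on `γ` — a pulse-shaped
regional signal is attributed to `β2` because the random walk
disfavours tracking it. `β1` is identified much more strongly, by
route-level contrast within stratum-years. Posterior uncertainty for
`B2` is correspondingly wider.

## Priors and defaults

| parameter | prior | default hyperparameter | why |
|---|---|---|---|
| B1, B2 | Normal(0, sd²) | sd = 10 | diffuse on log scale |
| ζ | Normal(0, sd²) | sd = 10 | diffuse |
| each SD (σ_λ, σ_ω, σ_ε, σ_B1, σ_B2) | Uniform(0, U) on the SD | U = 10 | weakly informative, standard for this model family |
| γ_{i,1} | Normal(0, σ_λ²·1000) | inflation = 1000 | effectively flat first year relative to the innovation variance |

Only the uniform-on-SD variance family is implemented; its conditional
is a truncated inverse-gamma, which keeps the variance updates
conjugate.

## Sampler

Metropolis-within-Gibbs. Given everything else, the `ε` are mutually
independent, as are the `ω`, the stratum slopes, and year effects of
equal parity within a chain — so each block is a single vectorised
random-walk Metropolis sweep (year effects in an even pass then an odd
pass, so neighbours in the random walk are never proposed together).
`B1`, `B2` and all variances are Gibbs updates; the variance
conditional InvGamma((n−1)/2, SS/2) is sampled by rejection against
the Uniform(0, U) SD-prior bound, falling back to inverse-CDF
truncation in the rare case the bound binds.

Numerical choices:

- Per-site proposal scales adapt by Robbins–Monro toward a 0.44
  acceptance rate **during burn-in only**; scales freeze afterwards, so
  the post-burn-in kernel satisfies detailed balance.
- Acceptance deltas use `exp(η)·expm1(d)` so each block costs one
  exponential pass over the data.
- Initial year effects start at the log observed cell means (+0.5
  offset for empty cells); other effects start near zero with
  per-chain jitter. SDs start at 0.5.
- All randomness descends from one master seed through named
  SeedSequence streams (one per simulation component, one per chain),
  so runs are bit-reproducible and components are reproducible in
  isolation.
- Convergence is monitored by split-Rhat and bulk ESS on the scalar
  hyperparameters (threshold Rhat ≤ 1.05, surfaced as a warning, never
  a silent pass). `σ_ε` mixes slowest — the usual behaviour of
  observation-level random effects — and is the parameter most likely
  to trip the warning at short run lengths.
- Missing route-years simply contribute no likelihood term; the year
  random walk still spans all years.
- Default storage covers hyperparameters, slopes, year effects and
  observer effects; the per-observation `ε` draws are stored only on
  request, so memory scales with the monitored set.

Defaults are 2 chains × 5 000 iterations with 2 500 burn-in; at the
default study dimensions (below) a fit takes well under a minute on one
CPU.

## Synthetic data

The generator draws from the model's own generative direction, with a
defoliation pulse emulating a decade-scale outbreak: a trapezoid
(linear ramp, plateau, linear ramp; ramp length ≈ a quarter of the
pulse) on the proportion scale. Route-level local series are offset
around the stratum profile on the logit scale (SD 0.75 by default),
which keeps proportions in [0, 1] and gives the within-stratum contrast
that identifies `β1`. Observer turnover is a Bernoulli renewal per
route-year (default probability 0.1 → a handful of observers per route
over 30 years).

Default study dimensions are 6 strata × 20 routes × 30 years with
baseline log abundance `γ_0 ~ N(0.7, 0.3²)` (mean counts of a few
birds per route), local/regional pulse peaks 0.8/0.6, and effect sizes
`B1 = 1.1`, `B2 = 0.5`, `σ_B1 = σ_B2 = 0.2`, `σ_λ = 0.1`,
`σ_ω = 0.3`, `σ_ε = 0.2`, `ζ = −0.2` — magnitudes typical of
route-count analyses of outbreak-associated warblers. Test and
acceptance runs use these dimensions (smaller ones for plumbing
tests), a deliberate desk-scale choice.

What the generator does **not** emulate: real route geometry and the
50-stop structure, detection distance effects, spatial correlation of
defoliation between neighbouring routes beyond the shared stratum
profile, severity classes of defoliation, and temporally correlated
observer quality. Passing recovery tests therefore demonstrate that
the inference machinery is correct and calibrated *under the model*,
not that the model is adequate for any particular field dataset.

## Covariates

- The trailing regional mean at year *t* uses years *t−1 … t−4*
  (exclusive of the current year), matching the dispersal-lag
  rationale: regional recruits arrive after the defoliation that
  produced them.
- The era cutoff defaults to `first regional year + window − 1`, which
  reproduces the historical 1969/1970 switch for a 1966 series and
  generalises to arbitrary synthetic year ranges.
- Years with an incomplete window store `b2 = 0` with `I1 = 0` rather
  than being dropped; the stored zero is never used because the model
  multiplies the term by `I1`.
- The GIS overlay that produces the local proportions is out of scope;
  `b1` arrives precomputed (the buffer radius in the source surveys is
  partly arbitrary, and the overlay is a preprocessing concern).

## Filters

"At least 4 years per route, averaged" is read as: the mean over a
stratum's detected routes of the number of *detection* years (years
with a positive count) must be ≥ 4, boundary inclusive — detection
years rather than surveyed years, consistent with the detection-based
route rule. The occupancy proportion `z_i` is computed on the
pre-filter universe of surveyed routes, because its later role is to
scale route-conditional predicted means up to all routes in the
stratum. Filtering is idempotent and monotone under detection removal
(verified by property tests).

## Trajectories

For each posterior draw, stratum and year:

```
N^b = z_i/r_i · Σ_{j∈o_i} exp(γ_{it} + β1_i b1_{jt} + β2_i I1 b2_{it} + ω_j + 0.5 σ_ε²)
```

where `o_i` is read as "the observer–route combinations occurring in
stratum *i*" and `r_i` is their number. `N^0` drops both defoliation
terms from the same draws; `N^n` applies the formula to the naive
fit's parameters. The `0.5σ_ε²` term is the lognormal mean correction
for the marginalised observation effect; no analogous `ω` correction
is added because the sum runs over the actual `ω_j` draws. Each route
contributes its own year-specific `b1`. `z_i` is a fixed per-stratum
constant (the formula subscripts it by stratum only). Credible bands
are empirical 2.5/97.5 percentiles with linear interpolation between
order statistics — stated explicitly because draw counts are finite.

## Known limitations

- `β2` is prior-identified (see above); with strongly trending data or
  a very smooth defoliation series its posterior can remain wide or
  mildly confounded with the year effects.
- The single-site Metropolis updates mix slowly for `σ_ε` when counts
  are small; run lengths below a few thousand iterations often leave
  Rhat above 1.05 for that parameter.
- No spatial correlation between strata beyond the shared
  hyperdistribution, and no model-comparison machinery (DIC/WAIC) —
  both outside the package's scope.
- The naive-model comparison is a visual/overlap check, not a formal
  test.
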