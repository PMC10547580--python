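# Methods

## Model

The package fits the standard single-season, single-species occupancy
model with imperfect detection. Site *i* (of *N*) carries a latent
occupancy indicator `z_i ~ Bernoulli(psi_i)`. Conditional on occupancy,
the `y_i` detections out of `n_i` active occasions are
`Binomial(n_i, p)`; an unoccupied site yields no detections, so the
observed data follow a zero-inflated binomial with marginal likelihood

```
L_i = psi_i C(n_i, y_i) p^y_i (1-p)^(n_i - y_i) + (1 - psi_i) 1{y_i = 0}
```

Occupancy probability is logit-linear in seven z-scored site covariates
(canopy cover %, livestock count, large-predator detection proportion,
human count, and distances in metres to settlement, road and water), plus
an intercept. Detection probability is a single constant: the package
deliberately fits no detection covariates, and models detection at the
level of the per-site sufficient statistics `(y_i, n_i)`, which is exact
when `p` is constant across sites and occasions. Occasions lost to
inactive cameras enter as `NA` cells and simply reduce `n_i`.

Standardization uses the sample mean and sample SD (`n-1` denominator) of
each predictor; the `(mean, SD)` pairs are retained in a
`StandardizationSpec` so fitted coefficients can be mapped back to
natural units and prediction inputs can be scaled identically. Without
scaling, distance covariates in metres would force slope magnitudes
toward zero and make coefficients incomparable.

## Priors

Defaults are vague: `beta_k ~ Normal(0, 10)` independently and
`p ~ Beta(1, 1)`. Both are configurable; `beta_sd=None` gives an improper
flat prior (used when checking the sampler against maximum likelihood).

A caution that the package's own validation surfaced: at weak designs
(few occasions, moderate sample size), `Normal(0, 10)` on the logit scale
is *not* uninformative. It places most prior mass where `|logit psi|` is
large, i.e. on near-certain occupancy or absence ("bathtub" prior), and
the posterior can then concentrate in a ridge where nearly every site is
treated as occupied with a compensatingly small `p`. This is a property
of the posterior, not of the sampler — an independent marginalized
Metropolis implementation agrees draw-for-draw in distribution. For
inference at designs like 152 sites × 3 occasions we recommend a
weakly-informative scale, `beta_sd` of 1–2.5, which is what the worked
example and the calibration study use.

## Sampler

Metropolis-within-Gibbs on the augmented posterior `(beta, p, z | y)`:

1. **Latent state.** `z_i = 1` with certainty where `y_i > 0`; otherwise
   `z_i ~ Bernoulli( psi_i q_i / (psi_i q_i + 1 - psi_i) )` with
   `q_i = (1-p)^{n_i}` — the exact full conditional.
2. **Detection.** Conjugate update
   `p ~ Beta(a + Σ_{z=1} y_i, b + Σ_{z=1} (n_i - y_i))`.
3. **Coefficients.** For each `beta_k` in turn, a Gaussian random-walk
   proposal accepted against `Π_i Bernoulli(z_i | psi_i)` times the prior.
   The linear predictor is updated incrementally (rank-1), so a sweep
   costs O(N) per component.

Proposal scales start at 0.5 and are multiplicatively adapted every 50
iterations *only during the adaptation phase* (default 1000 iterations,
discarded), targeting ~35% acceptance — within the 20–50% band that is
efficient for one-dimensional random-walk updates — and are frozen
afterwards, so every recorded draw satisfies detailed balance. Defaults
mirror common practice for this model class: 3 chains, 1000 adaptation
iterations, 15,000 recorded iterations, first half discarded as burn-in.

Chains are initialized overdispersed with `beta ~ Normal(0, min(prior SD,
2.5))`, `p ~ Uniform(0.1, 0.9)`, and `z` set to 1 at detected sites and
coin-flipped elsewhere. Starts are deliberately capped at SD 2.5 rather
than drawn from a `Normal(0, 10)` prior: prior draws at that scale start
chains in logit-saturated regions where the data augmentation scheme
mixes extremely slowly, wasting the adaptation phase without improving
the diagnostic value of overdispersion. `init_scale` overrides the cap.

The kernel is vectorized over independent `(dataset, chain)` pairs.
`run_mcmc` fits one dataset; `run_mcmc_batch` fits many identically
shaped datasets in a single pass of array operations, which is how the
20-replicate calibration study runs in under a minute.

Two derived quantities are recorded per iteration: the across-site mean
of `psi_i`, and the finite-sample occupancy `Σ z_i / N`. Both are
reported because a single "occupancy" summary is ambiguous between them;
they differ in small samples. The posterior mean of `z_i` per site is
also accumulated (post burn-in) for latent-state diagnostics.

## Convergence

`gelman_rubin` implements the classic split-chain potential scale
reduction factor: each post-burn-in chain is halved, and
`Rhat = sqrt( ((L-1)/L · W + B/L) / W )` over the 2C half-chains, with
`W` the mean within-sequence variance and `B/L` the variance of sequence
means. The convergence flag requires `Rhat < 1.1` for every model
parameter. A zero-variance (stuck or degenerate) parameter yields `NaN`
with a warning rather than a spurious 1.0. The implementation is
cross-checked against arviz's split-R̂ in the test suite.

## Synthetic data

`SimulationScenario` defaults encode the survey design the package
targets: 152 sites, 3 weekly occasions (a 21-day deployment), detection
probability 0.319 per occasion, and covariates moment-matched to the
field study's reported means/SDs:

| covariate | family | mean ± SD | note |
|---|---|---|---|
| canopy cover % | truncated normal on [0, 100] | 42.19 ± 21.36 | underlying (μ, σ) solved so the *truncated* law has these moments |
| human count | negative binomial | 76.72 ± 244.55 | SD ≫ mean ⇒ heavy-tailed |
| livestock count | negative binomial | 36.74 ± 102.45 | |
| predator proportion | 3-point mixture on {0, ⅔, 1} | 0.37 ± 0.48 | an SD of 0.48 on [0, 1] forces a near-Bernoulli law |
| d_settlement (m) | lognormal | 2182.80 ± 1691.33 | closed-form moment match |
| d_road (m) | lognormal | 741.69 ± 1138.91 | |
| d_water (m) | lognormal | 3354.83 ± 2213.63 | |

The default coefficient vector is the study's fitted effect profile
(intercept at logit 0.15; slopes 1.00, −2.24, 3.01, 1.42, 0.36, 0.06,
0.46 on the standardized scale), so the default scenario produces data
with the qualitative signature of the real survey — a minority of sites
detected, predator presence the dominant positive effect. Coordinates are
uniform over a 60 × 40 km extent. One seeded generator stream drives the
covariate draw and a spawned child stream the detection draw, so the same
covariates can be reused across detection replicates.

What the generator does **not** emulate: camera failure patterns (no NA
process by default, though NA is supported downstream), spatial
autocorrelation in occupancy or covariates, animal movement,
between-occasion detection heterogeneity, and multi-species dynamics
(the predator covariate is drawn directly as a proportion, not simulated
from a second species' detection process). Passing recovery tests
therefore demonstrates correctness of the *estimator* under the model's
own assumptions, not robustness to these real-data features.

## Validation design

Four layers, in increasing scope:

1. **Likelihood.** `site_marginal_loglik` is checked against brute-force
   enumeration over the latent state and all `2^n` occasion outcome
   vectors for every `(y, n ≤ 5)` on a (ψ, p) grid, to 1e-10, and
   `total_loglik` against an occasion-level re-implementation.
2. **Latent state.** On a 3-site intercept-only dataset the MCMC
   posterior `P(z_i = 1)` is compared with dense two-dimensional
   quadrature over `(beta0, p)` (4001 × 2001 grid), agreeing within 0.01
   at 150,000 post-burn-in draws.
3. **Point estimation.** With flat priors and 2000 sites, posterior means
   of `(beta0, p)` match the numerical MLE within 0.05.
4. **Calibration at the survey design.** 20 replicate datasets at 152
   sites × 3 occasions with `p = 0.32`; the true coefficient vector of
   each replicate is drawn from the fitting prior `Normal(0, 1)`. Under a
   correct sampler this design makes posterior means exactly unbiased and
   95% credible intervals exactly nominal on average (the
   Cook–Gelman–Rubin property), so miscalibration is attributable to the
   implementation rather than to finite-sample shrinkage. Checks: pooled
   interval coverage within the binomial band [88%, 100%], posterior-mean
   bias within 3 Monte-Carlo standard errors, every R̂ < 1.1. The
   fixed-truth alternative was examined and rejected as a test oracle:
   at 3 occasions the posterior mean carries genuine finite-sample bias
   along the ψ–p ridge for any fixed truth, so it cannot distinguish a
   sampler bug from honest Bayesian shrinkage.

The replicate count (20) and the single-fit problem sizes were chosen so
the full validation runs in about two minutes on one CPU; the batched
kernel makes larger studies linear in replicates.

## Screening and naive summaries

Collinearity screening computes Pearson r for all 21 unordered predictor
pairs and flags `|r| > 0.7` (strict inequality). Flagging is advisory:
the pipeline proceeds, leaving predictor choice to the analyst. Pearson
(not rank) correlation is used, as is conventional for this rule of
thumb in the occupancy literature.

Naive summaries are model-free: per-site detection proportion `y_i/n_i`
(also the construction used for the large-predator covariate), detection
and occupied-site totals, and trap nights = active occasions ×
days-per-occasion (default 7; the deployment calendar is not inferred
from dates). "Total detections" counts detection-occasions `Σ y_i`, not
independent photographic events.

## IDW surface

The detection surface assigns each pixel centre the weighted mean of the
per-site values with weights `d^-k` (Euclidean distance, projected metric
coordinates). Defaults: 1000 m pixels and `k = 2`, the common GIS
default; both configurable, as is an optional neighbourhood radius
(outside-radius pixels become NA). A pixel within 1e-9 m of a sample
takes its value exactly. Consequences tested as invariants: interpolated
values are convex combinations (never outside the sample range), the
surface is translation-invariant, and as `k` grows each pixel tends to
its nearest sample's value wherever the nearest sample is unambiguous.
No habitat masking is applied; the grid is the bounding box of the sites.
Output formats are plain text: long-form CSV and ESRI ASCII grid.

## Numerical notes and edge cases

- The marginal log-likelihood is computed in log space
  (`logaddexp` for the `y = 0` mixture term); ψ from a saturated linear
  predictor is clipped away from exact 0/1 before logs.
- `standardize` refuses zero-variance covariates; `correlation_screen`
  refuses them too (r undefined).
- The MLE uses BFGS on `(beta, logit p)`; `|logit p| > 8` is flagged as a
  boundary solution (e.g. every site detected on every occasion drives
  `p → 1`).
- With `n_i = 1` everywhere, ψ and p are only identified through their
  product; the likelihood is flat along `(psi·c, p/c)` and the model
  should not be fit to single-occasion data (tested as an invariant, not
  guarded at runtime).
- Reproducibility: every stochastic entry point takes a seed; the
  pipeline derives simulation and MCMC streams from one master seed and
  stamps every output file with the config hash and seed.

## Known limitations

- Constant `p`: no detection covariates, trap-specific effects or
  temporal variation.
- Single season, single species; no spatial random effects; no model
  selection machinery.
- Component-wise random-walk updates mix slowly for strongly correlated
  coefficients; for badly conditioned designs consider longer chains or
  thinning.
- The IDW map interpolates *naive* detection proportions (the per-site
  value column is user-overridable), and inherits IDW's usual artifacts
  (bullseyes around isolated sites).
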