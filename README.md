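# occubear

Bayesian single-season occupancy analysis for camera-trap surveys of a
focal species — built around the design of a sloth bear (*Melursus
ursinus*) survey in Nepal's Parsa–Koshi Complex: 152 camera sites, a
21-day deployment collapsed into 3 weekly sampling occasions, and seven
site covariates (canopy cover, livestock and human detections,
large-predator detection proportion, and distances to settlement, road and
water).

It is aimed at wildlife ecologists who have a site × occasion binary
detection matrix and a site covariate table, and want the full analysis
chain with no external MCMC engine: collinearity screening, a
data-augmentation Gibbs/Metropolis sampler for the occupancy model,
convergence diagnostics, naive detection summaries, and an
inverse-distance-weighted (IDW) detection-probability surface. A
synthetic-data module reproduces the survey's statistical structure so the
whole pipeline runs, and can be validated, without any field data.

## The model

Each site *i* has a latent occupancy state and detections over *n<sub>i</sub>*
active occasions:

```
z_i ~ Bernoulli(ψ_i)
y_i | z_i ~ Binomial(n_i, p · z_i)
logit(ψ_i) = β0 + β_cc cc_i + β_livestock livestock_i + β_predators predators_i
           + β_human human_i + β_settlement settlement_i + β_road road_i
           + β_water water_i
```

with covariates z-scored before entering the linear predictor and a single
per-occasion detection probability *p*. Fitting marginalizes nothing away:
the sampler alternates (1) an exact Gibbs draw of *z* from its full
conditional, (2) a conjugate Beta draw of *p*, and (3) component-wise
random-walk Metropolis updates of β, with proposal scales adapted only
during a frozen-afterwards adaptation phase (defaults: 3 chains, 1000
adaptation iterations, 15,000 recorded iterations). Convergence is judged
by the split-chain potential scale reduction factor (R̂ < 1.1). An
independent numerical maximum-likelihood fit of the marginal
(zero-inflated binomial) likelihood is included as a cross-check.

## Worked example

```python
import occubear as ob

scenario = ob.SimulationScenario(seed=1)          # 152 sites, 3 occasions
ds = ob.simulate_dataset(scenario)
print(ob.dataset_summary(ds.detection_history))

std, _ = ob.standardize(ds.covariates)
chains = ob.run_mcmc(ds.detection_history, std,
                     ob.MCMCConfig(seed=2), ob.Priors(beta_sd=2.5))
print(ob.summarize_posterior(chains))
```

prints

```
65 detections across 46 of 152 sites (naive occupancy 0.303); 456 trap-occasions = 3192 trap nights at 7 days/occasion
                     mean      sd    q2.5   q97.5    rhat
parameter
beta0             -0.4012  1.0035 -2.1577  1.7476  1.0097
beta_cc            0.7428  0.7729 -0.7796  2.2880  1.0008
beta_livestock    -1.6310  1.4430 -4.4963  0.9030  1.0021
beta_predators     5.2774  1.2952  3.1152  8.2390  1.0024
beta_human         1.0687  1.1128 -0.6040  3.6944  1.0031
beta_d_settlement  0.7287  0.8222 -0.7155  2.4883  1.0024
beta_d_road       -0.0910  0.8694 -1.6983  1.9140  1.0022
beta_d_water       0.6009  0.8518 -0.9540  2.4355  1.0032
p                  0.3281  0.0373  0.2599  0.4053  1.0012
psi_mean           0.4386  0.0258  0.3786  0.4849  1.0074
occ_fss            0.4381  0.0223  0.3816  0.4803  1.0060
all Rhat < 1.1: converged
```

The survey effort line reproduces the study's bookkeeping (152 sites × 3
weekly occasions × 7 days = 3192 trap nights). The effect table is the
posterior over the standardized-scale coefficients: here the simulated
truth put a strong positive effect of large-predator presence on
occupancy, which the fit recovers (`beta_predators` interval well above
zero), while `p` is estimated near the generating per-occasion detection
probability of 0.319. Two derived occupancy summaries are reported:
`psi_mean` (posterior of the across-site mean of ψ<sub>i</sub>) and
`occ_fss` (posterior of the realized fraction of occupied sites, Σz/N) —
both exceed the naive occupancy of 0.303, as imperfect detection requires.

## Command line

```bash
occu-bear simulate --seed 1 --out data/          # detection, covariate, truth CSVs
occu-bear screen   --covariates data/covariates.csv
occu-bear fit      --detections data/detections.csv --covariates data/covariates.csv \
                   --chains 3 --adapt 1000 --iters 15000 --seed 7 --out fit/
occu-bear summarize --detections data/detections.csv
occu-bear map      --values sites.csv --pixel 1000 --power 2 --out surface.asc
occu-bear run      --config pipeline.yaml        # the whole chain, one seed
```

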