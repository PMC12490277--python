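# spatialfactor

Bayesian dynamic spatial factor models for multiple correlated areal
count outcomes — the kind of joint surveillance data that arises when
several interrelated epidemics (an opioid syndemic: overdose deaths,
emergency-department visits, treatment counts, buprenorphine
prescriptions, new HCV and HIV diagnoses) are tracked as yearly
county-level counts.

The package is for spatial epidemiologists and biostatisticians who want
to (a) quantify how much shared structure a single latent spatio-temporal
factor explains across outcomes, and (b) ask whether the strength of each
outcome's link to that factor — its *loading* — varies over the map or is
constant across it.

## The model

For region i = 1..N, year j = 1..J, outcome k = 1..K:

```
Y_ij^(k) ~ Poisson(E_ij^(k) λ_ij^(k))
log λ_ij^(k) = γ_i^(k) f_ij + ε_ij^(k),    ε_ij^(k) ~ N(0, σ_k²)
```

with expected counts `E_ij^(k) = P_ij r^(k)` (population × baseline-year
statewide rate), so `λ` is a relative risk against the baseline year.
The latent factor `f` is intrinsic CAR (ICAR) in space with an AR(1)
structure in time around yearly intercepts μ_j; the loadings are either
spatially constant scalars `γ^(k) ~ N(1, τ_γ²)` or mean-one ICAR fields.
The reference outcome's loading is fixed at 1 for identifiability.
Interval-censored counts (small-cell suppression, e.g. counts in [1, 5])
enter through an exact interval likelihood.

The package also implements the closed-form marginal covariance of the
stacked outcome vector for the Gaussian layer: with spatially varying
loadings the (k₁,k₂) block has entries
`[δ_{k₁k₂} Σ^Γ(k₁)_ij + μ_i^(k₁) μ_j^(k₂)] Σ^F_ij + δ_{k₁k₂} δ_ij σ²_{k₁}`,
so outcome covariance is shaped by *both* the loading and factor spatial
covariances; with constant loadings it collapses to multiples of Σ^F.
A Monte-Carlo oracle verifies the algebra.

Inference is Metropolis-within-Gibbs (adaptive random-walk updates for
the latent log-rates and the AR coefficient, exact Gaussian and
inverse-gamma conditionals elsewhere), with classic Gelman-Rubin
diagnostics.  A synthetic-data generator reproduces the full generative
model on lattice graphs so the whole pipeline is testable and
calibratable without surveillance data.  See `docs/methods.md` for
modeling details and design choices.

## Worked example

```python
import numpy as np
import spatialfactor as sf

# synthetic surveillance panel: 30 regions, 5 years, 3 outcomes,
# reference outcome censored on [1, 5]
cfg = sf.default_config(seed=11)
ds = sf.simulate_dataset(cfg)

model = sf.DynamicSpatialFactorModel(
    ds.observations, cfg.graph, loadings_mode="varying"
)
res = model.fit(n_iterations=20_000, n_burnin=10_000, thin=5,
                n_chains=2, seed=7)

print(res.summary(parameters=("sigma2", "tau_f2", "eta")).frame
      [["parameter", "formatted"]].to_string(index=False))
scaled, defined = res.scaled_loadings()
print("scaled loadings, region 0:", np.round(scaled[0], 3))
ratio, above = res.variance_explained()
print("share of regions factor-dominated:", above[:, 1:].mean().round(2))
print("max PSRF (eta):", float(res.gelman_rubin("eta")).__round__(3))
```

Output from this exact script:

```
        parameter           formatted
sigma2[outcome_0] 0.066 (0.045,0.092)
sigma2[outcome_1] 0.091 (0.057,0.135)
sigma2[outcome_2] 0.069 (0.046,0.099)
           tau_f2 0.370 (0.246,0.524)
              eta 0.563 (0.331,0.783)
scaled loadings, region 0: [0.336 0.342 0.322]
share of regions factor-dominated: 0.37
max PSRF (eta): 1.0
```

Reading it: the error-variance intervals sit near the generating value
0.05; the factor's spatial variance τ_f² and the AR coefficient η cover
their true values (0.5 and 0.5).  Scaled loadings near the
equal-contribution baseline 1/3 say region 0's three outcomes track the
latent factor about equally; the variance-explained flag classifies 37%
of the non-reference region-outcome pairs as factor-dominated (ratio ≥
0.50) at these settings; a PSRF of 1.0 indicates the two chains mixed.

The same pipeline is scriptable from a shell:

```
spatialfactor simulate --out sim/ --seed 3
spatialfactor fit --data sim/observations.csv --adjacency sim/adjacency.gal \
    --out fit/ --iterations 20000 --burnin 10000 --chains 2 --mode varying
spatialfactor summarize --chains fit/chains --data sim/observations.csv \
    --adjacency sim/adjacency.gal --out summary/
spatialfactor diagnose --chains fit/chains
```

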