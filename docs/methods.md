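# Methods

## Model

`spatialfactor` fits a Bayesian hierarchical dynamic spatial one-factor
model to K correlated count outcomes observed on N areal units over J
years.  For region i, year j, outcome k:

    Y_ij^(k) ~ Poisson(E_ij^(k) λ_ij^(k)),
    log λ_ij^(k) = γ_i^(k) f_ij + ε_ij^(k),     ε_ij^(k) ~ N(0, σ_k²).

The expected count E_ij^(k) = P_ij r^(k) combines the region-year
population with the baseline-year statewide rate of outcome k, so
exp(log λ) is a relative risk against the baseline year: log λ = 0 means
the region tracks the baseline-year statewide rate exactly.

**Latent factor.**  The factor field is intrinsic CAR (ICAR) in space and
AR(1) in time.  Year 1 has conditional mean μ₁ plus the average neighbor
deviation and conditional variance τ_f²/w_i+; year j ≥ 2 replaces μ_j by
μ̃_ij = μ_j + η(f_i,j−1 − μ_{j−1}).  The joint over years is the product
of these year-wise ICAR densities — a valid directed-in-time
construction.

**Loadings.**  The reference outcome's loading is fixed at 1 everywhere
(the identifiability constraint that pins the scale and sign of the
factor).  In the *spatially varying* variant, each other outcome's
loading field is a mean-one ICAR with a single shared variance τ_γ²; in
the *spatially constant* variant it is a scalar γ^(k) ~ N(1, τ_γ²).
τ_γ² is a single parameter shared across the non-reference outcomes,
matching the single shared symbol in the model statement; a per-outcome
loading variance is a straightforward extension but is deliberately not
implemented, to keep the variance bookkeeping identical between the two
loading modes.

**Censoring.**  Small-cell suppression is modeled by an interval
likelihood: a censored cell contributes log Σ_{y=a}^{b} Poisson(y; m),
computed by log-sum-exp.  We read the suppression interval as inclusive
on both ends ([1, 5] by default, the standard small-cell suppression
band); an open right end would simply shift the bound by one.  The
observation model is pure Poisson with interval censoring — no
generalized-Poisson dispersion parameter is retained, since nothing in
the hierarchical model statement introduces one (the ε layer already
absorbs extra-Poisson variation on the log scale).

**Priors.**  Inverse-gamma(0.5, 0.5) on σ_k², τ_f², τ_γ² (equivalently
Gamma(0.5, rate 0.5) on the precisions); flat priors on the yearly
intercepts μ_j; Uniform(−1, 1) on η.  The η prior is this package's
choice (the model statement leaves it open): it keeps the AR(1) trend in
the stationary range and is flat over it.  A sensitivity toggle switches
every variance prior to precision ~ Gamma(5, rate 2), i.e. variance ~
Inverse-Gamma(5, 2); the "Gamma(5, 2)" is read on the rate
parameterization.

## ICAR handling

The ICAR joint is improper.  We represent it in unnormalized
pairwise-difference form

    −((N − c)/2)·log τ² − (1/2τ²) Σ_{i<l} w_il (d_i − d_l)²,

with d the deviations from the stated prior mean and c the number of
connected components — the standard rank correction, and the canonical
joint consistent with the stated full conditionals.  Isolated regions
are a hard error (the conditional divides by w_i+); disconnected graphs
are accepted with a warning and the rank correction uses c.

Two flat directions need care:

* **Factor level vs μ_j.**  Because Q1 = 0, the yearly intercepts carry
  no density information: μ_j is pure gauge.  After each factor update
  the sampler runs a forward-in-time recentring sweep that absorbs each
  year's mean deviation into μ_j.  This moves the state along an exact
  flat direction of the posterior (the density is unchanged), so it
  leaves the distribution of every identified quantity untouched while
  making μ_j the identified level of the factor field.  This is why the
  spec-level "flat-prior Gaussian update for μ_j" appears as a
  deterministic recentring: the Gaussian conditional is degenerate.
* **Loading level.**  "Mean one" carries no density weight in the
  improper pairwise-difference form (again Q1 = 0), so the anchor is
  made explicit: each varying-loadings Gibbs draw is conditioned exactly
  on the column-mean-one constraint (standard Gaussian conditioning of
  the full-conditional draw on 1'γ = N).  This is the proper
  representative of the mean-one ICAR and matches the generative model,
  which is what credible-interval calibration presumes.  Setting
  ``constrain_loading_level=False`` recovers the unanchored variant, in
  which the loading level is identified by the likelihood alone; the
  dual-route sampler validation uses that variant.

For simulation and for the closed-form covariance theory, the proper
sum-to-zero representative N(0, τ² Q⁺) is used (Q⁺ the Moore-Penrose
pseudo-inverse), with deviations drawn in the eigenbasis of Q.  Under
this representative the full conditionals differ from the improper-ICAR
conditionals by a rank-one term that vanishes with N; consistency is
therefore checked on pairwise *contrasts* (d_i − d_l), which are
invariant to the representative: Gibbs sweeps of the stated
conditionals with one coordinate pinned reproduce the contrast
covariances of τ²Q⁺ (tests in `test_graph.py`).

## Sampler

Metropolis-within-Gibbs, one sweep =

1. every log-rate cell by adaptive random-walk MH against the Poisson /
   censored term plus its Gaussian ε layer (per-cell scales adapt toward
   0.44 acceptance during burn-in, frozen afterwards);
2. the factor field year by year from its exact Gaussian full
   conditional (the ε layer and the ICAR/AR structure are jointly
   Gaussian given log-rates and loadings), then the μ recentring sweep;
3. loading columns from Gaussian full conditionals (scalars in the
   constant variant);
4. σ_k², τ_f², τ_γ² from conjugate inverse-gamma conditionals with the
   (N − c) rank correction per ICAR field;
5. η by random-walk MH restricted to its prior support (its conditional
   is a truncated Gaussian; the MH step keeps the update prior-agnostic).

Initialization: log-rates at log((count + ½)/E) (censored cells at the
interval midpoint), factor and intercepts at 0, loadings at 1, variances
at 1, η at 0.  Censored cells use the interval likelihood directly, not
data augmentation — fewer latent states, identical posterior.  Fixed
seeds give bit-identical chains; multi-chain runs spawn per-chain seeds
from one root seed.

**Validation strategy.**  Three independent routes:

* *Dual-route check*: the conjugate/Gibbs sampler is compared against a
  plain site-wise random-walk MH sampler targeting the independently
  coded joint log-posterior (which is itself tested against a
  from-scratch component-sum oracle).  Posterior means agree within
  Monte-Carlo error on a strongly identified 3-region model.
* *Prior recovery*: with the Poisson term disabled, marginal chain
  quantiles of every variance group reproduce their inverse-gamma prior
  and η reproduces its uniform prior.  This check runs under the
  lighter-tailed IG(5, 2) prior: the conditional-update code path is
  identical, and under IG(0.5, 0.5) (infinite mean, very heavy tail)
  the prior-only chain mixes too slowly through the small-τ region for
  quantile comparison at desk-scale run lengths.  This replaces a full
  Geweke marginal-conditional test, which is not defined here because
  the flat μ and improper ICAR priors cannot be simulated from.
* *Simulation-based calibration*: 90% credible intervals for the
  non-reference loadings cover the generating truth at the nominal rate
  over 20 matched-prior replicates.  Coverage indicators are strongly
  correlated within a replicate, so the calibration band is a t-interval
  over replicate-level coverage means, not a raw binomial interval over
  cells.  Coverage measured this way runs slightly conservative (a few
  percentage points above nominal): the replicates fix the generator's
  hyperparameters at the study conditions while inference places the
  model's diffuse priors on them, and the flat intercepts and improper
  ICAR cannot be drawn from, so exact simulation-based calibration is
  unattainable for this model class.  The deviation is in the safe
  direction (intervals mildly too wide, never too narrow).

Convergence in applied runs is monitored with the classic (unsplit)
Gelman-Rubin PSRF per scalar component, cross-checked against arviz's
split-R̂ in the tests; runs are declared converged below 1.1.

## Covariance theory

For the Gaussian linear layer Y_i^(k) = γ_i^(k) f_i + ε_i^(k) with
F ~ N(0, Σ^F), independent loadings γ^(k) ~ N(μ^(k), Σ^Γ(k)) and
independent errors, the marginal covariance of the stacked outcome
vector has block form with (k₁, k₂) block entry

    [δ_{k₁k₂} Σ^Γ(k₁)_ij + μ_i^(k₁) μ_j^(k₂)] Σ^F_ij + δ_{k₁k₂} δ_ij σ_{k₁}².

The spatially constant case replaces Σ^Γ(k) by τ_γ(k)² and μ^(k) by a
scalar.  The derivation is for K = 3 but the pattern is fully
determined pairwise, so the implementation generalizes to any K with
outcome 1 as reference.  Σ^Γ(k) may be any PSD matrix; ICAR-derived
inputs use the rank-corrected pseudo-inverse.  The printed cross-block
between the reference and outcome k is resolved by symmetry as
μ_j^(k) Σ^F_ij above the diagonal and its transpose below.  A
chunked Monte-Carlo oracle (draw F, loadings, errors; form Y; empirical
cross-covariance with entrywise standard errors) verifies the algebra;
PSD validation uses an eigenvalue floor of −1e−8 times the largest
eigenvalue.  This theory covers the Gaussian layer only — the marginal
moments of the Poisson-scale outcomes are deliberately out of scope.

## Synthetic-data generator

The generator emulates a state-level surveillance panel at desk scale.
Defaults (chosen once as the package's study conditions):

| quantity | default | rationale |
| --- | --- | --- |
| graph | 5×6 queen lattice (N = 30) | desk-scale stand-in for a ~100-county point-touch adjacency |
| J, K | 5 years, 3 outcomes | mirrors a 2017–2021 six-outcome panel at reduced width |
| μ_j | linspace(0, 0.4) | gentle upward factor trend, as in the applied analyses |
| η | 0.5 (fixtures sweep 0, 0.5, 0.9) | moderate year-to-year persistence |
| τ_f², τ_γ², σ_k² | 0.5, 0.25, 0.05 | visible spatial structure; log-scale noise sd ≈ 0.22 |
| populations | lognormal, median 5·10⁴, sd 0.6 | county-like population spread |
| baseline rates | 2·10⁻³, 2·10⁻⁴, 5·10⁻⁴ | treatment-like reference outcome, death-like and ED-like others |
| censoring | reference outcome, counts in [1, 5] | small-cell suppression of the treatment-type outcome |

What the generator does *not* emulate: real county geography and
population sizes, secular changes in baseline rates, reporting artifacts,
outcome-specific overdispersion beyond the lognormal ε layer, or
loadings that drift over time.  Passing calibration tests therefore
demonstrates internal consistency of model + sampler under the model's
own assumptions, not robustness to real-data misspecification.

## Postprocessing choices

* **Scaled loadings** (per-region loading divided by the sum of the K
  loadings there; 1/K is the equal-contribution baseline) are computed
  per posterior draw and then averaged, which propagates uncertainty
  through the nonlinear ratio; a plug-in `posterior_mean` option
  reproduces the simpler workflow.  Regions whose loading sum falls
  below 1e−6 in magnitude are flagged undefined rather than dropped.
* **Variance explained** is Var_j(γ̂_i^(k) f̂_ij) / (Var_j + σ̂_k²) with
  posterior means plugged in and the empirical variance taken over the J
  time points; "total variance" is resolved as signal-plus-noise on the
  log-rate scale.  Draw-wise ratios and space-time variances are noted
  alternatives, not implemented.  The 0.50 threshold classifies regions
  as factor-dominated or noise-dominated.
* **Log relative risk** is the posterior mean (and central 95% interval)
  of log λ per cell.

## Problem sizes in the automated checks

The test suite and `scripts/acceptance.py` use the desk-scale defaults:
calibration over 20 replicates × 20 000 iterations in the suite (10 ×
12 000 in the acceptance script), 10⁶ draws for the covariance oracle,
and 8–10 k iterations for paired model comparisons.  These sizes were
chosen so the full pipeline re-runs from scratch in minutes on one CPU
while leaving Monte-Carlo error well below the effect sizes being
checked; production analyses should use the documented defaults
(10⁶ iterations, half burn-in, thinning 50, ≥ 2 chains).

## Known limitations

* Single factor only; no multi-factor or time-varying-loadings variants.
* No covariates, zero-inflation, or overdispersion parameters.
* The improper ICAR plus flat intercepts make μ_j meaningful only
  relative to the recentring convention; compare factor *contrasts*
  across models, not raw levels.
* Heavy-tailed IG(0.5, 0.5) priors make posterior *means* of weakly
  identified variance components unstable summaries; the reported
  credible intervals and medians are the robust quantities.
* Choropleth rendering is out of scope; exports are CSV keyed by
  region/outcome/year for mapping in external GIS tools.
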