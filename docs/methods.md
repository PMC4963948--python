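# Methods

`stuntcast` implements model-based geostatistics (MBG) for under-five
stunting: cluster-survey binomial counts are smoothed over space and years by
a latent Gaussian field, linked to gridded environmental covariates, and used
to predict and *forecast* prevalence on a 1×1 km raster with full posterior
uncertainty. This note records the model, its assumptions, the defaults and
why, and what the synthetic experiments do and do not demonstrate.

## Model

For cluster *i* at location *s_i* in year *t(i)*:

```
n_stunted_i ~ Binomial(n_examined_i, p_i)
logit(p_i)  = x_i'β + S_{t(i)}(s_i) + ε_i ,    ε_i ~ N(0, σ_ε²)
```

* **Fixed effects** `β`: intercept plus the screened environmental
  covariates, on their native scales (so `exp(β_j)` is an odds ratio per
  native unit — per mm of precipitation, per unit EVI).
* **Latent field** `S_t`: a Matérn (ν = 1) Gaussian field with marginal
  standard deviation σ_s and range ρ (κ = √8/ρ), evolving across years as a
  stationary AR(1): `S_t = φ S_{t−1} + ω_t`, with innovation variance
  σ_s²(1 − φ²) so the marginal variance is σ_s² every year (the
  "marginal-variance" convention).
* **Nugget** `ε_i`: cluster-level extra-binomial noise (survey design
  effects, local heterogeneity). It is part of the likelihood but excluded
  from pixel prediction, which targets the latent prevalence surface.

The field is represented by the SPDE (α = 2) finite-element construction on
a Delaunay mesh: with lumped mass matrix `C` and stiffness matrix `G`,

```
Q_s = τ² (κ⁴ C + 2κ² G + G C⁻¹ G),      σ_s² = 1 / (4π κ² τ²)
```

is the sparse spatial precision of the node weights, and the space-time
precision is the Kronecker product `Q_time(φ) ⊗ Q_s` with `Q_time` the
unit-marginal AR(1) precision. Cluster and pixel values are barycentric
interpolations of node weights (each projector row is non-negative and sums
to one, so linear functions are reproduced exactly).

## Covariate screening

A deliberately non-spatial pre-selection step: every subset of the five
candidate covariates (precipitation, EVI, temperature, distance to water,
urbanisation) is fitted as a binomial logit GLM on cluster counts and ranked
by BIC with `n` = number of clusters. Spatial correlation is ignored here by
design; consequently, with strong residual spatial structure the BIC can
admit weakly informative covariates. The audit table of all 2^m subsets and
per-coefficient Wald intervals are returned so the selection is reviewable.
The geostatistical model, not the screen, is the inferential product.

## Inference

**Laplace engine (default).** The latent vector (node weights per year, β,
nugget values) is jointly Gaussian given the hyperparameters
θ = (κ, τ, φ, σ_ε). For each θ, a damped Newton iteration finds the mode of
the latent posterior; the nugget block of the Hessian is diagonal and is
eliminated analytically (Schur complement), so the dense factorisation only
involves mesh nodes × years + fixed effects (a few hundred dimensions). The
Laplace-approximated marginal posterior of θ (transformed to log κ, log τ,
atanh φ, log σ_ε) is maximised by Nelder–Mead. Finally the posterior is
represented as an importance-weighted mixture of conditional Gaussians at
~16 hyperparameter draws from the curvature at the mode
(`ModelConfig.hyper_mix_draws`; 0 gives pure empirical Bayes). The mixing
step exists because pure empirical Bayes understates fixed-effect
uncertainty — most visibly for the intercept, which is confounded with the
field's overall level; the mixture restores near-nominal interval coverage
at negligible cost. Joint samples (default J = 1,000) of (β, all node
weights, all years) are drawn from the mixture; all downstream uncertainty
(pixel sds, exceedance probabilities, excursion sets) is computed from these
samples.

**MCMC engine.** The identical posterior — jointly over latent variables and
hyperparameters — is sampled with an affine-invariant ensemble sampler
(emcee), initialised near the Laplace solution. It is practical only for
small instances (tens of clusters, a handful of mesh nodes) and serves as
the reference implementation in the test suite: on such instances the two
engines' fixed-effect posterior means agree within 0.1 logit units.

**Priors** (all overridable in `ModelConfig`):

| parameter | prior | default rationale |
|---|---|---|
| β | N(0, 10²) | weakly informative on the logit scale |
| log ρ | Normal, median = domain diagonal / 5, sd 1 | median-based range rule |
| log σ_s | Normal, median 1, sd 1 | order-unity logit-scale variation |
| atanh φ | Normal(2.0, 1.3) | persistence-favouring (below) |
| log σ_ε | Normal, median 0.25, sd 1 | modest overdispersion |

The φ prior deserves a note. Chronic malnutrition surfaces change slowly
between years, and in the forecast design the earliest fit uses a *single*
survey year, where φ has no likelihood information at all: whatever the
prior says is what the forecast uses. A prior symmetric around zero would
make that forecast silently drop the latent field. The default therefore
favours persistence (prior median φ ≈ 0.96, in the spirit of the
penalised-complexity prior with base model φ = 1 and of R-INLA's default
AR(1) prior); `phi_prior="uniform"` restores a flat prior on (−1, 1). With
two or more fitted years and realistic survey sizes the likelihood dominates
either choice.

## Forecasting (model 1) vs full-data prediction (model 2)

* **Model 2** fits all survey years jointly and predicts each year from its
  own posterior field — the gold standard.
* **Model 1** fits only the years before the target year and carries the
  model forward: per joint posterior sample, the last fitted year's field is
  propagated by the AR(1) (`S_{t+1} = φ S_t + ω`) with a fresh spatially
  correlated innovation, and the target year's covariates enter the fixed
  effects. `mode="fixed_only"` instead zeroes the field — the literal
  "coefficients applied to covariates" reading — and is retained as an
  explicit alternative.

Regional prevalence is the population-weighted aggregate of the posterior
mean pixel surface (per-sample aggregation is available as an option but the
mean-surface wording is the default). WHO classes use left-closed bins:
low < 20 % ≤ medium < 30 % ≤ high < 40 % ≤ very high.

## Exceedance and excursion sets

Marginal exceedance `P(p(s) > u)` is the fraction of joint samples above the
threshold (default u = 0.40, the WHO "very high" boundary). The positive
excursion set E⁺(u, α) is built by the one-parameter parametric-family
sweep: pixels ordered by decreasing marginal probability (row-major ties),
grown as a prefix while the *joint* probability — the fraction of joint
samples in which every member exceeds u — stays ≥ 1 − α (default α = 0.05).
Using samples instead of Gaussian numerical integration makes the joint
probability exact up to Monte-Carlo error for any posterior representation,
including the hyperparameter mixture; it requires J ≥ 500 samples and is
validated against exhaustive subset search on small instances.

## Validation

The holdout is declustered over space and time: strata are survey year × a
4×4 block grid, and `round(0.10 × stratum size)` clusters are drawn from
each stratum. Model 2 metrics come from refitting on the 90 % training set
(the statistically honest reading of holdout validation); model 1 is scored
on the holdout share of the forecast year it never saw. Metrics: RMSE, MPE
(= mean(observed − predicted); positive means under-prediction), MAPE (mean
absolute error on the prevalence scale), and Pearson correlation. Observed
cluster prevalence is the raw fraction stunted/examined.

## Synthetic study conditions

The generator emulates the structure of the 2007–2010 Somalia FSNAU/UNICEF
survey series: four annual waves, 250 clusters/year, 30–150 children per
cluster (~90 k children), pooled prevalence ≈ 30 %, five spatially
autocorrelated covariate layers with precipitation and EVI truly active
(OR 0.994 per mm and 0.719 per EVI unit), the rest null. The domain is a
48×48 km planar raster with 18 Voronoi regions in three zones; the latent
field is simulated *exactly* by dense Cholesky of the Matérn covariance
(which caps the grid at ~4,000 pixels and sets the domain size). Truth
defaults: σ_s = 0.30, ρ = 15 km, σ_ε = 0.15, φ = 0.99. The intercept
(1.05) follows from the generative identity
`logit(0.30) = β₀ + β_precip·E[precip] + β_EVI·E[EVI]`. The persistence
φ = 0.99 encodes a near-static chronic-stunting surface; it is calibrated to
the documented level of agreement between the forecast and full-data designs
(regional differences below ~3 percentage points), which is the only
empirical anchor available for the field's year-to-year dynamics.

**What the synthetic tests show** — and do not. They show that the estimation
machinery is correct and calibrated *when the model is true*: coefficient
intervals attain near-nominal coverage, the SPDE precision reproduces the
Matérn covariance, the Laplace posterior matches MCMC, and the
forecast/full-data agreement emerges from persistence rather than being
hard-coded. They do not establish robustness to model misspecification
(non-Matérn fields, covariate measurement error, informative cluster
placement, survey nonresponse), and a 48 km domain with 11 km regions
aggregates far less than Somalia's ~200 km regions — regional maxima of
model differences are therefore noisier here than in the original setting.

## Numerical choices and problem sizes

* Mesh: thinned cluster locations plus a lattice at `max_edge` = 8 km,
  buffered 10 km beyond the raster (≈ 110 nodes on the default domain);
  coarse relative to ρ = 15 km but sufficient for regional aggregates, and
  chosen so a full fit takes ~3 s, keeping the replicate studies (100-seed
  coverage, 20-seed agreement) practical on a single CPU.
* Inner Newton: convergence at gradient norm < 1e−6 (scaled), step-halving
  line search, warm-started across hyperparameter evaluations.
* Outer Nelder–Mead: ≤ 150 evaluations, xatol 1e−2.
* Positive-definiteness is enforced by Cholesky everywhere; the exact
  simulator adds jitter (starting at 1e−8 σ_s²) only if factorisation fails.
* Degenerate inputs: zero-area triangles, rank-deficient GLM designs,
  clusters outside the raster/mesh, forecast years not after the fitted
  period, and surfaces without samples all raise typed errors naming the
  offending object.
* Reported percentages are rounded half-up to 2 decimals.

## Known limitations

* Planar km coordinates; no geodesy or reprojection.
* Separable space-time covariance; no seasonal (Gu/Deyr) term — season is
  carried as metadata only.
* Empirical-Bayes-plus-mixture hyperparameter treatment rather than full
  numerical integration; the MCMC engine bounds what this loses on small
  instances.
* The MCMC engine does not scale to realistic instance sizes; it is a
  verification tool.
* Forecasting propagates the latent field under the fitted AR(1); structural
  breaks (conflict shocks, displacement) are outside the model.
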