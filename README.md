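# stuntcast

Bayesian space-time geostatistical mapping and **forecasting** of under-five
stunting prevalence from cluster surveys and environmental covariates.

Nutrition surveys measure stunting (height-for-age z < −2) in a few hundred
clusters per year, but planners need prevalence everywhere, now and next
year. `stuntcast` addresses this with model-based geostatistics: cluster
counts `n_stunted_i ~ Binomial(n_examined_i, p_i)` are linked to gridded
covariates and a latent Matérn Gaussian field with AR(1) year-to-year
dynamics,

```
logit(p_i) = x_i'β + S_{t(i)}(s_i) + ε_i ,   S_t = φ S_{t−1} + ω_t ,
```

fitted via the SPDE/GMRF sparse-precision representation with a fast Laplace
engine (an MCMC engine on the same posterior serves as a verification
oracle). Two designs mirror an operational forecasting study of stunting in
Somalia 2007–2010: **model 1** fits the years before a target year and
carries the field forward through the AR(1); **model 2** fits all years
jointly (the gold standard). The package also provides BIC covariate
screening, WHO prevalence classification (low < 20 % ≤ medium < 30 % ≤ high
< 40 % ≤ very high), population-weighted regional aggregation, exceedance
probabilities and joint excursion sets at the 40 % threshold, and
declustered holdout validation (RMSE/MPE/MAPE/correlation). A synthetic-data
module generates a full test country — rasters, regions, population,
covariates, latent truth, surveys — so the whole pipeline runs with no
external data.

The published regional summary of the underlying survey series (1,066
clusters, 73,778 children) ships with the package
(`stuntcast.datasets.load_somalia_summary`); the cluster-level microdata are
not public, so analyses here run on synthetic surveys with known truth.

## Worked example

```python
from stuntcast import synthetic, pipeline, odds_ratios
from stuntcast.spacetime import ModelConfig

bundle = synthetic.default_bundle(seed=11)          # 4 years x 250 clusters
cfg = pipeline.RunConfig(seed=11, model=ModelConfig(n_samples=600))

res2 = pipeline.run_model2(bundle, cfg)             # full-data design
res1 = pipeline.run_model1(bundle, cfg)             # forecast design
print(odds_ratios(res2["fit"]))
table, max_diff = pipeline.compare_model_runs(res1, res2)
print(f"max |model1 - model2| regional difference: {max_diff:.2f} pp")
```

prints (seed 11; generative truth OR_precip = 0.994, OR_EVI = 0.719, other
covariates null):

```
           covariate        OR  CrI_2.5%  CrI_97.5%  significant
0      precipitation  0.993734  0.993092   0.994325         True
1                EVI  0.516516  0.379690   0.719616         True
2        temperature  1.018779  0.990815   1.047672        False
3  distance_to_water  0.996173  0.980270   1.011894        False
4              urban  1.003142  0.901412   1.127657        False
max |model1 - model2| regional difference: 3.39 pp
```

Reading: the non-spatial BIC screen admitted all five candidates on this
realisation (it ignores spatial correlation by design), but the spatial
model sorts them out — the three null covariates are flagged
non-significant, the precipitation odds ratio per mm is recovered to the
third decimal, and the weak EVI effect (one covariate unit spans only ~0.33
logit) is estimated low with a credible interval reaching the truth at its
upper end. Typical regional forecast disagreement is under 3 percentage
points (97 % of region-years across replicate surveys), with seed-level
maxima around 2–4 pp.

`res1["excursions"][2010]["set"]` holds the pixels that jointly exceed 40 %
prevalence with 95 % posterior confidence; `res2["metrics"]` the holdout
validation (RMSE 0.056 here; typically 0.05–0.08 on synthetic defaults).

A CLI mirrors the library per stage:

```bash
stuntcast simulate --outdir data/ --seed 1
stuntcast screen --clusters data/clusters.csv --out bic.csv
stuntcast model2 --indir data/ --outdir out/ --seed 1
stuntcast report --indir data/ --outdir out/ --seed 1
```

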