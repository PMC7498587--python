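# chltrend

Bayesian spatio-temporal trend estimation for gridded ocean-colour
chlorophyll, with informative priors built from climate-model ensembles.

## The problem

Satellite ocean-colour records (~20+ years of monthly chlorophyll-a) are
short relative to the natural variability of the ocean, which makes
regional trend detection hard: a naive per-pixel regression wastes the
strong spatial coherence of chlorophyll anomalies, and a frequentist fit
cannot absorb independent knowledge of what trends coupled
physical–biogeochemical models expect. `chltrend` addresses both with a
hierarchical Bayesian model fitted independently in each biogeochemical
province, plus a principled way to turn a multi-model ensemble into a
prior for the trend. It is aimed at ocean-colour and climate-trend
researchers who want calibrated trend uncertainties, and it ships a
synthetic-data generator with known ground truth so every stage can be
validated end to end.

## The model

Observed log-chlorophyll at cell *n*, month *t*:

```
Z_{n,t} = O_{n,t} + ε_{n,t},            ε_{n,t} ~ N(0, σ²_ε)        (data level)
O_{n,t} = x_t'β + w_{n,t}                                           (process level)
x_t'β   = β₀ + β_trend·t + β_seas·cos(2πt/12 + φ)                   (covariates)
w_t     = ρ·w_{t−1} + η_t,  η_t ~ N(0, σ²_w·S),  S_{nm} = exp(−d_{nm}/λ)
```

The spatial correlation decays exponentially with great-circle distance
(λ = 500 km by default, so correlation ≈ 0.05 by 1,500 km); temporal
correlation is AR(1); the seasonal phase φ is fixed beforehand so the
cosine peaks on the climatological month of maximum chlorophyll. The
trend coefficient β_trend carries a normal prior — either vague,
N(0, 100) on the % year⁻¹ scale, or built from an ensemble of climate
model runs: a GLS regression with AR(1) errors extracts a trend from each
run's regional-mean series, ensemble members are averaged within each
model, and the across-model mean and sample variance become the prior.
Fitting is by MCMC (collapsed Metropolis-within-Gibbs with
forward-filter/backward-sampling of w). Trends are estimated on the
log-per-month scale and reported as percentage change of un-transformed
chlorophyll per year, `pct = (exp(12β) − 1)·100`, summarised by the
posterior mode and the 95% highest density interval (HDI); a trend is
significant when the HDI excludes zero. Regional modes aggregate into a
global figure weighted by each region's mean chlorophyll times its areal
extent.

## Worked example

`examples/01_simulate_and_fit.py` simulates one 8×8-cell region for 120
months with a known trend of +1.2 % year⁻¹ and refits it:

```
true trend        : +1.20 % / yr
posterior mode    : +1.36 % / yr
95% HDI           : (+0.90, +1.80) % / yr
significant       : True
AR(1) rho (mean)  : 0.52  (generator used 0.6)
```

The mode is the reported trend estimate; the HDI is its uncertainty band
(here it covers the truth and excludes zero, so the trend is detected
with the right sign and roughly the right size). The other examples build
ensemble priors from a 14-model/24-run synthetic archive
(`02_ensemble_priors.py`), scan prior variances from 100 down to 0.001 to
show shrinkage toward the prior mean (`03_prior_sensitivity.py`), and run
the whole pipeline over four provinces under both priors, ending in the
weighted global trend (`04_full_pipeline.py`). A thin CLI wraps the same
calls: `chltrend run-all --seed 7 --output-dir out/`.

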