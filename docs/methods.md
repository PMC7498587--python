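# Methods

## Model

Each region (a contiguous set of grid cells standing in for a
biogeochemical province) is analysed independently with a two-level
Gaussian model of monthly log-chlorophyll. The data level adds iid
measurement error ("nugget", variance σ²_ε) to a latent true surface; the
process level decomposes the surface into fixed regional covariate
effects — intercept, a linear trend in months, and an annual cosine —
plus a latent space–time process `w`. The process follows AR(1) dynamics
in time with innovations that are spatially correlated as
`exp(−d/λ)` in great-circle distance; each month depends on the previous
month only. The seasonal phase is not estimated: it is fixed beforehand
so the cosine crests on the calendar month at which the across-years mean
of the regional series peaks (ties break to the earliest month). The
time covariate is centered at the record midpoint purely for numerical
conditioning; the trend coefficient is unchanged by this.

Coefficients are region-constant (one trend per region, which is the
point of the province decomposition), and trends are carried internally
in log-chlorophyll per month and reported as percent per year of
un-transformed chlorophyll via `pct = (exp(12β) − 1)·100`. The inverse
and the delta-method variance map live in `priors.convert_prior_units`;
the round trip is exact to floating point.

## Priors

* Trend: normal. The vague form is mean 0, variance 100; a bare variance
  of 100 is scale-ambiguous, so the scale is explicit on every
  `TrendPrior` (default: % year⁻¹, converted inward
  to log-month for fitting — at these magnitudes it is effectively flat
  either way, varying by ~2% across ±2 % year⁻¹).
* Ensemble trend prior: per-run GLS-AR(1) trend on the regional-mean
  series, unweighted ensemble mean within each model (so multi-member
  models do not count extra), then across-model mean and sample variance
  (ddof=1). Fewer than two models is an error; a spread below 1e−8
  (% yr⁻¹)² is floored at 1e−6 with a warning, since a point-mass prior
  is never the intent.
* Intercept and seasonal amplitude: N(0, 10⁴) — diffuse at log-chl scale.
* Variances σ²_ε, σ²_w: inverse-gamma(0.01, 0.01). A scale parameter of
  order one (e.g. IG(2, 1)) is *not* weakly informative here: with true
  variances of order 10⁻³–10⁻², its −scale/σ² term contributes hundreds
  of log-units against small variances, overwhelms the likelihood, and
  visibly biases ρ and σ²_w (and hence interval widths). IG(0.01, 0.01)
  keeps the prior contribution negligible at every plausible scale.
* ρ: uniform(−1, 1). λ is fixed (default 500 km, chosen so correlation
  falls to e⁻³ ≈ 0.05 by 1,500 km) and configurable; sampling it is out
  of scope.

## Sampling

A Metropolis-within-Gibbs sampler, seeded and bit-reproducible:

1. **Missing observations** are imputed from their conditional normal
   each sweep, which keeps the complete-data observation precision
   proportional to the identity. That in turn lets one orthogonalizing
   basis diagonalize everything spatial: with `V` chosen so that
   `VV' = C*` (the knot/cell correlation) and `V'A'AV` diagonal, the
   latent process decouples into independent scalar AR(1) chains
   observed in noise.
2. **β** is conjugate normal given `w`.
3. **(σ²_w, ρ)** are updated jointly by random-walk Metropolis on
   `(log σ²_w, atanh ρ)` against the likelihood with `w` integrated out
   (scalar Kalman prediction-error decompositions per spatial mode, run
   in numba). Collapsing is essential, not cosmetic: the full
   conditionals of these parameters given `w` have standard deviations of
   order 10⁻², so a pure Gibbs scan moves them as a tiny random walk and
   a chain started at ρ = 0 never reaches equilibrium in any practical
   number of sweeps. Step sizes adapt toward ~30% acceptance during
   burn-in only (Robbins–Monro), then freeze, preserving the stationary
   distribution. The marginal-likelihood kernel is validated in tests
   against a dense multivariate-normal evaluation.
4. **w** is then redrawn exactly by forward filtering/backward sampling
   across all months jointly, O(modes × months) per sweep.
5. **σ²_ε** is conjugate inverse-gamma (skipped when fixed).

Setting `sample_process=False` with a fixed nugget collapses the sampler
to conjugate Bayesian linear regression, which is how it is checked
against the closed form. For large regions, `knots=m` switches the
process to a reduced-rank predictive-process approximation with knots on
a regular sub-grid of the region's cells; the full-rank path is the
default at synthetic sizes.

Defaults: 5,000 post-burn-in draws after 1,000 burn-in — desk-scale
settings appropriate to the synthetic problem sizes here (recovery
studies use 3,000 + 1,000; the sensitivity scan uses reduced lengths,
mirroring how such scans trade draws for grid coverage). Production-size
runs are a config value, not a default.

## Summaries

* **Mode**: Gaussian KDE (Silverman bandwidth) evaluated on a 512-point
  grid, with the peak refined by a parabola fitted within three
  bandwidths of the argmax. The refinement matters: the raw argmax of a
  flat-topped KDE has sampling noise of the same order as the grid span
  (~0.05 for 50k standard-normal draws), and the parabolic fit averages
  it down ~3×. Bandwidth choice is configurable in principle but
  Silverman is used throughout.
* **95% HDI**: the shortest window containing ⌈0.95·n⌉ sorted draws.
  It is never wider than the equal-tailed interval. Summaries are
  computed on %-per-year-transformed draws; because the map is monotone,
  significance (HDI excludes zero, boundary counts as touching) is
  unaffected, and endpoints agree with endpoint-wise transformation up to
  the small window shift a convex map can induce.
* **Scenario comparison**: two priors "differ" in a region only if their
  95% HDIs are disjoint; a shared endpoint counts as overlap. Both the
  full width and the half width (± notation) are reported in tables.
* **Global trend**: convex combination of regional posterior modes with
  weights ∝ mean chlorophyll × area, the natural reading of weighting by
  a region's chlorophyll burden. Mean chlorophyll is computed from
  un-logged values over the full record; an area-only weighting is
  available by flag. Posterior modes (not mixed posteriors) enter the
  average.

## Synthetic data

The generator mirrors exactly the structure the model assumes —
per-region intercept + trend + annual cosine, spatially correlated AR(1)
process started from its stationary distribution, white nugget,
missing-completely-at-random gaps — so recovery tests probe estimation,
not model misspecification. Defaults: 1° cells straddling the equator,
8×8 cells per region, 120 months from September 1997; process sd 0.05
and nugget sd 0.10 in log units with ρ = 0.6 (monthly regional log-chl
anomalies of a few percent with ~10% cell-level retrieval noise, typical
open-ocean magnitudes); seasonal amplitude 0.15; intercepts around
ln(0.25 mg m⁻³); 10% missingness. Climate-run series reuse the process
sd and ρ for their AR(1) noise around each model's trend line, with
model trends drawn around the regional truth with configurable spread;
the default archive spans twice the observational record.

What it does not emulate — and what passing tests therefore do not
establish about real data: cloud-structured (non-random) gaps, sensor
merging discontinuities, El Niño-scale interannual events, non-Gaussian
tails, spatially varying trends within a province, and uncertainty in λ.
On real records those effects can widen true uncertainties beyond the
model's; the calibration demonstrated here is internal.

## Numerical choices and edge cases

* GLS-AR(1) (prior construction): iterated feasible GLS, Prais–Winsten
  whitening that keeps the first observation, ρ re-estimated from
  residual lag-1 autocorrelation to tolerance 1e−8 (max 50 iterations,
  failure carries the last iterate); |ρ̂| ≥ 1 is clipped to ±0.99 with a
  warning; an exactly collinear (noise-free) fit short-circuits ρ to 0.
  Leading/trailing missing months are trimmed; interior gaps are
  rejected. Equivalent to dense GLS under the stationary AR(1)
  covariance, which the tests verify to 1e−8.
* Spatial matrices: duplicate cell coordinates raise a degenerate
  geometry error before factorization; eigenvalues of the knot
  correlation must be positive.
* Region layouts grow from random seed cells by round-robin
  breadth-first frontier expansion, giving contiguous, roughly balanced
  provinces; areas follow the exact spherical-zone formula on
  R = 6,371 km, and distances are haversine.
* Downscaling is a box mean over non-missing fine cells (missing only if
  the whole box is missing) and requires integer nesting.
* Regional means are area-weighted by default with an unweighted option,
  since either reading of "regional average" is defensible.
* All randomness flows from explicit integer seeds; pipeline sub-seeds
  are derived per (region, scenario) or per sensitivity-grid cell from
  the base seed via seed sequences, and the run manifest (config hash,
  seeds, version) suffices to reproduce outputs byte-for-byte.

## Known limitations

Single-region fits only (no cross-province borrowing); λ fixed rather
than estimated; Gaussian errors throughout; the predictive-process path
trades small-scale spatial variance for speed as all reduced-rank
methods do; the KDE mode is bandwidth-dependent on strongly skewed
posteriors; and the sensitivity scan defaults to a single region because
its cost is a full refit per grid cell.
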