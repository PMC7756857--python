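# Methods

This note documents the statistical machinery, the synthetic-data
generator, the defaults and the numerical choices. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Responses and data preparation

The unit of replication is the vineyard-year. Weekly scouting visits
record the percentage of 100 inflorescences/bunches with egg infestation.
Three responses are built per farm-year:

* **Mean infestation** per generation (negative binomial, log link). The
  per-generation arithmetic mean of visit percentages is rounded half-up
  to an integer count at model time only; the raw mean is preserved in the
  tables. (How an "average percentage" becomes count-distributed is
  genuinely open; rounding is the simplest faithful choice and is isolated
  in one line of the pipeline.)
* **Outbreak likelihood** per generation: number of visits strictly
  exceeding the 8% economic injury threshold out of total visits
  (binomial, logit link). Ties at exactly 8% count as no outbreak.
* **Insecticide applications** per season: count of applications targeted
  at the focal pest (Poisson, log link).

Generation boundaries are estimated from a pooled seasonal smooth of
infestation on day-of-year (cubic regression spline, basis dimension 10,
unpenalized least squares): the two interior minima of the fitted curve
separate the three flight peaks. If fewer than two interior minima exist
the pipeline falls back to fixed windows (Mar 1–May 15, May 16–Jul 15,
Jul 16–Sep 30) with a warning; with more than two, the two lowest are
used. Day-of-year is computed on a non-leap calendar so windows are
year-stable.

Filters: generation rows with fewer than 4 visits and season rows with
fewer than 10 visits are dropped (inclusive bounds retained); every drop
is itemised in the run report. Farms are excluded when >10% (strict) of
the unweighted 2 km landscape is water, when their location is neither a
vineyard cell nor 8-adjacent to one (programmatic stand-in for manual
imagery checks of coordinate errors), or when they sit closer than 2 km to
the raster edge.

Climate: two separate PCAs (temperature, precipitation) of station-level
mean monthly values across years, on centred data via SVD; each farm
inherits its nearest station's first two axis scores (planar Euclidean
distance, ties to the lowest station id). A greedy collinearity screen
drops, for every covariate pair with |r| > 0.5, the non-preferred member
(altitude preferred over slope, vineyard over annual-crop cover).

## Landscape covariates

Ring profiles use cell-centre membership: a cell at distance d from the
farm belongs to ring `floor(d/100) + 1` (20 rings to 2 km). At 100 m cells
against 100 m rings the discretisation error of polygon clipping is not
worth its cost, and the oracle tests use the same rule. Decay weights are
the Gaussian kernel `exp(−d²/2δ²)` evaluated at ring midpoints
(50, 150, …, 1950 m) and normalised to sum to 1 *before* averaging; the
weighted covariate is the dot product of weights and ring proportions
(and ring-mean NDVI). Whether the original weighting used midpoints or
cell-exact distances, and normalised before or after averaging, is not
recoverable from the literature; this convention is fixed and documented
here, and both orders coincide for the uniform-ring limit.

Covariates for non-map years are piecewise-linear interpolations of the
*covariates* (not the rasters) between 2006/2012/2018 — linearity makes
the two orders equivalent and covariate-space interpolation is far
cheaper. The annual NDVI year runs Sep 15 to Sep 14, aligning the
composite with the end of the third generation.

## The model core

One fitter covers all three families. The linear predictor stacks an
intercept, linear terms, cubic-regression-spline smooths, and one dummy
block per random-effect factor (year, farm, region, observer, cultivar).

* **Splines.** Cardinal natural cubic splines on quantile knots, basis
  dimension capped at k = 3 per smooth; the exact integrated squared
  second derivative is the penalty (`S = D'B⁻¹D`); a sum-to-zero
  constraint is absorbed by reparameterisation, leaving k−1 columns with a
  rank-1 penalty whose null space is the linear trend. Outside the data
  range the basis extrapolates linearly, as natural splines do.
* **Random intercepts** are ridge-penalized coefficient blocks: factor j
  with m_j levels contributes an identity penalty λ_j I, and its variance
  component is φ/λ_j. This is the standard mixed-model-as-penalty
  identity and keeps the whole model inside one penalized least squares
  problem per IRLS step.
* **Smoothing selection.** All λ (smooths and factors alike) maximise the
  REML of the working Gaussian model via the Fellner–Schall update
  `λ_j ← φ(rank S_j − λ_j tr((X'WX+S)⁻¹S_j)) / (β'S_jβ)`, applied once per
  IRLS iteration with step ratios clamped to [1/30, 30] and λ bounded in
  [1e−7, 1e9]. Convergence is two-phase: β and λ co-iterate until the
  working REML score stabilises (relative change < 1e−6, or λ steps
  < 1e−3), then λ is frozen and β polished to a relative deviance change
  < 1e−11. A unit test verifies the Fellner–Schall fixed point against a
  direct grid search of the REML criterion.
* **Negative binomial θ** is profiled by an outer bounded 1-D
  optimisation of the exact log-likelihood over log θ ∈ [log 0.05,
  log 10⁴], warm-starting the inner fit.
* **Weights.** Count-family models take the number of farm visits as
  prior weights; the binomial outbreak model does not (its trials already
  carry the sample size).
* **Summaries.** Effective degrees of freedom `tr((X'WX+S)⁻¹X'WX)`;
  AIC = −2ℓ + 2·edf; deviance explained = 1 − D/D_null with the null from
  an intercept-only fit of the same family (and the same θ); "without
  random effects" always means a *refit* of the same fixed-effect
  structure, not zeroed-out predictions. Term p-values are Wald statistics
  on the penalized (Bayesian) covariance with reference df
  `max(1, round(term edf))` — a heavily shrunk smooth is tested against
  χ²₁, not χ²ₖ. This follows common penalized-smooth practice; it is an
  approximation whose tail behaviour can differ from software-specific
  tests, and a simulation spot-check in the test suite finds it close to
  nominal under the null.
* **Prediction curves** vary one covariate over its observed range, hold
  other continuous covariates at sample medians and random effects at 0,
  and band the linear predictor with ±1.96 SE before applying the inverse
  link. Grids outside the observed range trigger an extrapolation warning.
* **Moran's I** on farm-averaged deviance residuals uses inverse-distance
  weights (zero diagonal, unnormalised; a binary 4-NN scheme is available)
  with the normal-approximation two-sided p-value.
* **Degenerate inputs.** All-zero count responses are rejected (infinite
  intercept); all-zero or all-one binomial responses warn; an
  ill-conditioned penalized system gains a diagnosed ridge floor.

The farmer-response analysis fits (a) Poisson sprays on an ever-exceeded
indicator, (b) Poisson sprays on a k = 3 smooth of the fraction of visits
above threshold, and (c) model (b) excluding never-sprayer farms — farms
with zero insecticide rows of *any* target across the study.

## The subsampling experiment

Farms are assigned to quintiles of their time-averaged surrounding
vineyard cover (stable across iterations); each iteration draws 5 farms
per quintile without replacement plus a uniformly chosen pair of
consecutive years, and refits a simplified model: the vineyard smooth
(k = 3, entering as two unpenalized spline columns), linear climate and
topography terms, a year fixed effect, no random effects. Families follow
the response (binomial for exceedance, Poisson for sprays). These reduced
fits are ordinary GLMs (statsmodels); the vineyard p-value is a 2-df
likelihood-ratio test, which calibrates better than a Wald test at n ≈ 50
rows. Iterations with design or fitting failures are flagged
non-converged and excluded from the significant fraction (the convergence
rate is reported; >20% failures abort). Equal 5+5+5+5+5 allocation is the
natural reading of sampling "across five levels" of cover.

## The synthetic generator

The generator is the package's test bed: it emulates the *structure* of a
regional monitoring database with known ground truth, not any particular
real dataset.

* **Land cover**: argmax over per-class Gaussian random fields, each a
  two-scale mixture — a coarse field (σ = 24 cells) driving
  landscape-scale composition gradients and a fine field (σ ≈ 2.7 cells)
  interleaving classes — with per-class offsets calibrated iteratively on
  the realisation so empirical frequencies match the configured mix
  (default: vineyard 0.30, annual crops 0.15, shrubland 0.15, olive 0.10,
  forest 0.10, grassland 0.10, other 0.08, water 0.02). Semi-natural
  classes get a stronger coarse component (sierra flanks vs cultivated
  plains), so monitored vineyards span contexts from near-monoculture to
  mosaics. Later map years redraw classes on ≤10% of cells inside smooth
  patches. Farms are placed on vineyard cells (monitored farms *are*
  vineyards) with ≥2 km edge margin.
* **NDVI** composites: class-typical levels (forest 3900, shrubland 3100,
  olive 2500, vineyard 2200, grassland 1800, water 400, ×10⁻⁴) plus
  smooth spatial noise and a yearly anomaly.
* **Visits**: weekly March–September; per-visit infested count
  ~ BetaBinomial(100, p) with
  logit p = generation baseline (−6.0, −5.3, −4.6) + a sinusoidal
  within-generation phenology bump (amplitude 0.8, peaking mid-window)
  + vineyard (+1.5) + grassland (+0.8, generation 1 only) + shrubland
  (−0.8, generations 2–3) + a high-NDVI term (−1.0 per 1000 units above
  the 2800 knee, generations 2–3) + random intercepts
  (SD 0.5/0.7/0.4/0.2/0.2 for year/farm/region/observer/cultivar) + visit
  noise (SD 0.3). Beta-binomial overdispersion (ρ = 0.10) makes 8%
  exceedances possible at low mean infestation. Baselines, ρ and the
  field smoothness were calibrated once so that visit-level exceedance
  rates rise through the season at a few percent and mean infestation sits
  at 1–3%, the regime the reported outbreak probabilities describe; they
  were then frozen. Farm-years participate with probability 0.85 and
  individual visits are missed with probability 0.10, so the visit-count
  filters have work to do.
* **Management**: 20% of farms are permanent never-sprayers. Sprayer farms
  treat once per run of consecutive over-threshold visits, within 1–7
  days, with 90% compliance; they also apply rare other-target
  insecticides (rate 0.15/yr) and occasional prophylactic targeted sprays
  (rate 0.2/yr) — without the latter, "never exceeded ⇒ never sprayed"
  would hold deterministically and the ever-exceeded spray model would be
  separated. Fungicide/herbicide/tillage events are Poisson background.
  No farmer-behaviour model is claimed as inference; this is the simplest
  rule set that produces a saturating spray-vs-exceedance relationship
  when never-sprayers are included.

What the generator does **not** emulate: weather-driven pest dynamics,
between-farm dispersal, observer drift, reporting gaps correlated with
infestation, or the real deposit's sparsity pattern (participation here is
near-complete, the real network is much sparser). Passing tests therefore
demonstrate correctness and statistical behaviour of the *methods* under a
known truth, not conclusions about any real landscape.

## Problem sizes used in tests and the acceptance script

Unit tests run on a 60-farm × 4-year study; the end-to-end recovery and
deviance-partition checks use 20 replicates at the full 400 × 13 design
and 5 replicates at 150 × 6 respectively; the subsampling experiments use
300–500 iterations. The acceptance script runs the full default design
once per seed with 500 subsample iterations per response.

## Known limitations

* The shrubland effect is weak by design realism: shrubland averages only
  ~8% of farm surroundings, so its simulated −0.8 effect is detectable in
  roughly half of full-scale replicates, not near-always (the recovery
  test documents this; the vineyard effect is recovered essentially
  always).
* Smooth p-values are Wald-type approximations; no bootstrap or exact
  tests.
* No tensor-product or spatial smooths; random effects are intercepts
  only.
* Single planar CRS; no reprojection. Raster I/O is plain TIFF with JSON
  grid metadata, readable by any TIFF tool but not a full GeoTIFF CRS
  encoding.
* The deposited-data reader maps columns by a user-editable dictionary;
  aggregated (non-visit-level) deposits skip the response-building stage.
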