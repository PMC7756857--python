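# vinescape

Landscape effects on vineyard pest outbreaks and insecticide use: a tested
analysis pipeline for long-term, generation-resolved pest-monitoring data.

## The scientific problem

The European grapevine moth (*Lobesia botrana*) completes three generations
per growing season in Mediterranean vineyards. Regional monitoring networks
scout vineyards weekly, recording the percentage of 100 inflorescences or
bunches carrying eggs; farmers following integrated pest management (IPM)
are supposed to spray only when infestation exceeds the economic injury
threshold (>8% of bunches). Two questions drive the analysis:

1. Does **landscape simplification** — vineyard-dominated surroundings, as
   opposed to mosaics with shrubland, forest and grassland — increase the
   probability that infestations exceed the economic threshold, and the
   number of insecticide applications?
2. Would such landscape effects even be **detectable** in a conventional
   study of a few dozen sites and one or two seasons, given how stochastic
   pest populations are between farms and years?

`vinescape` implements the full chain as a reusable, tested library:

* **Distance-decay landscape covariates.** Land cover around each farm is
  summarised in twenty 100 m concentric rings out to 2 km, then collapsed
  with normalised Gaussian decay weights
  `w_k ∝ exp(−d_k² / 2δ²)` at decay rates δ ∈ {250, 750, 1250} m, for each
  cover class and for mean NDVI (stored ×10⁴). Maps exist only for 2006,
  2012 and 2018; intermediate years are linear interpolations (2008 gives
  double weight to the 2006 map).
* **Penalized-spline mixed models (GAMMs).** Responses per vineyard-year:
  mean infestation (negative binomial), visits exceeding the 8% threshold
  out of total visits (binomial), targeted insecticide applications
  (Poisson). Smooth terms are cubic regression splines capped at 3 knots;
  random intercepts for year, farm, region, observer and cultivar enter as
  ridge-penalized dummy blocks. All smoothing parameters are selected by
  REML via Fellner–Schall updates inside the penalized IRLS loop. The
  package reports AIC, deviance explained with and without random effects,
  Wald-type term p-values, prediction curves with 95% bands, and Moran's I
  residual diagnostics.
* **Subsampling detectability experiment.** 500 times, reduce the data to
  25 farms (5 per quintile of surrounding vineyard cover) and 2 sequential
  years, refit a simplified GLM, and record the fraction of iterations in
  which the vineyard effect is significant.
* **Synthetic-study generator.** A first-class module simulating the whole
  monitoring database — categorical land-cover rasters, NDVI composites,
  farms, weather stations, beta-binomial weekly visits with known effect
  sizes and variance components, and rule-based farmer spraying — so every
  stage is testable end to end with known ground truth.

## Worked example

```python
from vinescape import synthdata, pipeline, gamm

study = synthdata.generate_study(synthdata.SimulationConfig(seed=1))
cfg = pipeline.PipelineConfig(seed=1, deltas=(1250.0,), run_powersim=False)
gen_tables, season_tables, report = pipeline.build_model_tables(study, cfg)

g3 = gen_tables[1250.0]
g3 = g3[g3["generation"] == 3]          # generation-3 outbreak table
fit = gamm.fit_gamm(pipeline._exceedance_spec(cfg), g3)
print(round(fit.deviance_explained, 3))
print(round(fit.p_values["s(vineyard)"], 6))
curve = gamm.predict_curve(fit, "vineyard", grid=[0.0, 0.9])
print(curve[["vineyard", "fit"]].round(4))
```

prints (seed 1; a warning notes that cover 0.0 sits just below the
observed range, i.e. the first value is a flagged extrapolation):

```
0.753
0.0
   vineyard     fit
0       0.0  0.0596
1       0.9  0.3413
```

Read: the generation-3 outbreak model explains 75% of deviance (most of it
via the random intercepts — refitting without them drops it below 10%,
which is the stochasticity story); the vineyard smooth is highly
significant; and the predicted probability of exceeding the 8% threshold
rises from ~6% in vineyard-free landscapes to ~34% at 90% surrounding
vineyard cover in this simulated study.

The same pipeline runs end to end from the command line:

```bash
vinescape run-all --seed 1 --out results/
vinescape simulate --seed 1 --out study/ && vinescape metrics --input-dir study/
```

## Layout

```
src/vinescape/
  rasters.py     planar-grid raster container + TIFF I/O
  splines.py     natural cubic regression splines with curvature penalty
  landscape.py   ring profiles, decay weights, interpolation, exclusions
  synthdata.py   the synthetic monitoring-network generator
  prep.py        generation windows, response tables, filters, climate PCA
  gamm.py        penalized IRLS mixed-model core, Moran's I, comparisons
  powersim.py    stratified subsampling detectability experiment
  pipeline.py    orchestration, run reports, deposited-table reader
  cli.py         `vinescape` command-line entry points
docs/methods.md  model and generator documentation
```

See `docs/methods.md` for the statistical details, default parameters and
known limitations.
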