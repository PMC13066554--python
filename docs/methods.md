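# Methods

This note documents the models, defaults and numerical choices behind
`anppgrid`, in the order the pipeline runs them.

## The synthetic study system

Real applications of this workflow consume field ANPP compilations, a
multi-year-mean ANPP grid, monthly climate reanalyses, and scenario climate
from coupled-model ensembles. The `world` module replaces all of these with a
generated system whose ground truth is known exactly, so every downstream
stage can be tested quantitatively.

**Climate.** Each of four generated variables (temperature °C, precipitation
mm yr⁻¹, shortwave radiation W m⁻², PET mm yr⁻¹) has a spatially
autocorrelated baseline field — Gaussian-filtered white noise (default
length scale 6 cells) rescaled to a prescribed spatial SD around a mean level
— plus a linear trend centred on the 1970–2000 baseline window and spatially
coherent interannual noise. The aridity index is always the cellwise ratio
P/PET, never generated independently, so the ratio identity is exact by
construction. Monthly values are the annual value distributed by fixed
seasonal weights (summed variables) or offset by a zero-mean seasonal cycle
(averaged variables), plus small jitter, so both monthly and annual code
paths are exercised. Non-negative variables are clipped at small positive
floors.

Default magnitudes (mean ± spatial SD; interannual SD): temperature
8 ± 5 °C (0.7), precipitation 550 ± 200 mm (110), radiation 180 ± 25 (8),
PET 900 ± 220 mm (60). These are chosen once to resemble mid-latitude
grassland climates with ~20 % relative interannual precipitation
variability; they are study conditions, not fitted values.

**Ground truth.** Baseline productivity is a smooth positive surface
`B = B_max · P/(P + P_half) · exp(g·(T − T_ref))` (Michaelis–Menten
saturation in baseline precipitation, a gentle exponential tilt in baseline
temperature; `B_max` = 600 g m⁻², `P_half` = 350 mm, `g` = 0.012 °C⁻¹).
Annual truth multiplies `B` by `max(1 + Σ_v s_v a_v, 0.05)` where `a_v` are
the anomalies of the generated annual climate and the sensitivity vector
defaults to s = (precipitation 0.55, PET −0.20, radiation 0.10, temperature
0.03 °C⁻¹, aridity 0). Interannual variability of truth is therefore
entirely climate-driven, which makes anomaly-feature recovery well-posed:
a model denied the anomaly columns must lose skill, and the size of that
loss is meaningful. The aridity sensitivity is zero by default because P and
PET already enter separately; the aridity *feature* is still built and
tested.

**Observations.** Sites are masked cells drawn without replacement
(grassland mask: a smooth random field thresholded at 85 % coverage); each
record is truth plus Gaussian noise (default SD 25 g m⁻², a free test
parameter — field ANPP measurement error is not well constrained), floored
at zero. Reference NPP series divide truth by a temporally stable ANPP/NPP
fraction (default 0.5) and add independent noise, standing in for satellite
and vegetation-model products in the temporal battery.

**What the generator does not emulate:** real biome geography, covariances
between climate variables beyond the P/PET link, reporting heterogeneity of
field compilations, disturbance, or CO₂ effects. Passing tests demonstrate
the *machinery* recovers known structure under realistic noise, not that any
real-world accuracy figure transfers.

## Features

Annual aggregation sums precipitation and PET, averages temperature and
radiation, and recomputes aridity as annual P / annual PET (averaging
monthly ratios is refused). Normals are cellwise means over the configured
baseline window (default 1970–2000, inclusive). Anomalies are relative for
precipitation, radiation, PET and aridity, and absolute (°C) for
temperature; a relative anomaly with |mean| ≤ 1e−6 (variable units) is
flagged undefined and propagates as NaN rather than producing an extreme
outlier — the same concern that motivates the difference form for
temperature, extended to arid-cell zero precipitation. Site→cell lookup is
containment (cell-centre registration, no interpolation). Rows with any
undefined predictor are dropped with a logged count. The base predictor set
is 11 columns (mean ANPP, 5 baselines, 5 anomalies); the extended set
appends 10 static soil/topography rasters.

## Cross-validation schemes

* **random**: seeded permutation split, fold sizes within one row.
* **spatial_block**: square lon/lat tiles (default size targets ≈5·k
  occupied tiles); tiles ordered by descending occupancy (ties shuffled by
  seed) and each assigned to the currently smallest fold, so no tile is ever
  split. Fewer occupied tiles than folds is an error suggesting a smaller
  block size.
* **env_stratified**: z-scored stratification features (mean ANPP + 5
  baselines), k-means with k-means++ and 10 restarts into 10 climate
  classes; each class's rows dealt round-robin (continuing a global pointer)
  after a seeded shuffle, so per-class fold counts differ by at most one and
  overall fold sizes stay balanced. All-constant features fall back to the
  random split with the same seed (logged).

## Model harness

Scores pool out-of-fold predictions into a single vector before computing
R²/RMSE/MAE; per-fold averaging is noisier for small folds. The six learner
families use fixed, conventional settings except the random forest, whose
`ntree` (trees) and `mtry` (predictors tried per split) are grid-searched —
default grid ntree ∈ {200,…,1000} × mtry ∈ {2,…,10}, 10 repetitions, mean R²
deciding, ties to the smaller ntree then mtry. Strategy/learner differences
are tested with repeated-measures ANOVA (the repetition seed is the subject;
all learners share folds within a repetition) followed by Tukey HSD. The
model population retrains the tuned forest under distinct seeds, scores each
by environmentally-stratified CV, and selects the best by R² (tie: lower
RMSE); predictions use that single best model, not the population mean.

## Scenario projection

QDM uses empirical quantile functions with linear interpolation
(min(n, 100) knots), applied per calendar month and per cell: additive for
temperature, multiplicative for precipitation, PET and radiation; aridity is
recomputed from corrected P and PET. Multiplicative divisors are floored at
1e−9 (logged). Correcting the calibration window itself reproduces observed
quantiles exactly at the knots, and constant additive/multiplicative biases
are removed exactly — both asserted in tests. Future anomalies are computed
against the observed 1970–2000 normals, which is consistent because QDM
aligns scenarios to that baseline. Bilinear regridding uses cell-centre
weights, is exact on affine fields, clamps to edge cells outside the source
lattice, and returns NaN whenever any corner is NaN. Predicted ANPP is
floored at 0 g m⁻² (physical non-negativity). Ensemble layers (mean,
population std, median, p05, p95; linear-interpolation quantiles) are NaN
wherever any member is NaN.

## Validation batteries

Percentile classification uses each map's own 20/40/60/80th percentiles
(intervals closed on the left, last closed), which fixes both marginals near
20 % so Kappa isolates spatial co-location; whether shared breaks would be
preferable is genuinely open, and the break source is an argument. Moran's I
and LISA use row-standardised queen contiguity on the raster lattice with
NaN cells removed from the graph; rook weights are available. LISA
significance is a two-sided pseudo-p from seeded conditional randomisation;
neighbour values are drawn with replacement from the other cells — on a
lattice (degree ≤ 8, n ≥ 100) this is indistinguishable in practice from
without-replacement permutation and vectorises cleanly. Residual diagnostics
use sample SD (n−1), five-year bins anchored at the earliest sampling year,
bins with fewer than two observations excluded (logged), and a zero-mean
bin flagged undefined. Gridwise correlations are Pearson over common years,
NaN for zero-variance series, summarised by the fraction of valid cells with
r > 0 per reference member and for the ensemble mean.

## Pipeline, determinism and problem sizes

Every stage derives its seed from the single run seed via CRC-tagged seed
sequences, so a rerun writes byte-identical products; the manifest records
config, seeds, selected hyperparameters and SHA-256 checksums of every file.
The default desk-scale configuration uses a 24×24 half-degree grid,
1958–2023, 240 observations, 5-fold CV, a reduced tuning grid
(ntree {200,400} × mtry {2,4,6}), a 20-model population, three synthetic
scenario "models" under two emission pathways through 2030, and 199 LISA
permutations — sizes chosen so a complete run finishes in minutes on one
core while exercising every code path; all are configurable up to
study-scale values.

## Known limitations

* The synthetic world's anomaly–response link is linear by construction;
  the pipeline's skill there is an upper bound on what identical machinery
  achieves on real, partially non-climatic variability.
* QDM is univariate; cross-variable dependence is preserved only through the
  P/PET recomputation of aridity.
* The spatial-block scheme uses fixed square tiles, not buffered or
  leave-location-out designs.
* Model persistence relies on joblib; containers are versioned but not
  portable across major library versions.
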