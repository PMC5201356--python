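# Methods

## The model

Ground-level PM2.5 at location *l* on day *d* is modelled as a locally linear
function of a boundary-layer-revised aerosol optical depth and six further
covariates:

PM2.5(l,d) = β₀(l,d) + β₁(l,d)·Revised_AOD(l,d) + β₂(l,d)·ST(l,d)
           + β₃(l,d)·RH(l,d) + β₄(l,d)·PS(l,d) + β₅(l,d)·WS(l,d)
           + β₆(l,d)·NO2(l,d) + β₇(l,d)·EVI(l,d)

with units: PM2.5 μg/m³; Revised_AOD dimensionless (AOD divided by PBLH
expressed in km); ST K; RH %; PS Pa; WS m/s; NO2 in consistent arbitrary
column-concentration units (the model is unit-agnostic, coefficients absorb
scale); EVI dimensionless in [−0.2, 1].  NO2 proxies anthropogenic emissions;
EVI proxies the mitigating effect of vegetation.  The reduced model drops NO2
and EVI.

The coefficients are estimated by geographically weighted regression: at each
calibration location a weighted least-squares problem is solved with kernel
weights wᵢ = exp(−(dᵢ/b)²) on great-circle distances (haversine, spherical
Earth R = 6371 km).  The bandwidth is adaptive — b is the distance to the
k-th nearest calibration point (ties included; a zero k-th distance from
duplicated locations falls back to the smallest positive distance) — so
dense clusters get narrow kernels and sparse regions wide ones.  The
alternative half-exponent kernel exp(−(d/b)²/2) is available by
configuration; it only rescales b.

### Estimation choices

- **Local solver.** The weighted system is solved by SVD least squares on the
  square-root-weighted, column-scaled design.  A rank-deficient local design
  receives a tiny ridge (1e-10 × trace of the scaled normal matrix / p) and
  is flagged; a still-singular system raises.  The calibration point's own
  row enters with weight 1 (in-sample fits; held-out skill is measured by
  cross-validation).
- **Bandwidth selection.** k minimises the leave-one-out CV residual sum of
  squares over a configured range, by integer golden-section search (assumes
  a unimodal CV profile; an exhaustive grid search is available and is used
  automatically for small ranges).  Ties break toward larger k (smoother
  surfaces).
- **Fit scope.** Either one fit per calendar day (coefficients indexed by
  day) or a single pooled fit with purely spatial weights.  Pooled is the
  package default and is what the small synthetic studies use; results
  record the scope.
- **Prediction.** A target location gets its own local fit with the kernel
  centred on it; targets whose nearest calibration point lies beyond 3× the
  local bandwidth are masked as extrapolation.

## Upstream stages

- **QA filtering and fusion.** Dark-target AOD keeps only QA = 3 retrievals;
  deep-blue keeps QA ∈ {2, 3}.  The filtered DB field is interpolated to the
  fine grid by ordinary kriging and fills DT gaps; where both are valid the
  DT value is kept (finer native resolution; a mean-blend policy exists).
  Per-cell provenance (DT/DB/blend) is stored.  No cross-product bias
  adjustment is applied.
- **Ordinary kriging.** Exponential variogram γ(h) = nugget +
  sill·(1 − exp(−h/range)); defaults: sill = source variance, range = 3× the
  mean nearest-neighbour spacing of the sources, nugget 0 (exact
  interpolation).  Each target solves the OK system with unbiasedness
  constraint in a neighbourhood of up to 12 nearest sources within a search
  radius of 3× the range; cells without support stay masked; a singular
  neighbourhood system falls back to inverse-distance weighting with a
  logged warning.
- **Temporal matching.** Meteorology uses the 06:00 UTC synoptic slice
  (≈ 14:00 local at the satellite overpass; one national slice is used for
  all stations).  AOD and NO2 are daily; EVI uses the 16-day composite whose
  window contains the date.
- **Collocation.** Each covariate is read from the grid cell containing the
  station (cell-registered half-open cells, lower-left origin).  Rows with
  any missing covariate are dropped (complete-case) with a logged count.

## Cross-validation and diagnostics

Rows are split into 10 balanced random folds; each fold is predicted by a
model fitted on the other nine, with bandwidth selection repeated inside each
training set so no information leaks from the held-out fold.  (Leave-one-out
is available for small scenes.)  Metrics on the pooled held-out predictions:
MAE; the regression R² (squared Pearson correlation of the scatter — the
headline number) and 1 − SSE/SST, both reported because "R²" is ambiguous
between them; and the OLS line of *predicted on measured* (orientation
recorded), whose crossing with y = x, intercept/(1 − slope), is the
demarcation point: with slope < 1 and intercept > 0 the model overestimates
below it and underestimates above — the expected attenuation of any local
smoother, since neighbouring coefficients are shrunk toward each other.

## Synthetic scenes

The generator emulates the national-scale inputs the pipeline was designed
for, on a configurable lon/lat box (default 104–120°E, 26–40°N at 50 km):

- **Covariates** are transformed Gaussian random fields: a persistent base
  pattern plus independent daily synoptic anomalies at a 120 km length scale,
  plus cell-scale texture carrying `covariate_fine_fraction` (default 0.5) of
  the variance, mimicking the mesoscale roughness of real retrievals.  AOD,
  PBLH, NO2 and EVI are log-normal-type (right-skewed); RH/ST mildly skewed;
  pressure is bimodal — a smooth "elevation" field split by a sigmoid into a
  lowland mode near 101.3 kPa and a plateau mode near 70.3 kPa (the
  plateau/lowland elevation contrast of the real domain); EVI is constant
  within 16-day composite blocks.  Magnitudes (AOD ≈ 0.5, PBLH ≈ 800 m,
  ST ≈ 289 K, RH ≈ 60%, wind components SD 3.2 m/s) are typical mid-latitude
  values.
- **Stations** are either a homogeneous point process on the spherical patch
  or a mixture with urban clusters whose centres concentrate toward the
  eastern edge (east-dense / west-sparse, like the real network).
- **Truth** is a set of eight coefficient surfaces, each base + low-order
  polynomial in normalised lon/lat + a smoothed Gaussian field (default
  length scale 600 km); a length scale below the grid spacing is rejected as
  unresolvable.  Default magnitudes put each covariate's contribution at a
  few μg/m³ SD around a ~50 μg/m³ mean, echoing the observed national
  distribution; the intercept absorbs the raw-scale ST/PS offsets.
- **Observations** evaluate the forward model at station cells and add
  Gaussian noise (absolute μg/m³ or a fraction of the signal SD).  Simulated
  PM2.5 below 0.1 μg/m³ is truncated to 0.1 and flagged, keeping the μg/m³
  domain valid.  Raw products: DT = true AOD on the fine grid, DB = 3×3
  block average on the coarse grid, each with independent uniform missingness
  masks and QA draws (QA independent of AOD magnitude by design).
- **Determinism.** All randomness flows from one seed through named
  `SeedSequence` substreams, so scenes are bit-identical given a config and
  the station layout does not depend on the number of days.

What the generator does *not* emulate — orbital swath gaps, cloud-correlated
missingness, QA–value correlation, retrieval bias between DT and DB,
measurement-error structure of the monitors — bounds what passing tests show
about real data: they validate the estimation machinery and its statistical
behaviour under known truth, not retrieval-error robustness.

### Study configurations

Two frozen study configurations drive the headline numbers:

- **Model comparison** (`model_comparison_config`): constant true
  coefficients with genuine NO2 and EVI signal, the EVI contribution
  (~7.5 μg/m³ SD) larger than NO2's (~4 μg/m³ SD), 150 stations × 2 days,
  4 μg/m³ noise.  Ten-fold CV skill then orders the nested models:
  reduced < +NO2 < +EVI < full in R², the reverse in MAE.
- **Parameter recovery** (`recovery_scene_config`): 400 stations, one day,
  25 km grid, noise 10% of the response SD.  The three satellite-covariate
  slopes (Revised_AOD, NO2, EVI) carry distinct domain-scale linear trends;
  the meteorological slopes are constant.  Identifying several simultaneously
  varying surfaces from one day of data requires covariates whose texture
  decorrelates between neighbouring stations (fine fraction 0.9 on the 25 km
  grid); coarser texture makes the local designs collinear and lets the
  surfaces leak into each other.  The recovery fit uses a fixed k = 40
  (~10% of n): LOO-CV selects a prediction-optimal k that is much smaller
  and noisier in the coefficients, and the wide kernel is unbiased for the
  linear trend surfaces.  Estimated and true slope surfaces correlate ≥ 0.9
  for all three varying coefficients across arbitrary seeds; the noiseless
  constant-coefficient scene is recovered to machine precision.

## Numerical conventions and edge cases

- Grids are cell-registered, origin at the box's lower-left, half-open cells;
  "the pixel containing the monitor" uses that convention, so collocation is
  invariant to position within a cell.
- Problem sizes in the test and acceptance studies (80–500 stations, 1–6
  days, 25–150 km grids) are chosen so the full suite runs in a couple of
  minutes on one CPU while leaving every statistical property measurable.
- A fold whose rows cannot be predicted (extrapolation mask) is excluded
  from CV metrics with a logged count; a slope of exactly 1 makes the
  demarcation point undefined (flagged, not a number); zero variance in the
  measured values is an error.
- Annual means default to `min_coverage = 0` (any available day counts),
  configurable; classification bands are half-open and lower-inclusive, so
  exactly 35 μg/m³ counts as exceeding the standard.
- Pipeline stage seeds are derived from the global seed via `SeedSequence`
  so each stage is independently reproducible; artifacts carry SHA-256
  checksums in a manifest and stale inputs are refused.

## Known limitations

- No space–time kernel, mixed global/local terms, or per-covariate
  (multiscale) bandwidths.
- Golden-section bandwidth search assumes a unimodal CV profile; use the
  grid search when in doubt.
- Kriging uses a fixed exponential variogram with heuristic parameters, not
  a fitted variogram.
- Rasters are exported as NetCDF (and tables as CSV); no GeoTIFF writer and
  no cartographic styling.
- The demarcation point is a diagnostic of the fitted scatter, not a
  physical threshold; it moves with the response distribution.
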