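# gwrpm25

Satellite-based estimation of ground-level PM2.5 with a geographically
weighted regression (GWR) model, built for exposure-assessment work where
monitoring networks are too sparse to map fine-particle pollution directly.

Column aerosol optical depth (AOD) retrieved by satellite is a proxy for
particulate loading, but the AOD–PM2.5 relationship varies strongly with
region, aerosol type and mixing state.  This package implements the full
calibration pipeline around a spatially varying coefficient model:

1. **AOD fusion** — fine-resolution dark-target (DT) and coarse-resolution
   deep-blue (DB) AOD products are quality-filtered (DT keeps QA = 3, DB
   keeps QA ∈ {2, 3}), the DB field is brought onto the fine grid by ordinary
   kriging, and the two are merged cell-by-cell (DT priority, provenance
   recorded) to maximise coverage.
2. **Covariate integration** — meteorology (surface temperature ST,
   relative humidity RH, pressure PS, wind u/v, boundary-layer height PBLH),
   NO2 column concentration and 16-day composite EVI are matched to the
   06:00 UTC satellite overpass, collocated to the grid cell containing each
   monitor, and assembled into complete-case station-day design rows.  The
   fused AOD is revised by the boundary layer, `Revised_AOD = AOD / PBLH[km]`,
   to approximate a near-surface extinction proxy.
3. **GWR** — at every location *l* the model

   PM2.5(l,d) = β₀(l,d) + β₁(l,d)·Revised_AOD + β₂·ST + β₃·RH + β₄·PS
                + β₅·WS + β₆·NO2 + β₇·EVI

   is fitted by weighted least squares with adaptive Gaussian kernel weights
   w = exp(−(d/b)²), where the bandwidth b is the great-circle distance to
   the k-th nearest station and k is chosen by leave-one-out cross-validation.
   The reduced model (without NO2 and EVI) and the single-addition variants
   (+NO2, +EVI) are available for comparison.
4. **Validation** — balanced 10-fold cross-validation (bandwidth re-selected
   inside every training fold), R² (both the predicted-vs-measured regression
   R² and 1 − SSE/SST), MAE, and the demarcation point
   `intercept / (1 − slope)` where the predicted-on-measured line crosses
   y = x, separating the overestimation regime (low PM2.5) from
   underestimation (high PM2.5).
5. **Mapping** — daily prediction grids aggregated to annual means and
   classified against air-quality bands (35 μg/m³ = WHO IT-1 / national
   level-2 annual standard).

Because the real national station/satellite archives are not shipped, the
package includes a first-class **synthetic scene generator**: gridded
covariates with realistic marginals (log-normal AOD/PBLH/NO2/EVI, bimodal
pressure), an east-dense/west-sparse station network, known spatially varying
coefficient surfaces, and raw DT/DB AOD pairs with missingness and QA draws —
so every stage is testable end-to-end against a known truth.

## Worked example

```python
import gwrpm25 as g

scene = g.simulate(g.SceneConfig(n_stations=120, n_days=2, grid_res_km=100.0,
                                 noise_sd=3.0, seed=0))
fused = [g.fuse_products(dt, db) for dt, db in zip(scene.dt_grids, scene.db_grids)]
samples = g.build_matched_samples(
    scene.samples[["station_id", "lon", "lat", "date", "pm25"]],
    scene.covariates, fused, scene.config.grid, dates=scene.dates)
cv = g.cross_validate(samples, g.GWRConfig(k_range=(12, 60)), seed=0)
print(f"n={cv.n_rows}  R2={cv.r2_regression:.3f}  MAE={cv.mae:.2f}  "
      f"slope={cv.slope:.3f}  intercept={cv.intercept:.2f}  "
      f"demarcation={cv.demarcation:.1f}")
```

prints

```
n=240  R2=0.902  MAE=5.12  slope=0.906  intercept=4.45  demarcation=47.4
```

i.e. on this 240-row scene the full model explains ~90% of the held-out
PM2.5 variance with a 5.1 μg/m³ mean absolute error; the regression slope
below 1 with a positive intercept is the usual kernel-smoothing attenuation —
the model overestimates below ~47 μg/m³ and underestimates above.

The same pipeline runs from the shell:

```bash
gwrpm25 run-all --out runs/demo --seed 0 --model full --k-range 12,60
```

writing the scene, fused AOD, matched samples, per-location coefficients, CV
summary and the annual mean/band rasters under `runs/demo/` with a checksum
manifest.

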