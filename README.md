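# airfusion

Daily air-pollutant concentration fields that are spatially complete *and*
temporally faithful: `airfusion` fuses sparse ground-monitor observations
(AQS-style point measurements) with gridded chemical-transport-model (CTM)
output such as CMAQ. The CTM supplies complete spatial coverage; the
monitors supply the true temporal variation; the fusion keeps both.

It is aimed at exposure assessment for epidemiology: the output is a daily
concentration raster per pollutant-year, plus evaluation (monitor
withholding) and population-weighted exposure trend tools.

## Method

For each pollutant and year, the CTM field is first calibrated against the
monitors with a power regression on annual means,

    CMAQ_corrected = α · CMAQ^β ,        0 ≤ β ≤ 1,

where α, β are fit by log–log least squares between annual-mean
observations `OBS̄` and annual-mean model values `CMAQ̄` at monitor cells,
both averaged over the *same* day set m (so partial-year monitors are
comparable). Each monitor then yields a daily dimensionless ratio

    r_i = (OBS_i / OBS̄) · (α·CMAQ̄^β) / (α·CMAQ_i^β)

(on non-sampling days r is filled by linear interpolation in time). The
ratios are clipped to [0.1, 10] and spread across the raster by
inverse-distance weighting (IDW, exact at monitor cells), and the fused
field is

    C*_i = IDW(r)_i × α·CMAQ_i^β .

At a monitor cell this collapses to `OBS_i · (α·CMAQ̄^β)/OBS̄` — the fused
field reproduces the observations' day-to-day variation exactly while
inheriting the CTM's spatial texture elsewhere.

Evaluation uses temporal/spatial/pooled squared Pearson correlations and
NRMSE (RMSE / mean observation), with 10-fold random monitor-site
withholding; exposure tools grid census-tract populations by the
cell-centroid rule and compute `Σ F_pop,i · C*_i` daily, with OLS trend
slopes.

A seeded synthetic-data module generates the whole study — grid, smooth
positive truth field with a seasonal cycle, a model field whose corrected
values differ from truth by a smooth spatiotemporal multiplicative error,
monitor networks sampling daily / 1-in-3 / 1-in-6 days, and rectangular
census tracts — so everything is testable without downloads.

## Worked example

```python
import airfusion as af

scn  = af.SyntheticScenario(seed=11)          # 30x40 grid, 365 days, 40 sites
data = af.generate_scenario(scn)
res  = af.run_fusion_year(data.monitors, data.model, data.grid, pollutant="pm25")
print(f"alpha={res.params.alpha:.3f} beta={res.params.beta:.3f} r2={res.params.r2:.3f}")

cv = af.cross_validate(data.monitors, data.model, data.grid, k=10, seed=11)
print({k: round(v, 3) for k, v in cv.summary.items()})
```

prints

```
alpha=1.164 beta=0.834 r2=0.891
{'pooled_r2_fused': 0.696, 'pooled_r2_raw': 0.1, 'nrmse_fused': 0.166,
 'nrmse_raw': 1.028, 'n_folds': 10}
```

The fit comes close to the generator's true parameters (α\*=1.5, β\*=0.8)
but not exactly — the smooth model error leaks into the annual means — and
the daily ratio field removes the residual bias: at withheld monitors the
fused field's NRMSE (0.166) is a sixth of the raw model's (1.028), and its
pooled R² (0.70) far exceeds the raw model's (0.10).

The same pipeline is available from a shell:

```sh
airfusion make-fixtures --scenario small --seed 7 --out fixtures/
airfusion fuse --model fixtures/model.nc --monitors fixtures/monitors.csv --out fused.nc
airfusion crossval --model fixtures/model.nc --monitors fixtures/monitors.csv \
    --k 10 --seed 1 --out cv.json
airfusion exposure --field fused.nc --tracts fixtures/tracts.geojson --out exposure.csv
```

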