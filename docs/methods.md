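# Methods

This note documents the statistical model, the numerical conventions, the
synthetic-data generator, and the design choices that were genuinely open.

## The fusion model

The package combines two data sources with complementary failure modes. A
chemical-transport model (CTM) field is spatially complete but biased: its
magnitudes can be off by large, spatially and temporally structured factors
(emissions inventories, meteorology, sub-grid variability). Ground monitors
are accurate but sparse in space and, for many particulate species, sparse
in time (1-in-3-day or 1-in-6-day schedules).

The calibration step fits, per pollutant and per year,

    OBS̄_s = α · CMAQ̄_s^β,   β ∈ [0, 1],

across monitor cells s, where both annual means are taken over the same day
set (the days the monitor reported). Restricting the model mean to the
monitor's day set is what makes seasonal or partial-year monitors
comparable to year-round ones. β is capped at 1 so the correction can never
amplify high model values super-linearly, and floored at 0 so it stays
monotone.

The daily step converts each monitor observation into the dimensionless
ratio r = (OBS/OBS̄)·(α·CMAQ̄^β)/(α·CMAQ^β). The first factor carries the
observation's temporal anomaly; the second normalizes by the model's own
anomaly at that cell, which removes the part of the day-to-day variation
the model already captures. α cancels algebraically but is carried through
for numerical parity with the calibration. Ratios are interpolated across
the raster (IDW) and multiplied with the corrected model field.

Consequences worth knowing:

- **At monitor cells the fused field is exact in a specific sense**: it
  equals OBS·(α·CMAQ̄^β)/OBS̄, i.e. the observation rescaled by the cell's
  annual calibration factor. In-sample temporal R² at monitor cells is
  therefore 1 by construction; only *withheld* monitors measure real skill.
- **The method cannot create spatial detail** beyond what the CTM field and
  the monitor network jointly contain; between monitors the spatial pattern
  is the corrected model's, modulated by a smooth ratio surface.
- **Annual-mean calibration under a time-varying field has a Jensen gap**:
  mean(m^β) ≠ (mean m)^β, so even noise-free observations that satisfy
  OBS = α·CMAQ^β daily do not put the annual pairs exactly on the power
  law unless the field is time-constant at each cell or β = 1. The gap is
  O(β(1−β)·var(log m)) — fourth decimal place for realistic seasonal
  amplitudes — and the daily ratio field absorbs it.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| IDW power | 2 | distance-decay exponent of the interpolation weights |
| IDW neighbours | all | every monitor contributes to every cell |
| ratio bounds | [0.1, 10] | clip applied to point ratios before interpolation |
| node epsilon | 1 m | distance under which a cell takes a point's ratio exactly |
| β bounds | [0, 1] | exponent constraint of the calibration |
| min pairs | 3 | annual pairs needed for a fit |
| min paired days/sites | 3 | pairs needed for a Pearson correlation |
| folds k | 10 | withholding groups (≈10% of sites each) |
| east/west split | lon −94.6046° | boundary longitude; the line itself counts as east |

Clipping is applied to the *point* ratios rather than the interpolated
raster (a post-interpolation clip is available via
`IdwSettings(clip_stage="field")`). Clipping inputs makes the interpolated
field a convex combination of clipped values, which guarantees the
bounded-correction property C*/corrected ∈ [0.1, 10] everywhere; clipping
only the output would not bound values between monitors.

Temporal filling of ratios is linear between a site's consecutive sampling
days; beyond the first/last sample the nearest sampled ratio is held
constant (extrapolating the line instead can manufacture extreme ratios at
year edges).

Daily metrics follow the regulatory conventions: 24-h mean for particulate
species, daily 1-h maximum for gases, daily maximum 8-h running mean for
ozone. The 8-h metric uses the 17 windows wholly contained in the local
day; windows crossing midnight are excluded so each day is self-contained
(the window set is configurable in principle through the aggregation code,
and the choice matters at the ~1% level for typical diel cycles). Local
time is the nautical offset round(lon/15); a zone-override table can encode
civil time zones where that matters.

Fitting is by ordinary least squares in log–log space; "power regression"
admits several operationalizations, and the log-space fit is deterministic,
closed-form, and gives a closed-form re-estimate of log α (mean log-ratio)
when β must be clamped to a bound. A bounded nonlinear least-squares
alternative in the original scale is available (`method="nls"`). Annual
pairs with non-positive means are excluded rather than floored — flooring
would bias α low — and exclusion counts are logged.

## Evaluation conventions

Temporal R² is the unweighted mean over monitors of the squared Pearson
correlation of daily series; spatial R² the unweighted mean over days of
the cross-site correlation (medians available via `agg="median"`). Series
with fewer than 3 pairs or zero variance are excluded and counted, not
scored 0 — scoring them 0 would deflate the average with undefined
statistics. NRMSE is RMSE divided by the mean observation.

Withholding operates on whole monitor *sites* (all their observations), the
unit that tests spatial prediction; folds are a seeded uniform random
partition into k near-equal groups. Per fold, the regression is refit and
the fusion rerun from scratch on the retained sites only; withheld
observations enter nothing but the scoring. The raw (uncorrected) model is
scored at the identical site-days as the baseline.

Sampling-day strata: a calendar day is labelled **A** when only 1-in-3
monitors report, **B** when the 1-in-3 and 1-in-6 schedules coincide (every
sixth day, the densest case), and **C** when only daily monitors report.

## Population gridding

A cell belongs to the tract containing its centroid; each tract's
population is divided equally among its assigned cells (no dasymetric
refinement — within-cell population is assumed uniform). A populated tract
containing no cell centroid is reassigned to the cell nearest its centroid
with a warning, so population is conserved exactly and ΣF_pop = 1 by
construction. Trend slopes are OLS of the daily exposure series on day
index; the units are concentration per day.

## The synthetic generator

`SyntheticScenario` defaults define a 30×40 cell grid (0.1° spacing), one
365-day year, mean level 10 µg/m³, a log-scale seasonal cycle of amplitude
0.3, spatial structure from five Gaussian bumps (SD 1°, log-amplitude
±0.5), true calibration α\*=1.5, β\*=0.8, and 40 monitors (40% daily, 40%
1-in-3, 20% 1-in-6; the two sparse schedules coincide every sixth day).
Observation noise is multiplicative lognormal with log-SD 0.1 — keeping
everything strictly positive, consistent with the power-law form.

The model field is defined implicitly by α\*·M^β\* = T·exp(ε): correcting
it with the true parameters recovers truth up to the error surface ε. ε
has a static spatially smooth component (log-amplitude 0.3, the persistent
bias of emissions and terrain) and a temporally varying component of the
same spatial smoothness whose daily amplitudes follow a Gaussian-smoothed
path with ≈15-day correlation (log-amplitude 0.3, the meteorology-driven
error). A CTM whose error is constant in time would be a noiseless
monotone transform of truth — near-perfectly correlated with observations
day to day — which is not the regime a daily fusion method addresses; the
temporal component is what gives the raw model realistic (imperfect) daily
correlation. Both components vanish when their amplitudes are set to 0,
which is how the exact-identity tests construct their inputs.

What the generator does *not* emulate: real US geography and projection
(the grid is geographic, distances are haversine), CTM chemistry or
emissions structure, monitor siting bias toward cities, missing-data bursts
and QA flags, or spatially heterogeneous measurement error. Passing tests
therefore demonstrate the correctness and the qualitative behaviour of the
algorithms in their intended regime, not performance on any real network.

## Problem sizes

The test suite and the acceptance script use one full-size study (30×40
cells × 365 days × 40 sites, with 10-fold refits) and smaller 10×12-cell
scenarios for unit-level checks; parameter recovery uses 200 simulated
50-site networks per exponent. These sizes give stable estimates (the CV
summary moves in the third decimal across seeds) while the whole suite
runs in well under a minute.

## Known limitations

- IDW with all points and power 2 is O(cells × monitors) per year in
  memory; very dense networks would want the `neighbor_count` cutoff.
- Uncertainty is not quantified (no kriging variance analogue).
- One calibration per pollutant-year: no spatial or seasonal variation in
  α, β by design.
- The linear temporal fill of ratios assumes the monitor's relative anomaly
  moves smoothly between sampling days; sharp episodes between 1-in-6
  samples are smeared.
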