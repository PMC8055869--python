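# Methods

This note documents the statistical procedure the package implements, the
design of the synthetic study domain it is exercised on, the numerical
choices that matter, and what the tests do and do not establish about real
data.

## 1. Problem and estimator

The target is a complete daily panel of 24-h mean PM2.5 (µg/m³) at areal-unit
centroids (county / ZIP / census tract) over a study domain, estimated from
irregular monitor observations and gridded predictors. The estimator is a
stacked ensemble:

1. **Base learners.** A bagged-trees regressor (random-forest family) and a
   gradient-boosted-trees regressor, both LightGBM models run
   single-threaded with `deterministic=True` so that a fixed seed reproduces
   every number. Default capacities (trees/leaves/subsampling; see
   `pmstack.model.BAGGED_DEFAULTS` / `BOOSTED_DEFAULTS`) are sized so that a
   full multi-seed evaluation runs on one CPU in minutes while the boosted
   learner retains enough capacity to interpolate the training data closely
   — the overfitting diagnostic below depends on the model *being able* to
   overfit. Capacities are configuration, and `tune_hyperparameters`
   grid-searches per-learner parameter lists by CV RMSE (ties go to the
   first-listed point).
2. **Combiner.** Ordinary least squares of the labels on the two base
   learners' out-of-fold predictions, with intercept — an identity-link
   Gaussian GLM with exactly three parameters. Fitting the combiner on
   out-of-fold rather than in-sample predictions prevents it loading onto
   whichever learner memorizes hardest. The coefficients are unconstrained;
   nothing forces them to be positive or to sum to one.
3. **Refit.** After stacking, both base learners are refit on all training
   rows; for surface prediction the "full model" is refit on everything,
   including the held-out test rows, since at that point evaluation is done.

**Evaluation.** Before any cross-validation a 10% test set is removed: 10%
of *locations* for the spatial analysis, 10% of *observations* for the
random analysis. Ten-fold CV then either scatters observations at random or
keeps all records of a monitoring site in one fold ("spatial" folds,
balanced by location count). Random-fold CV answers "how well do we
interpolate at monitored places?"; spatial-fold CV answers "how well do we
predict where no monitor exists?" — the question the exported surface faces.
R² is the squared Pearson correlation by default (`r2_method="ss"` gives the
1 − SSres/SStot alternative; both are reported by the same code paths).
NRMSE divides RMSE by the mean observation of the subset. Stratified
reports cover cumulative concentration bands (below 35/60/150/300/500/1000
µg/m³), years, states and seasons.

**Seasons** are meteorological (DJF/MAM/JJA/SON) with December assigned to
the *following* year's winter so winters stay contiguous; the same rule is
used in evaluation strata and seasonal areal aggregation.

## 2. Feature recipes

All linkage is nearest-neighbour in WGS84 coordinates with haversine
distances (Earth radius 6371.0088 km); there is deliberately no projection
step. Exact-date matching is used for daily layers, month matching for the
vegetation index.

- **Fire proximity.** For each day-lag ℓ ∈ {0..7}, fire detections on day
  (t − ℓ) are counted within cumulative radii of 25, 50, 100 and 500 km,
  and the counts are combined with inverse-radius weights:
  idwℓ = Σᵣ (countᵣ/r) / Σᵣ (1/r). A binary indicator flags ≥ 1 detection
  within 500 km over the 8-day window. The weighting uses the buffer radii
  (the objects the recipe names), not per-fire distances; the per-fire
  Σ 1/dᵢ construction is a reasonable alternative the code does not use.
- **Buffer fractions.** Share of raster cells whose centre falls within
  1/5/10 km carrying urban land-cover codes 22/23/24; when the radius is
  below the cell size the nearest cell decides alone.
- **Road length.** Arterial + collector polyline length within 100/250/500/
  1000 m, by densified-vertex summation: segments are cut into ≤ 25 m pieces
  and a piece counts iff its midpoint is inside the buffer. Tests pin this
  against a 1-m densification oracle at 1%.
- **Meteorology.** 24-h means of up to four 6-hourly records (ten NAM-style
  variables); partial days average what is present.
- **Temporal harmonics.** cos(2πw/7) with Monday = 0, cos(2π(d−1)/365.25),
  cos(2π(m−1)/12). The 365.25 denominator keeps Dec 31 → Jan 1 aligned
  across leap years (|Δ| < 0.01).
- **Spatiotemporal basis.** One-hot periods (2008–2012 / 2013–2016 /
  2017–2018, mapped by year with years outside the range clamped to the
  nearest period), year, season, region, state, period×region interactions,
  plus raw latitude/longitude. Exactly one dummy is active per group per
  row. The region map for the 11 western US states ships as
  `features.WESTERN_US_REGIONS`; synthetic worlds carry their own map.

## 3. Imputation

Cloud-masked AOD leaves ~35% of rows incomplete, and the tree learners here
require complete design matrices. Missing predictor cells are filled by
chained bagged-tree imputation run independently **within each state**:
missing cells start at column medians, then each incomplete column (in order
of increasing missingness) is re-fit on the rows where it was observed and
its missing cells re-predicted, sweeping until the relative L2 change of the
imputed values drops below `tol = 1e-3` or `max_iter = 10` sweeps. The
imputation learner uses `min_child_samples=5` because state groups can be a
few dozen rows. The same routine is applied to training rows and prediction
inputs; rows with at least one imputed cell carry `missing_vars = 1` in the
exports. A column entirely missing within a state is an error, not a guess.

## 4. Prediction and export

The full refit model predicts every (centroid, day); raw ensemble values are
kept internally and negative values are truncated to zero at export (a
logged count; a flag disables it). Files are written one per state per
variant using the published column names — `ranger_preds`/`xgbt_preds`
(no-CTM variant) or `CMAQ_ranger_preds`/`CMAQ_xgbt_preds` (with-CTM) plus
`County_FIPS, Tract_code, ZCTA5_code, Lon, Lat, Date, Missing_vars,
Ens_pred` — so downstream tooling built for the deposited dataset reads
them unchanged. Validation pairs each monitor observation with the spatially
nearest centroid's same-day prediction (ties to the lowest unit id), reports
RMSE/R² for all monitors and for "stable" monitors (≥ 31 distinct days;
short-lived mobile fire deployments sit at extreme conditions and distort
network-wide comparisons), and can emit per-location time series and
seasonal areal means.

## 5. The synthetic world

The generator emulates the statistical structure of the study inputs, not
their physics. Truth is log-additive:

    PM2.5(s, t) = exp( b(s) + 0.09·local(s) terms + 0.33·cos-seasonal(t)
                       + 0.5·urban(s) − 0.25·(elev(s) − mean)/km
                       + valley(s)·0.5·max(0, 400/PBL(s,t) − 1)
                       + 0.25·weather(s,t) )
                  + Σ_fires size·exp(−d²/2σ²)·decay^lag,  lag = 0..7

with σ = `smoke_sigma_km` (40 km) and decay = `smoke_decay_per_day` (0.65).
The exponential gives nonnegative, right-skewed concentrations; the
inversion term couples winter PM to low boundary-layer heights inside a
low-elevation valley around the main city; fire occurrence is seasonal
(late-summer peak) with lognormal sizes, so summer/fall carry smoke spikes
into the hundreds of µg/m³. The spatial baseline uses a fixed set of
low-frequency sinusoids rather than a Gaussian-process draw (O(n) to
evaluate anywhere, controllable correlation length). A separate
**short-wavelength (~25 km) component** represents monitor-site-scale
variation that gridded predictors cannot resolve; it is what makes random
folds measurably optimistic relative to spatial folds on synthetic data, the
same mechanism as in real networks. Removing it makes the two CV geometries
nearly indistinguishable — worth remembering when reading the acceptance
numbers.

Predictor layers derive from the truth: AOD is affine in same-day cell truth
plus correlated noise, masked by smoothed "cloud" fields at marginal rate
`aod_missing_prob`; the CTM proxy is the truth grid spatially smoothed at
`ctm_smooth_km` plus a constant `ctm_bias` (smoothing alone is the error
model); meteorology is built from seasonal cycles, diurnal profiles and
smooth noise, with PBL height collapsing in winter. All rasters share one
resolution and registration (`raster_resolution_km`, 25 km) because
nearest-neighbour joins are the linkage everywhere; multi-resolution
fidelity would add cost without exercising different code.

The monitor network is 60% urban-sited; `every_third_day_fraction` (0.6) of
stationary monitors report 1-in-3 days (the regulatory-network cadence
typical away from cities); 30% of monitors run the full year and the rest a
contiguous 60–240-day window, reflecting commissioning/decommissioning in
real archives, whose long-run density is far below a full panel. Mobile
fire monitors exist only on days with an active fire within 100 km of their
site. A `duplicate_fraction` of records is re-emitted verbatim under a
second source label, and `extreme_injection_count` records are overwritten
with values above 850 µg/m³ — both exist to be removed by QC, and the
per-source raw tables use heterogeneous column layouts to exercise
harmonization. Observation noise is multiplicative lognormal
(`obs_noise_sd` = 0.10 on the log scale); the noise model is a generator
choice, not a claim about instruments.

Determinism: every component draws from `default_rng([seed, crc32(name)])`,
so identical configs regenerate bitwise-identical worlds and changing one
component (e.g. `fire_rate=0`) leaves the others untouched — the additive
structure of truth is testable exactly.

**What passing tests show — and don't.** On this world the pipeline
reproduces the qualitative findings that motivate the design: random-fold
CV ≥ spatial-fold CV R² across seeds, in-sample R² ≈ 0.95 far above both,
the with-CTM variant beating the no-CTM variant, underprediction of the top
percentile, and imputation beating median fill. The synthetic world has no
real atmospheric transport, no satellite swath geometry, no instrument
biases differing by network, and its missingness is ignorable by
construction; absolute error levels on real data will differ, and the
acceptance numbers are properties of the generator's conditions, not
forecasts of field performance.

## 6. QC rules

Records are deduplicated on (lon, lat rounded to 5 decimals ≈ 1 m, date) —
coordinates are the only cross-source-stable key — keeping the copy from the
highest-precedence source (caller-configurable order, default
`airnow > improve > state_network > fire_cache`). Values strictly above
850 µg/m³ are removed as implausible (the boundary value 850.0 is kept), and
negative reported concentrations are dropped: 24-h averages below zero are
instrument artifacts and the training target must be nonnegative. Both
filters are idempotent, and filtering commutes with deduplication when
duplicate copies carry equal values.

## 7. Numerical and problem-size choices

- Acceptance experiments run the default world (300 monitors + 30 mobile,
  365 days, ≈ 40k observations after QC) over seeds 1–10; unit tests use a
  40-monitor, 120-day world. These sizes keep the full suite at minutes on
  one CPU while leaving every mechanism (schedules, windows, duplicates,
  extremes, fires, inversions) active.
- Fold assignment is by shuffled round-robin, so fold sizes differ by at
  most one (rows in random mode, locations in spatial mode).
- Nearest-neighbour ties break to the lowest source index / unit id,
  deterministically.
- The stacker solves least squares via `numpy.linalg.lstsq`; tests pin the
  coefficients to the normal-equations solution at 1e-8.
- Permutation importance permutes each feature with
  `default_rng([seed, feature_index, repeat])`, making single columns
  reproducible in isolation; collinear features share credit, so duplicated
  signals rank lower individually — by design of the metric, not a bug.
- CSV round-trips use `float_precision="round_trip"` on read; default
  pandas parsing is not bit-exact.

## 8. Known limitations

- Buffer fractions count raster cell centres; at radii close to the cell
  size the fraction is quantized (the nearest-cell fallback covers the
  sub-cell regime).
- `harmonize_sources` assumes µg/m³ throughout; no parameter-code-specific
  handling (e.g. FRM vs non-FRM equivalence corrections).
- Validation matches against all observations, including rows the full
  model trained on; the overlap is inherent to a complete-panel comparison
  and is documented rather than corrected.
- The spatial CV estimates new-*location* error inside the monitored
  domain; it says nothing about extrapolation beyond the domain boundary or
  to unmonitored regimes (e.g. plume cores never observed).
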