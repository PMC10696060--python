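# Methods

`stopover_radar` re-implements, as a tested pipeline over a synthetic world
with known ground truth, a continental analysis of nocturnal bird-migration
stopover density measured by S-band weather-surveillance radar and modelled
against 49 landscape predictors. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic world
does and does not establish.

## The measurement model

**Stopover density** is vertically integrated linear radar reflectivity
(η, cm²/km²) of biological scatterers at the nightly *exodus time* — the
minutes-after-sunset instant at which the smoothed median reflectivity of
the lowest sweep (≤ 100 km) rises fastest. It is estimated per station and
season by a penalized B-spline GAM (basis dimension k = 10, via
`statsmodels` `GLMGam`) of median η on minutes after sunset, with per-date
intercept offsets standing in for date random effects; the smooth is
evaluated on a 1-minute grid over [0, 150] and the maximum first difference
selects the time (ties resolve to the earliest minute). Degenerate series
that the GLM iteration cannot fit (e.g. exactly interpolable curves) fall
back to unpenalized least squares on the same design; a flat fitted curve
raises "no exodus signal".

**Clutter mitigation** applies, in order:

1. *Topographic mask.* Under 4/3-earth standard refraction, beam-center
   height is h = √(r² + R′² + 2rR′ sin θ) − R′ + h₀ with R′ = (4/3)·6371 km.
   A voxel is terrain-blocked when the lower beam edge (center minus half
   of the 1° beam width) lies at or below the running maximum of terrain
   elevation along the ray out to that voxel. The running-max criterion —
   rather than permanent occlusion — lets gates clear again once the beam
   climbs above an obstacle, which matches how a discrete wall should mask.
2. *POD mask.* For each year, the 300-scan January pool (first scans from
   2 January; 60 at desk scale) is reduced to the 30 lowest-total-linear-
   reflectivity scans after clipping at 35 dBZ, totals computed on a fixed
   1° × 500 m polar grid. Probability of detection at 10 dBZ is the
   fraction of those clear scans strictly exceeding 10 dBZ; a cell is
   static clutter iff POD ≥ 20% in ≥ 2 years. Masks are kept per elevation
   angle.
3. *Precipitation.* Precipitation masks are inputs (the upstream
   convolutional rain classifier is out of scope; the simulator provides
   ground-truth masks). Contaminated voxels plus everything within 5 km
   *ground-projected Euclidean* distance (not gate/azimuth counts — the
   physical size of a polar cell is range-dependent) become missing; a scan
   is rejected when the contaminated fraction of the 7.5–80 km annulus
   strictly exceeds 30%.
4. *Exclusion buffers* (e.g. bat roosts) are permanent circular masks in
   domain coordinates; whole-station exclusion is supported.

**Range correction.** The vertical profile of reflectivity (VPR; 20 bins of
100 m, 0–2000 m AGL) is the mean valid η per beam-center-height bin, pooled
over all sweeps at 5–35 km range — the band where every sweep still
overlaps the 0–2000 m layer, giving a stable profile. For a voxel at range
r, overlap(r) = Σ_b VPR(b)·w(b|r) / Σ_b VPR(b), where w is the Gaussian
beam weight (FWHM 1°, σ = FWHM/2.355) at the bin mid-height summed over the
sweeps actually valid at that voxel. Column density = (vertically summed η)
× (1/overlap) × 0.1 km. Voxels with adjustment factor ≥ 10, or outside
7.5–80 km, are dropped. Polar columns are resampled to the 1-km grid by the
mean of voxel centers per cell (cells containing no voxel center stay
missing). Nightly rasters are averaged per season-year over non-rejected
nights, stations are mosaicked by the per-pixel mean, and the result is the
measured stopover response.

The estimated VPR is a beam-smoothed version of the true profile; because
the overlap integral itself smooths at the same scale, the induced range
bias is small — the uniform-truth check bounds the residual trend below 2%
of the mean per 10 km.

## Predictors (49)

4 monthly EVI layers per season-year (quality handled as a binary
good/filtered flag honoured at assembly — real QA bit layouts are out of
scope), 15 merged land-cover class fractions at 1-km and again within a
5-km circular buffer (the two low-intensity developed classes merge; the
buffer is computed by disc-kernel convolution of the 1-km fractions, edges
clipped), % canopy, % impervious, 8 semimonthly accumulated nocturnal
degree-day (ANDD) layers, seasonal mean daily precipitation, skyglow,
elevation, distance to the nearest station, and year.

**ANDD.** Minimum nightly LST is the per-composite minimum of the two
nominal overpass series (one missing → the other). Gaps are filled by
seasonal decomposition: the periodic per-position mean is removed, the
deseasonalized series is filled by an exponentially weighted moving average
(weights 2^−|offset| over up to 4 composites each side; missing neighbours
are skipped, and isolated long gaps fall back to the nearest valid value —
a windowed variant of the R `imputeTS` procedure, identical on isolated
gaps), and the seasonal component is restored. Observed values are never
altered. NDD_t = max(minLST_t − 0 °C, 0); each 8-day composite contributes
NDD_t × m degree-days, where m is the number of covered days falling in
each month (e.g. the DOY-057 composite splits 3 days into February and 5
into March in non-leap years; the final composite truncates at year end).
Accumulation resets on 1 January. Semimonthly layers read out at the last
composite ending on or before each half-month's final day — the readout
instant is not pinned down externally, and this choice makes layers exact
partial sums.

## Niche model

Gradient-boosted regression trees (XGBoost, squared error, response on the
natural density scale) with max_depth 16, min_child_weight 1, gamma 0,
colsample_bytree 1, subsample 1, learning rate 0.1, and early stopping
(patience 10) on the validation fold. The 75/15/10 train/validation/test
split is assigned at the *location* level by hashing pixel ids with the
seed (order-independent, one global assignment reused by every box). The
hyperparameter search grid that selected these values ships as
`BOOST_SEARCH_GRID` documentation and is not run by default. Numerical
choices: `tree_method="hist"` with max_bin 64 and a single thread — the
histogram resolution is an implementation knob, not a model hyperparameter,
and one thread keeps runs bit-reproducible.

Spatial partitioning guards against long-distance learning: boxes are
squares centered on uniform random points, clipped to the domain. At continental
scale that is 2000 × 400 km + 500 × 800 km; the desk profile uses
60 × 200 km + 15 × 400 km over the 512 × 512 km domain so the full ensemble
trains in minutes on one CPU. Prediction mosaics per-box predictions of the
latest year's layers with distance-to-radar fixed at 35 km, averaging
overlaps.

**Holdout experiment.** Each small box reruns with a 10-km block held out,
centered on the median (x, y) of the box's rows; boxes with fewer than 25
held points are excluded. Training uses the modified hyperparameters
(learning rate 0.25, colsample 0.75, subsample 0.5). Pooled predictions are
averaged per (location, year), one year is kept per location uniformly at
random, and predicted is regressed on actual by OLS; R² is the headline
fidelity number. Interpretation and the holdout use the small-box ensemble
(mirroring the source analysis, which used the 400-km models); the large
boxes participate in surface prediction only.

**Interpretation.** Gain is normalized to sum to 1 within each model, then
averaged across models (variables absent from a model contribute 0).
Partial dependence holds all other predictors at the box's *training*
medians — PDPs are per-model objects — over a 50-point grid spanning the
observed range. Directionality: OLS slope of PDP prediction on grid value
with a two-sided t-test (grid points treated as independent observations,
mirroring the source's linear fit to PDP predictions); slopes with p < 0.05
are kept; a variable is positive if > 55% of *significant* slopes are
positive, negative if < 45%, neutral between, insufficient if none is
significant. Whether the percentage is taken among significant slopes only
or among all models is ambiguous in the source; the significant-only
reading is the default, with `among_significant=False` exposing the
alternative.

## Mapping

Hotspots are relative: per pixel, the 50th/90th empirical quantiles
(inclusive linear interpolation, so the ≥ class rule is deterministic) of
defined values within a 265-km circular focal window (pixel-center
membership, clipped at domain edges — edge behaviour is not specified
externally; clipping is the documented choice); classes are high ≥ Q90,
medium ≥ Q50, low < Q50, undefined when fewer than 10 defined values fall
in the window. Region-level (e.g. state) classification applies the same
rule within labels. The analysis driver computes focal quantiles on a 4-km
aggregation of the 1-km surface; the window radius dwarfs the aggregation
scale. Flyway bands use the nominal-longitude affine: west strictly beyond
103°W, central (90, 103], east ≤ 90°W.

## The synthetic world

The generator supplies everything the real pipeline would download, with
the statistical structure the analysis assumes and full ground-truth
traceability (truth density, clutter/precipitation/bat masks, planted
take-off midpoints):

- **Landscape.** All continuous fields derive from Gaussian random fields
  (white noise smoothed by a Gaussian kernel whose sd is the range
  parameter, 50 km by default; periodic boundary; empirically
  standardised). Land-cover fractions are a softmax over 15 per-class
  fields with prevalence offsets, so they are smooth and close to 100% per
  pixel; the developed classes and skyglow share exponential-decay kernels
  around random city points (decay length 9 km), making skyglow spatially
  confounded with development — deliberately, since disentangling such
  predictors is what the box models must do. Canopy tracks forest
  fractions; EVI tracks canopy with monthly perturbations; nighttime LST
  follows an annual cosine (peak near DOY 196) with an elevation lapse and
  per-composite noise; precipitation is lognormal over a long-range field.
- **Truth density.** log density = intercept (5.3) + β-weighted
  standardised predictors + static spatial residual GRF (sd 0.141, range
  25 km) + iid noise (sd 0.141; total noise sd 0.2). Default coefficients:
  skyglow +0.8, canopy +0.3, deciduous (5-km) +0.25, precipitation +0.25,
  evergreen (1-km) +0.2, elevation +0.2, cultivated (5-km) −0.25. Because
  generated fields are not exactly orthogonal, the combined signal is
  rescaled once to sd 1.0 (`signal_sd`); raw-β mode remains for
  variance-addition checks. Fall density is 1.66× spring.
- **Radar forward model.** Airborne density over a pixel is truth density ×
  a logistic take-off curve (station-specific midpoint drawn uniformly in
  [27, 77] min after sunset, scale 12 min) × a per-night lognormal factor
  (sd 0.15), distributed over altitude by a truncated-normal profile
  (mean 500 m, sd 350 m, support 0–2000 m). Voxel η is the Gaussian-beam-
  weighted sample of that column, with multiplicative lognormal voxel noise
  (sd 0.25 in log, mean-corrected) and a −5 dBZ noise floor (floored, not
  missing). dBZ↔linear uses Z = 10^(dBZ/10) with a single fixed η-per-Z
  constant (1.0) stored in config; every check is invariant to its value.
  Contamination: persistent clutter voxels (1% of cells, ~40 dBZ, two
  lowest sweeps), drifting precipitation discs (30% of nights, occasionally
  large enough to trigger scan rejection), optional expanding bat rings.
  January pools contain floor noise, the same clutter, and occasional broad
  weather echoes so clear-scan selection has something to reject.
- **Scan cadence** is fixed at one scan per 10 minutes from sunset to
  +150 min (the operational 5–10 min cadence is hardware-dependent).

### Desk-scale study conditions

512 × 512 km planar domain at 1 km, 9 stations on a 3×3 lattice, 2 years,
2 seasons, 6 sampled nights per season-year (spread evenly over each
93-night window), polar geometry 1° × 500 m to 100 km (the operational
0.5° × 250 m geometry remains the `PolarGeometry` default), 60-scan January
pools, 16 000 sampled locations (~32 000 rows/season), and the 60+15 box
partition. These sizes were chosen once so the full two-season pipeline,
including ensemble training, completes in a few minutes on a single CPU;
`continental_scale()` records the full-scale constants. The nominal-longitude
affine (110°W − 0.0508°/km) places both flyway boundaries inside the
domain.

### What the synthetic world does not establish

The generator emulates spatial autocorrelation, predictor confounding,
measurement noise, contamination, and the take-off dynamics — not real
atmospheres or birds. It has no electromagnetic scattering, no insects, no
velocity products, no real map projections, and its predictor–response link
is log-linear by construction, which flatters any sufficiently flexible
learner. Passing tests therefore demonstrate that the *pipeline* recovers
planted structure through the full measurement chain at the stated noise
levels — not that the ecological findings would replicate on real
archives.

## Known limitations

- The exodus GAM treats dates as fixed intercept offsets rather than true
  random effects; with ≤ 12 nights per station this is the stabler fit.
- VPR estimation inherits beam smoothing; profiles much narrower than the
  beam at 35 km would be over-smoothed and the factor cap does the
  guarding.
- Tree ensembles flatten partial dependence at the sparse extremes of a
  predictor's range, attenuating fitted PDP slopes for heavy-tailed
  predictors; sign-based directionality is unaffected.
- Focal quantiles are exact order statistics per window; the analysis
  driver trades 1-km for 4-km windows for tractability.
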