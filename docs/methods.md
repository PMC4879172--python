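# Methods

`pollenlevels` predicts days with *high* airborne pollen concentration of
hazel (*Corylus*), alder (*Alnus*) and birch (*Betula*) from gridded daily
meteorology, at monitoring stations and across a whole grid. This note
documents the models, the numerical choices, and what the synthetic test
world does and does not show.

## Outcome definition

Daily counts (grains/m³) are dichotomized at symptom-based limits:
35 (hazel), 45 (alder), 20 (birch); a day at or above its limit is high.
The boundary is inclusive because the limits mark first-symptom
concentrations — the limit value itself is already symptomatic.

Each site-year season is delimited by the 99 % method: onset on the first
day cumulative pollen reaches 0.5 % of the annual total, end at 99.5 %.
Crossings are inclusive (first day with cumulative ≥ the percentage); the
convention is configurable because either reading is defensible. Days
missing from a year are treated as zero counts in the cumulative sum and
logged. Per taxon, the union of all site-year seasons (minimum onset to
maximum end, day-of-year, both ends inclusive) fixes the analysis window;
all modeling rows are restricted to it.

## Predictors

Thirty predictors per (location, date):

* 12 monthly mean temperatures of the preceding calendar year. The daily
  mean is `(tmax + tmin)/2` — the gridded source exposes extremes, not a
  dedicated mean field; this is configurable in code.
* 4- and 16-day averages of the seven daily fields (max/min temperature,
  vapor pressure, wind speed, precipitation, potential evaporation, global
  radiation), lagged by one day: the value at day *t* is the mean of days
  *t−k…t−1*. Windows with missing source days propagate the gap (no
  skipping), and rows with any missing predictor are dropped, not imputed;
  complete cases only.
* Cumulative growing degree days lagged by one day. Daily GDD is
  `(tmax + tmin)/2 − 5 °C`, zero when `tmax ≤ 5 °C`, and clamped at zero
  when the daily mean falls below the base (standard GDD practice);
  accumulation restarts every January 1.
* Grid-cell longitude, latitude and altitude.

Stations join to the grid cell with the nearest center by haversine
distance, ties broken toward the lowest row-major cell index.

## Classifier and threshold optimization

A random forest (default 500 trees) classifies each day. The number of
candidate predictors per split (`mtry`) is tuned by repeated stratified
k-fold cross-validation (default 100×10; the test suite and acceptance
script run the desk-scale 5×5 profile, which leaves the selection behavior
intact at a fraction of the cost). Stratification is used because the high
class can be a few percent of rows.

High days are rare, so the default 0.5 cutoff is replaced by an optimized
probability threshold: the pooled out-of-fold probabilities are evaluated
at n evenly spaced cutoffs `i/(n+1)`, i = 1…n (default n = 20, so cutoffs
never reach 0 or 1), and the cutoff minimizing

    distance = sqrt((1−Sens)² + (1−Spec)² + (1−Ppv)² + (1−Npv)²)

is selected (a day is called high when its probability ≥ cutoff). Inside
this distance an undefined Ppv/Npv (no predicted positives/negatives)
counts as 0, penalizing degenerate cutoffs; reporting contexts flag
undefined ratios as NaN instead. Each `mtry` candidate is scored by its
own optimal-cutoff distance — the selection metric and thresholding are
deliberately coupled, since the cutoff is part of the deployed decision
rule (plain CV accuracy is available as an alternative). Ties break toward
the smallest `mtry` and the smallest cutoff, for determinism and
parsimony. The whole training path is reproducible bit-for-bit under a
fixed seed.

Variable importance is the permutation mean decrease in accuracy, averaged
over held-out stratified resamples (3 × 25 % splits, 2 shuffles each).
Probability–predictor profiles are observed-probability curves: the
predictor is binned over its range (default 50 bins) and the mean
predicted probability per bin reported; partial dependence was the
alternative and binning was chosen for its direct data-space reading.

## Evaluation

Rows split three ways: a random two-thirds of the core stations' *dates*
train the model; the remaining dates of the same stations form the
temporal test set; every row of the held-out stations forms the spatial
test set. Splitting at the date level keeps any calendar day on one side
only. Reported metrics: sensitivity, specificity, positive and negative
predictive value, and Cohen's Kappa `(O − E)/(1 − E)` with the expected
accuracy from the marginal products of the confusion matrix. Displayed
values round to two decimals; raw values are retained.

Grid prediction assembles the same 30 predictors for every cell and
applies the fitted forest and optimized cutoff, masking cells whose
lookback (16 prior days or the preceding calendar year) is incomplete.
Rasters are written as NetCDF (time, cell_y, cell_x with lon/lat/alt
coordinates); the domain is the full supplied grid — any geographic
cropping is the caller's concern.

## Synthetic world

The generator emulates the structure of an interpolated 25 × 25 km daily
meteorological product plus Hirst-type station counts:

* **Meteorology.** Each field is a sinusoidal annual cycle (warm-season
  peak at day 196) plus spatially correlated noise (Gaussian-smoothed
  white noise, 3-cell smoothing length, mild temporal persistence).
  Temperatures fall with latitude (0.8 °C/deg) and altitude
  (6.5 °C/km); `tmax ≥ tmin + 0.1 °C` is enforced; precipitation is
  zero-inflated. With noise amplitude 0 the temperature equals its
  closed-form sinusoid exactly, which anchors the tests.
* **Latent truth.** The probability of a high day is
  `(bump × band)^β`: a Gaussian bump in lagged cumulative GDD
  (center/width per taxon) times a soft plateau over the 16-day mean
  potential evaporation (logistic edges, 0.15 mm/day width). Default
  taxon parameters place hazel earliest (GDD ≈ 30), then alder (≈ 45),
  then birch (≈ 150), each co-occurring with its evaporation band in the
  synthetic spring — the qualitative ordering seen in real Betulaceae
  phenology, not a fit to any published optimum.
* **Counts.** Negative binomial (taxon-specific dispersion), with the
  mean solved per day so that P(count ≥ limit) equals the latent
  probability (capped at 0.98, mean capped at the taxon's peak rate).
  Below a 0.005 floor the mean scales down linearly instead — matching
  the tail equation exactly would force several grains per day even in
  deep winter because the overdispersed tail is long — so off-season days
  yield near-zero trace counts and season delimitation stays sharp.
* **Imbalance calibration.** The exponent β is calibrated by bisection so
  the expected high fraction among *analyzed* days hits the configured
  target (defaults 2.5 % hazel, 8 % alder, 17 % birch, the imbalance
  regime of multi-year Polish monitoring). "Analyzed" is anchored by a
  short fixed point: seasons are delimited on expected counts, β is
  recalibrated on the resulting window, three times. Realized fractions
  land within a few tenths of the target and are monotone in it.

Stored truth makes recovery tests direct: the generative GDD feature is
also a model predictor, so a working pipeline must rank it highly and
place the probability-profile peak inside the generative bump.

What the synthetic world does **not** contain: atmospheric dispersion and
long-range transport, urban heat islands, inter-annual phenology shifts
beyond what the weather noise induces, observation error of volumetric
traps, and irregular station histories. Passing tests therefore show the
pipeline recovers known structure under realistic imbalance and noise —
not that the fitted synthetic models transfer to real monitoring data.

## Problem sizes

The default world is a 12 × 10 grid, four generated years (the first is
burn-in for preceding-year features), 11 stations (8 core + 3 holdout).
Desk-scale training uses 5 × 5 repeated CV over the `mtry` grid
{2, 5, 10, 30}; a full pipeline run takes a few minutes on one CPU. The
test fixtures use a 6 × 5 grid with five stations.

## Known limitations

* GeoTIFF export is not built in; rasters are NetCDF (classic format).
* The probability-threshold grid never includes 0 or 1, so an
  all-high/all-low decision rule cannot be selected — intended, but worth
  knowing when n_thresholds is tiny.
* Kappa is NaN when the expected accuracy is 1 (single-class truth and
  prediction).
* Calibration clamps β (with a warning) for targets unreachable within
  the latent family, e.g. a 45 % target on a sharply seasonal taxon.
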