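# Methods and design notes

## Scope and data model

The package treats one fixed raster (projected metric coordinates, square
pixels, origin at the lower-left corner) as the common frame for terrain
covariates, daily temperature fields and phenology maps.  Daily sensor data
live in a long table `(sensor_id, date, variable ∈ {tn, tx}, value, source,
qc)`; the daily mean `tm = (tn + tx) / 2` is always derived, never stored,
so it can never drift out of sync with the extremes.

## Daily extremes from hourly records

Daily minima and maxima use asymmetric windows that follow the diurnal
cycle rather than the civil day: `Tn(d) = min` over `[d−1 18:00, d 19:00]`
and `Tx(d) = max` over `[d 06:00, d+1 07:00]`.  A day with any window hour
missing is emitted with `qc = suspect` (its value uses whatever hours
exist) and excluded from clean tables.  The synthetic hourly emitter is a
piecewise cosine anchored at the daily minimum at 06:00 and maximum at
15:00; it reproduces the daily extremes exactly when day-to-day changes are
moderate, which is the regime the tests use.

## MAD screening

For each day and variable, all probe values across the network are pooled;
with daily median m and `MAD* = 1.4826 · median|x − m|`, a value is deleted
iff `|x − m| > k · MAD*`.  The 1.4826 factor makes MAD a consistent
estimator of the standard deviation under normality; `k = 3` (a
conventional robust-rejection multiplier) is exposed in `QCConfig`.  Days
with fewer than 5 reporting sensors, and degenerate days with `MAD* = 0`
despite non-identical values, pass everything with a logged warning.

Two properties of this day-wise robust screen are worth stating plainly:

- With any continuous spatial spread there is an irreducible false-deletion
  floor (≈ 0.3 % at k = 3 for normal-like deviations); an exact
  "defect-free data pass untouched" no-op holds only when the network's
  daily deviations are degenerate (e.g. spatially uniform fields).
- The screen is not exactly idempotent: re-screening survivors recomputes
  narrower bounds on heavy-tailed days, so iterated application contracts
  the tails.  Probe merging and gap filling are idempotent.

Detection is intrinsically hardest on clear-calm nights, when genuine
spatial deviations (valley sensors 4–5 °C below the network median) are of
the same order as the smallest injected spikes: a spike of +8 °C on a −5 °C
valley sensor lands back inside the bounds.  Measured over many simulated
years at default conditions the screen catches ≈ 96 % of ≥ 8 °C spikes at a
≈ 0.3 % false-deletion rate.

## Eligibility and gap filling

A sensor-year is eligible for filling iff its missing fraction is strictly
below 30 % over the calendar year AND strictly below 20 % over the growing
season (Apr 1–Sep 30), evaluated per variable and combined by worst case.
Filling is additive network-deviation: `δ = mean over observed days of
(sensor − mean of all other reporting sensors)`, and each missing day gets
`mean(others that day) + δ`.  The additive (°C offset) form was chosen over
a multiplicative ratio because temperature is interval-scaled — ratios are
not invariant under the arbitrary zero of the Celsius scale.  δ uses all
observed days of the year, not only days adjacent to the gap.  Filled rows
are flagged `source = "filled"`: all index computations may use them, but
spatial-model training never does (an interpolated value carries no
independent information about the local deviation), and the daily
spatial-amplitude statistic excludes them because network-derived fills
would shrink the range artificially.

## Indices

CWI accumulates `max(Tm − 10, 0)` over Apr 1–Oct 31 (214 days in any year;
the leap day falls outside the window).  Missing days inside the window
contribute zero degree-days and are counted in the output rather than
interpolated, so callers can reject badly covered sensor-years; the
eligibility rule plus a 95 % coverage default keep this error small.  CWI
uses raw canopy temperatures (it is defined as a canopy index); only the
phenology model consumes corrected ones.

## Station bias correction

One OLS model per variable, `station = slope · canopy + intercept`, fitted
on paired same-day QC-passed values (≥ 30 required).  Direction: canopy is
the predictor because the goal is to express canopy series on the station
scale, where the published phenology thresholds were calibrated.  A single
global model is used despite a visible seasonal structure in the Tx
differences; a per-month variant would be a straightforward extension but
the single affine map is already sufficient for day-level phenology (the
end-to-end test shows ≤ 1 day of drift at 0.3 °C station noise).

## GFV thermal-time model

`S(d) = Σ_{doy=60}^{d} max(Tm, 0)`; a stage is declared on the smallest d
with `S(d) ≥ F*` (Merlot: flowering 1269 dd, véraison 2636 dd).  The start
day is inclusive — with a constant 20 °C series the 64th accumulation day,
DOY 123, is the flowering date.  Accumulation starts at DOY 60 in leap
years too; daily resolution, no sub-daily interpolation of the crossing;
unreached thresholds yield "absent", not an error.  Budbreak is stored from
observations but never predicted (no threshold exists for it in this model
family).

## Spatial mapping

Support-vector regression with a Gaussian kernel, one independent model per
day and variable, on the six covariates standardized with the training
sensors' statistics.  Hyperparameters: C = 10, ε = 0.1 °C, kernel width
from the median pairwise-distance heuristic in standardized space — all
overridable, with a leave-one-sensor-out CV helper for tuning.  Slope is in
percent from a Horn 3×3 stencil (edge pixels replicate the nearest interior
value); aspect is the downslope azimuth from north, decomposed as
northness = cos(aspect), eastness = sin(aspect), zero on flat pixels.
Sensor-to-pixel extraction is nearest-pixel with boundary ties broken
toward the lower index.

Seasonal maps average the daily predicted maps (daily-then-average);
pixel-wise CWI accumulates degree-days from the Tm of the corrected daily
map pair, and is tested to agree exactly with the series-level index run on
any pixel's extracted series.  Phenology maps apply the bias correction to
each day's Tn/Tx maps, form Tm, and run the threshold crossing per pixel;
pixels that never reach a threshold are flagged absent and excluded from
multi-year averages.

Per-day driver attribution is OLS on the standardized covariates with
variance shares by sequential sums of squares in the fixed order elevation,
slope, northness, eastness, x, y (shares then add up to the model R²);
signs come from the full model.  Sequential partitioning depends on the
order; elevation first reflects its expected dominance.

## The synthetic scene

The generator emulates the study conditions, not the physics:

- **Terrain**: a Gaussian random field, smoothed and pushed through a
  sigmoid, giving ~100 m limestone-like plateaus over ~2 m valley floors.
  Desk-scale grids (40×40 at 25 m) compress horizontal distances, so
  synthetic flank slopes run steeper than a real site's.
- **Weather**: each day is `clear_calm`, `cloudy` or `windy`
  (p = 0.40/0.35/0.25) with an `amplitude_scale` drawn per regime
  (clear 0.7–1.3, cloudy 0.08–0.25, windy 0.30–0.65); regional Tn/Tx follow
  a temperate-maritime annual cycle with AR(1) synoptic noise.
- **Fields**: `regional + amplitude_scale · (Σ wᵢ·covᵢ + smooth noise)`.
  The elevation weight for Tn is positive on clear-calm days (cold-air
  pooling) and negative on cloudy days (lapse rate); Tx keeps a negative
  elevation weight in all regimes.  Weights were calibrated once so the
  network's daily Tn amplitude distribution matches the observed one —
  mean ≈ 3.7 °C, extremes ≈ 10 °C on strong clear-calm nights, ≈ 1.3 °C on
  overcast days — and not revisited.
- **Defects**: two probes per shield with independent N(0, 0.2 °C) noise;
  1 % of sensor-day-variables get a ±8–12 °C spike on one probe; 2 % of
  sensor-days are withheld entirely.  Every defect is logged exactly once.
- **Station**: `slope · canopy_pixel + intercept + N(0, 0.3 °C)` with
  default intercepts +0.2 °C (tn) and −1.2 °C (tx), i.e. canopy maxima read
  well above the station and minima slightly below.
- **Phenology**: true stage dates run the same threshold rule on each
  sensor pixel's Tm series — by default on the station-scale transform of
  it, since the published thresholds are station-calibrated and the
  synthetic "biology" should live on that scale; observation noise is
  rounded Gaussian with per-stage sd 2.2 d (flowering) and 3.6 d
  (véraison).

What the generator does **not** emulate: atmospheric physics, advection or
fronts crossing the domain within a day, sensor drift or step changes,
rivers/urban heat effects, and any real geography.  Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline under
a plausible spatial-temperature model — not meteorological realism.  The
smooth spatial-noise scale is a free knob, not a calibrated quantity.

## Numerical choices and degenerate inputs

- Randomness flows from a single seed through `numpy.random.SeedSequence`;
  regeneration is bit-identical.
- The SVR solver's predictions are order-sensitive at the 10⁻³ °C level
  (libsvm working-set order); permutation invariance is asserted at that
  tolerance.
- Zero-variance covariate layers standardize to zeros; rank-deficient OLS
  designs raise, naming the collinear columns.
- A point exactly on a pixel boundary extracts the lower-index pixel.
- Empty index windows raise `UndefinedResultError`; unreached thermal
  thresholds are absent values, not errors.

## Problem sizes

Tests and drivers run at desk scale — 20×20 to 40×40 pixel grids, 12–25
sensors, one to three years — chosen as the smallest sizes at which every
network-level behaviour (MAD screening across regimes, eligibility, SVR
mapping, map/point phenology equivalence) is exercised meaningfully.  The
emulated full deployment (90 sensors, ~720×760 pixels, seven years) runs
through the identical code paths.
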