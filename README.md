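# vineclim

Local-scale vineyard temperature analysis: from a dense network of in-canopy
temperature sensors to daily temperature maps and vine-phenology maps.

Winegrowing regions have strong temperature structure at the kilometre
scale — on clear, calm (anticyclonic) nights cold air drains into valleys
and nightly minima can differ by ~10 °C across a single appellation, while
overcast days flatten the field to ~1 °C.  This package implements the full
chain needed to quantify that structure from a sensor network and turn it
into phenology predictions:

1. **QC and gap filling** of dual-probe daily records: per-day outlier
   rejection by median absolute deviation (MAD × 1.4826, k = 3 robust
   sigmas), probe merging, a strict missingness rule (< 30 % of the year and
   < 20 % of the Apr–Sep growing season), and network-deviation gap filling.
2. **Bioclimatic indices**: the canopy Winkler index
   CWI = Σ_{Apr 1}^{Oct 31} max(Tm − 10 °C, 0) with Tm = (Tn + Tx)/2,
   growing-season means, and the daily spatial amplitude max − min across
   the network.
3. **Bias correction**: per-variable OLS `station = a·canopy + b`, mapping
   canopy series onto the weather-station scale on which phenology models
   are calibrated.
4. **Thermal-time phenology (GFV)**: a stage occurs on the first day d with
   Σ_{doy=60}^{d} max(Tm, 0) ≥ F\*, with Merlot thresholds F\* = 1269
   degree-days (mid-flowering) and 2636 (mid-véraison).
5. **Spatial mapping**: one Gaussian-kernel support-vector regression per
   day and variable on six terrain covariates (elevation, slope %,
   northness, eastness, x, y), aggregated into seasonal and Winkler maps and
   coupled pixel-wise to the GFV rule to map stage dates.

Because network datasets of this kind are not public, the package ships a
first-class synthetic-scene generator (`vineclim.synth`) that emulates the
deployment — plateau/valley terrain, weather-regime-dependent spatial
structure, dual probes with injected spikes and gaps, a biased reference
station, noisy phenology observations — with a complete truth ledger, so
every stage is tested against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
scene (40×40 pixels at 25 m, 25 sensors, one year):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_qc.py
python analysis/03_indices.py
python analysis/04_bias_correction.py
python analysis/05_phenology.py
python analysis/06_maps.py
python analysis/07_pheno_maps.py
```

which prints (seed 1):

```
true Tn spatial amplitude: mean 3.7 degC, max 9.8 degC
MAD screen vs truth: recall 0.914, false-deletion rate 0.0015
CWI over 25 sensor-years: mean 1440 dd, spatial spread (max-min) 199 dd
tn: station = 0.995 x canopy +0.29 (r2 0.990, rmse 0.52 degC, n 365, ...)
tx: station = 0.995 x canopy -1.16 (r2 0.997, rmse 0.41 degC, n 365, ...)
flowering: RMSE 2.2 days, bias +0.4 days (n=25)
veraison: RMSE 3.5 days, bias +0.2 days (n=25)
largest-amplitude Tn day 2018-09-14: elevation explains 82.0% of variance (sign +)
smallest-amplitude Tn day 2018-02-26: elevation explains 50.5% of variance (sign -)
flowering: map RMSE 2.3 days (accuracy loss vs point prediction +0.1 days)
veraison: map RMSE 3.3 days (accuracy loss vs point prediction -0.1 days)
```

Reading this: the generated network shows the expected amplitude climate
(mean ~4 °C, extreme clear-calm nights near 10 °C); the MAD screen catches
injected ≥ 8 °C spikes while deleting ≈ 0.2 % of genuine values; the fitted
station correction recovers the planted bias (canopy maxima read ~1.2 °C
above the station, minima slightly below); thermal-time predictions land
within 2–4 days RMSE of the noisy observations; the per-day OLS attribution
shows the elevation driver flipping sign between clear-calm and overcast
days; and phenology dates extracted from the daily maps validate as well as
the direct per-sensor predictions (no accuracy loss from the spatial
modelling).

Outputs (CSV tables, JSON reports, ASCII-grid rasters) land under
`results/`.

## Layout

```
src/vineclim/       library: synth/, qc, bioclim, bias, gfv, mapping,
                    pipeline, evaluation, grids
analysis/           numbered narrative drivers (simulate → qc → ... → maps)
scripts/            acceptance.py
tests/              pytest suite (unit, property-based, end-to-end)
docs/methods.md     model and design notes
```
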