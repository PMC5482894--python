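# Methods

This note documents the models implemented in `grasstrend`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Field survey aggregation

Narrow-band NDVI uses the reflectances at exactly 680 nm (red) and 800 nm
(near infrared); the spectrometer delivers 1 nm resolution, so no band
averaging or interpolation is applied. A plot's NDVI and AGB are arithmetic
means over its quadrats; quadrats that carry a biomass weight but no
spectrum enter the AGB mean only. A plot with no spectra at all has
*undefined* NDVI (`None`), never a zero fill, so downstream fits cannot
silently absorb missing optics.

## Regression families and selection

All four families (linear, exponential, logarithmic, power) are scored by
R² = 1 − SS_res/SS_tot and RMSE = √(SS_res/n) **on the original response
scale**, which keeps the metrics comparable across families; fitting the
nonlinear families by transform-then-OLS would instead minimise error on the
log scale. Exponential and power fits therefore use nonlinear least squares
(Levenberg–Marquardt via `scipy.optimize.curve_fit`), initialised from the
log-transform closed form; when the response contains non-positive values
the initialiser falls back to a flat model (a = mean(y), b = 0). RMSE uses
divisor n (`ddof=0` default, configurable): with only two parameters and
survey-scale n the difference from n−p is immaterial, and n keeps RMSE equal
to the RMS residual. Selection is by maximal R², ties broken by minimal
RMSE, then by a simplicity order (linear < power < exponential < log);
exact ties essentially occur only on noiseless data.

## Calibration direction

Field NDVI is the response and satellite NDVI the predictor, so applying the
fitted model to a satellite raster yields calibrated, field-equivalent NDVI
— the only direction consistent with using the model to *correct* satellite
values. Output is clipped to the definitional NDVI range [−1, 1]. One
pooled model is fitted by default; per-type models are available
(`by_type=True` / `--by-type`) but a single raster can only be transformed
with the pooled model unless a type-resolved archive is supplied.

## AGB estimation and quality flags

Each grassland type has its own NDVI→AGB model because meadow and steppe
differ in structure, height and composition. Two conditions are converted
but flagged in a QA band rather than silently accepted: calibrated NDVI
above 0.8 (outside the surveyed range, where the index saturates) and
negative predictions at very low NDVI (floored at 0 — biomass cannot be
negative). Non-positive NDVI is treated as bare ground (0 kg/hm², flagged).

The flower-sensitivity refit excludes plots with large-flower coverage
above a threshold (default 20 %) and refits both types. Bright flowers on
top of the canopy inflate measured NDVI while the clip harvest includes
their biomass; contaminated plots therefore sit off the grass NDVI–AGB
relation, and comparing the all-plots model with the refit bounds the
resulting bias.

## Compositing and aggregation

The annual composite takes the per-pixel maximum over each year's non-nodata
layers (the classical maximum value composite, which suppresses cloud and
atmospheric depressions of the index); it is idempotent on annual stacks.
Spatial aggregation is block arithmetic mean by default (max and median are
options): the quantities mapped here are averages, so the mean is the
conservative choice, and factor-f aggregation rescales the affine transform
accordingly. Edge blocks use the cells available; all-nodata blocks stay
nodata. Rasters use NaN nodata in memory and are written as multi-page TIFF
with GeoTIFF pixel-scale/tiepoint tags, a GDAL nodata tag and a JSON
description carrying time labels, so outputs open in standard GIS tooling.

## Trend slopes and classes

The per-pixel trend is the OLS slope of annual AGB on the year index
i = 1..n, computed in closed sum form (algebraically identical to
cov(i, AGB)/var(i); the index origin is irrelevant to the slope). Slopes
are binned into four classes by half-open intervals at ±10 kg·hm⁻²·yr⁻¹:
(−∞, −10), [−10, 0), [0, 10), [10, ∞). **"Significant" here is a magnitude
convention, not a statistical test** — no p-values are computed. The
threshold is configurable. Default nodata policy: a pixel with any missing
year is masked; a pairwise-complete mode recomputes the sums over available
years.

## Rescaled-range analysis

For window length τ the series is cut into ⌊n/τ⌋ consecutive non-overlapping
windows (trailing remainder discarded). Per window: subtract the window
mean, accumulate the deviations, take R = max − min of the cumulative sums
and S = the population standard deviation (divisor τ); windows with S = 0
are skipped. (R/S)τ is the mean over windows, and H is the OLS slope of
log (R/S)τ on log τ (natural log; the base cancels in the slope).

Default τ grids: every integer from 4 to ⌊n/2⌋ plus n itself for long
series; the sparse grid {3, 4, 6, 12, 13} ∩ [2, n] for short annual series
(n < 16), whose members divide 12/13 almost evenly so most windows are
full-length. Classification: H > 0.5 persistent ("sustainable" trend),
H < 0.5 anti-persistent, H = 0.5 memoryless; an optional tolerance band
around 0.5 widens the "random" class (default 0, the strict rule).

Classical R/S is biased upward in small samples (the expected white-noise
R/S is above the asymptotic √τ law at small τ). An optional Anis–Lloyd
correction subtracts the log-log slope of the expected white-noise R/S on
the same grid; it is **off by default** since the basic estimator is the
reference procedure here. With only 13 annual values any R/S estimate has
large variance — map-scale summaries (fractions of pixels above 0.5) are
more meaningful than single-pixel values, and the recovery tests therefore
use longer synthetic series (256–1024 steps) to validate the estimator
itself.

## Future-dynamics classes

Persistent pixels keep their trend class (4 "sustainable ×" classes);
anti-persistent pixels are "uncertain" regardless of trend. Pixels with H
exactly 0.5 get their own "random uncertain" class for completeness — a
measure-zero event on real data — and a strict reporting mode collapses it
into the anti-persistent class for comparison with four-plus-one schemes.
"Improvement" aggregates the two sustainable increase classes,
"degradation" the two sustainable decrease classes; percentages are over
non-nodata grassland pixels and sum to 100 across the six classes.

## Synthetic data: what it emulates

**Survey.** 31 meadow + 33 steppe plots, nine quadrats each. Plot NDVI is
uniform within type ranges (meadow 0.52–0.78, steppe 0.08–0.48: meadow
above 0.5, steppe below, nothing above 0.8, matching the surveyed
separation), with quadrat-level jitter (sd 0.02). AGB follows a linear law
for meadow (a = 56.7, b = 1000) and a power law for steppe (a = 4390,
b = 1.8), scaled so the nominal type means sit at ≈706.7 and ≈498.7 kg/hm²,
with additive Gaussian noise (sd 80 meadow, 145 steppe, the steppe value
sized to the reported residual scale) floored at 0. The floor truncates the
noise on low-biomass steppe plots, so the *realized* steppe mean runs
somewhat above the nominal 498.7 — a deliberate price for keeping biomass
non-negative. Spectra are built by fixing R₈₀₀ = 0.5 and solving the NDVI
formula for R₆₈₀ (re-anchoring on R₆₈₀ when infeasible), so
`compute_narrowband_ndvi` inverts the construction exactly. Satellite NDVI
is a + b·field + noise with a = 0.05, b = 1.1, sd 0.02 — satellite running
higher than field, as broadband red/NIR windows do against 680/800 nm
narrow bands. A configurable fraction (default 13 %) of meadow plots is
flower-contaminated: measured NDVI shifted by +0.05 (capped at 0.8), AGB
increased by the flowers' clipped biomass (default +150 kg/hm², enough to
dominate the slope × shift ≈ 50 kg/hm² displacement so contaminated plots
sit *above* the clean relation), and flower coverage drawn above the 20 %
threshold.

**Stacks.** Pixel series are baseline + trend·i + innovation_sd·fGn(H),
with per-pixel trends constant or Gaussian and fGn generated exactly by
circulant embedding of the fGn autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) (Davies–Harte; an exact
O(n²) Cholesky construction is the fallback if the embedding is numerically
non-positive-definite, which does not occur for H ∈ (0,1) at these sizes).
Trend and noise are additive and independent. The optional 16-day mode
emits 23 within-year layers dipping below the annual value with the
mid-season layer equal to it exactly, so the maximum value composite
recovers the annual truth bit-for-bit.

**What passing tests do not show.** The generator has no spatial
correlation, no cloud artifacts, no mixed pixels, no NDVI saturation
dynamics, and its trend+fGn decomposition is an idealisation: recovery
results validate the estimators' correctness and calibration under their
own assumptions, not the accuracy of AGB mapping on any real landscape.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by choice: grids of
15×15–50×50 pixels, 13–256 annual steps, 50-replicate Monte Carlo for
estimator calibration — large enough for the stated tolerances (3 standard
errors for recovered coefficients, ±0.1 for mean Hurst estimates, ≥80 %
map-scale classification rates) while keeping the whole suite fast.
Floating-point specifics: NaN is the universal nodata; aggregation
conserves a nodata-free global mean to 1e−10; the sum-form slope matches a
generic OLS fit to 1e−9; NDVI clipping bounds calibrated output at ±1.
Determinism: every stochastic operation takes a seed (NumPy `default_rng`),
and a full pipeline rerun with the same config writes byte-identical
artifacts (TIFF output carries no timestamps).

## Known limitations

- R/S Hurst estimates from 13-point series are indicative at best; the
  package exposes the map-scale fractions rather than pretending per-pixel
  precision.
- The ±10 trend thresholds are in absolute kg·hm⁻²·yr⁻¹ and should be
  revisited when the AGB scale differs from alpine-grassland magnitudes.
- One pooled calibration is applied to all pixels; biome- or season-specific
  calibration would need paired data stratified accordingly.
- The type map is assumed static over the analysis period.
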