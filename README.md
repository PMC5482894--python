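# grasstrend

Spatiotemporal analysis of grassland aboveground biomass (AGB) from
calibrated satellite NDVI time series, for remote-sensing ecologists who
work with plot surveys and vegetation-index archives.

The pipeline covers the full chain from field spectra to a future-dynamics
map:

1. **Field NDVI.** Narrow-band NDVI from handheld-spectrometer canopy
   reflectance, `NDVI = (R₈₀₀ − R₆₈₀) / (R₈₀₀ + R₆₈₀)`, averaged over the
   nine 1 m × 1 m quadrats of each plot together with clip-harvested AGB
   (kg/hm²).
2. **Calibration.** Satellite NDVI is regressed against field NDVI with four
   candidate families — linear `y = a + bx`, exponential `y = a·e^{bx}`,
   logarithmic `y = a + b·ln x`, power `y = a·x^b` — and the best model by
   R² (ties: RMSE, then simplicity) converts satellite rasters to
   field-equivalent NDVI.
3. **AGB models.** The same four families map field NDVI to AGB separately
   for meadow and steppe grasslands, with a sensitivity refit that drops
   plots whose large-flower coverage exceeds 20 % (flowers inflate NDVI and
   add clipped biomass).
4. **Compositing.** 16-day NDVI stacks are reduced to annual maxima
   (maximum value composite) and optionally block-mean aggregated (e.g.
   1 km → 10 km).
5. **Trend.** Per-pixel OLS slope of annual AGB on the year index
   `i = 1..n`,

   ```
   slope = (n Σ i·AGBᵢ − Σ i Σ AGBᵢ) / (n Σ i² − (Σ i)²)
   ```

   classified as significant/non-significant decrease/increase with ±10
   kg·hm⁻²·yr⁻¹ magnitude thresholds.
6. **Persistence.** Rescaled-range analysis per pixel: for window lengths τ
   the mean rescaled range (R/S)τ follows `log(R/S)τ = a + H·log τ`; the
   Hurst exponent H > 0.5 marks a persistent (trend-sustaining) series,
   H < 0.5 an anti-persistent one.
7. **Future classes.** Sustainable pixels keep their trend class; anti-
   persistent pixels are "uncertain". Class area percentages are reported
   overall and per grassland type.

A synthetic-data module generates every input the pipeline needs — plot
surveys with invertible spectra, paired field/satellite NDVI, and raster
stacks with prescribed per-pixel trend and Hurst structure (exact fractional
Gaussian noise via circulant embedding) — so the whole chain is testable
without satellite downloads.

## Worked example

```python
from grasstrend import (SurveyConfig, simulate_survey, fit_calibration,
                        fit_agb_models, StackConfig, simulate_stack,
                        trend_map, hurst_map)
import numpy as np

survey = simulate_survey(SurveyConfig(seed=7))      # 31 meadow + 33 steppe plots
calib = fit_calibration(survey.plots)
print(f"calibration: field = {calib.a:+.4f} + {calib.b:.4f} * satellite "
      f"({calib.family.value}, R^2 = {calib.r_squared:.3f})")

models = fit_agb_models(survey.plots)
print(f"steppe AGB model: {models.steppe.family.value}, "
      f"a = {models.steppe.a:.1f}, b = {models.steppe.b:.3f}, "
      f"R^2 = {models.steppe.r_squared:.2f}")

stack = simulate_stack(StackConfig(n_rows=25, n_cols=25, n_years=13,
                                   trend_mean=2.0, trend_sd=8.0,
                                   hurst_target=0.7, innovation_sd=25.0,
                                   seed=7))
trend = trend_map(stack.stack)
hurst = hurst_map(stack.stack)
inc = trend.class_fractions["nonsig_increase"] + trend.class_fractions["sig_increase"]
print(f"pixels with increasing AGB: {100*inc:.1f}%")
print(f"pixels with H > 0.5: {100*hurst.fraction_sustainable:.1f}% "
      f"(mean H = {np.nanmean(hurst.h):.2f})")
```

prints

```
calibration: field = -0.0485 + 0.9120 * satellite (linear, R^2 = 0.994)
steppe AGB model: power, a = 4187.3, b = 1.759, R^2 = 0.98
pixels with increasing AGB: 55.8%
pixels with H > 0.5: 95.7% (mean H = 0.83)
```

The calibration recovers (the inverse of) the generator's linear
field→satellite map; the steppe fit recovers the generating power law
(a = 4390, b = 1.8) within sampling noise; and a stack built with mean
slope +2 and H\* = 0.7 yields mostly increasing, strongly persistent pixels.
Note that at 13 annual values the classical R/S estimate of H is biased and
noisy — mean H here reads 0.83 for a generating 0.7 — which is a property
of short-series R/S analysis, not of the simulation.

The same analysis runs from the shell:

```bash
grasstrend simulate survey --out-dir data/survey --seed 7
grasstrend simulate stack --out data/ndvi.tif --types data/types.tif --seed 7
grasstrend run --config run.yaml     # survey -> calibration -> AGB -> trend ->
                                     # Hurst -> future map + fractions.csv
```

`run.yaml` names the plot table, NDVI stack, type raster and output
directory; every intermediate (calibration and AGB models as JSON, annual
AGB stack, slope/class/Hurst/future rasters, class-fraction report, run
manifest) is written to the output directory, deterministically for a fixed
config.

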