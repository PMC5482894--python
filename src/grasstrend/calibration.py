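"""Calibration of satellite NDVI against field-spectrometer NDVI.

Handheld-spectrometer NDVI is treated as the reference: the regression uses
satellite NDVI as the predictor and field NDVI as the response, so applying
the fitted model to a satellite raster yields calibrated, field-equivalent
NDVI. All four regression families are tried and the best (by R^2, then
RMSE) is kept; in practice the relationship is close to linear.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .errors import DomainError, GrasstrendError
from .field_survey import GrasslandType, PlotRecord
from .rasters import RasterStack
from .regression import RegressionModel, fit_all_families, predict, select_best


def fit_calibration(
    plots: Sequence[PlotRecord], by_type: bool = False
) -> RegressionModel | dict[GrasslandType, RegressionModel]:
    """Fit field NDVI = f(satellite NDVI) over plots with paired values.

    With ``by_type=True`` returns one model per grassland type.
    """
    if by_type:
        return {
            gt: fit_calibration([p for p in plots if p.grassland_type == gt])
            for gt in GrasslandType
        }
    missing = [
        p.plot_id
        for p in plots
        if p.modis_ndvi is None or p.mean_field_ndvi is None
    ]
    if missing:
        raise GrasstrendError(
            f"plots lacking paired NDVI values: {missing[:10]}"
        )
    if len(plots) < 3:
        raise GrasstrendError("need at least 3 paired plots for calibration")
    x = np.array([p.modis_ndvi for p in plots])
    y = np.array([p.mean_field_ndvi for p in plots])
    return select_best(fit_all_families(x, y))


def apply_calibration(stack: RasterStack, model: RegressionModel) -> RasterStack:
    """Apply the calibration per pixel; output clipped to [-1, 1], nodata
    (NaN) propagated unchanged."""
    values = stack.values
    mask = np.isnan(values)
    out = np.full_like(values, np.nan)
    valid = values[~mask]
    try:
        calibrated = predict(model, valid)
    except DomainError as exc:
        n_bad = int(np.sum(valid <= 0))
        raise DomainError(
            f"calibration model domain violated at {n_bad} valid pixels"
        ) from exc
    out[~mask] = np.clip(calibrated, -1.0, 1.0)
    return replace(stack, values=out)
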