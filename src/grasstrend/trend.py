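"""Per-pixel linear trend of annual AGB and the four-class trend scheme.

The trend statistic is the ordinary-least-squares slope of AGB on the year
index i = 1..n, computed from the sum form

    slope = (n * sum(i*AGB_i) - sum(i) * sum(AGB_i))
            / (n * sum(i^2) - (sum(i))^2)

in the units of the stack variable per year (kg/hm^2 yr^-1 for AGB). Slopes
are classified into four levels by magnitude thresholds (default +-10):

    slope <  -t   significant decrease
    -t <= s < 0   non-significant decrease
    0 <= s <  t   non-significant increase
    s >= t        significant increase

"Significant" here follows the magnitude convention of the classification
scheme, not a statistical test.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import GrasstrendError
from .rasters import RasterStack


class TrendClass(IntEnum):
    SIG_DECREASE = 1
    NONSIG_DECREASE = 2
    NONSIG_INCREASE = 3
    SIG_INCREASE = 4


def pixel_slope(series) -> float:
    """OLS slope of one pixel's series against the year index 1..n."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise GrasstrendError("need a 1-D series of length >= 2")
    if np.any(np.isnan(series)):
        return float("nan")
    n = len(series)
    i = np.arange(1, n + 1, dtype=float)
    num = n * np.sum(i * series) - i.sum() * series.sum()
    den = n * np.sum(i**2) - i.sum() ** 2
    return float(num / den)


def slope_map(stack: RasterStack, nodata_policy: str = "strict") -> np.ndarray:
    """Vectorised per-pixel slope over an annual stack.

    ``strict``: any nodata year makes the pixel nodata. ``pairwise``: the
    sums are taken over the available years only (n adjusted per pixel).
    """
    v = stack.values
    n, nr, nc = v.shape
    if n < 2:
        raise GrasstrendError("need at least 2 annual layers for a trend")
    i = np.arange(1, n + 1, dtype=float)[:, None, None]
    if nodata_policy == "strict":
        valid = ~np.any(np.isnan(v), axis=0)
        num = n * np.sum(i * v, axis=0) - i.sum() * np.sum(v, axis=0)
        den = n * np.sum(i**2) - i.sum() ** 2
        slope = num / den
        slope[~valid] = np.nan
        return slope
    if nodata_policy == "pairwise":
        m = ~np.isnan(v)
        cnt = m.sum(axis=0).astype(float)
        vi = np.where(m, v, 0.0)
        iw = np.where(m, i, 0.0)
        si = iw.sum(axis=0)
        sii = (iw**2).sum(axis=0)
        sv = vi.sum(axis=0)
        siv = (iw * vi).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = (cnt * siv - si * sv) / (cnt * sii - si**2)
        slope[cnt < 2] = np.nan
        return slope
    raise GrasstrendError(f"unknown nodata policy '{nodata_policy}'")


def classify_trend(slope, threshold: float = 10.0):
    """Map slopes to the four trend classes (half-open intervals).

    Accepts a scalar (returns TrendClass) or an array (returns uint8 codes,
    0 where slope is nodata).
    """
    arr = np.asarray(slope, dtype=float)
    codes = np.zeros(arr.shape, dtype=np.uint8)
    codes[arr < -threshold] = TrendClass.SIG_DECREASE
    codes[(arr >= -threshold) & (arr < 0)] = TrendClass.NONSIG_DECREASE
    codes[(arr >= 0) & (arr < threshold)] = TrendClass.NONSIG_INCREASE
    codes[arr >= threshold] = TrendClass.SIG_INCREASE
    if np.isscalar(slope) or arr.ndim == 0:
        if np.isnan(arr):
            raise GrasstrendError("cannot classify a non-finite slope")
        return TrendClass(int(codes))
    return codes


@dataclass
class TrendResult:
    slope: np.ndarray  # float, NaN nodata
    trend_class: np.ndarray  # uint8 codes, 0 nodata
    n_years: int
    class_fractions: dict  # TrendClass name -> fraction of valid pixels


def trend_map(
    stack: RasterStack, threshold: float = 10.0, nodata_policy: str = "strict"
) -> TrendResult:
    """Slope raster + class raster + class area fractions for an annual stack."""
    slope = slope_map(stack, nodata_policy=nodata_policy)
    classes = classify_trend(slope, threshold=threshold)
    valid = int(np.sum(classes > 0))
    fractions = {
        tc.name.lower(): (float(np.sum(classes == tc)) / valid if valid else 0.0)
        for tc in TrendClass
    }
    return TrendResult(
        slope=slope,
        trend_class=classes,
        n_years=stack.values.shape[0],
        class_fractions=fractions,
    )
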