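"""Georeferenced raster stacks: I/O, annual maximum-value compositing, and
block-mean spatial aggregation.

Conventions
-----------
* values are float arrays indexed (time, row, col); nodata is NaN.
* row 0 is the northern edge; pixel indices are 0-based.
* the affine georeference follows the GDAL/rasterio convention:
  x = c + a*col + b*row,  y = f + d*col + e*row  (e is negative for
  north-up grids).
* time labels are either plain integer years (annual stacks) or
  (year, period) pairs (multi-composite stacks, e.g. 16-day steps).

Files are written as multi-page TIFF with GeoTIFF ModelPixelScale /
ModelTiepoint tags, a GDAL_NODATA tag, and a JSON image description that
carries the time labels and variable name, so outputs open in GIS tooling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import tifffile

from .errors import GrasstrendError, GridMismatchError


class Affine(NamedTuple):
    """GDAL-style affine transform (a, b, c, d, e, f)."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def identity(cls) -> "Affine":
        return cls(1.0, 0.0, 0.0, 0.0, -1.0, 0.0)

    def rescaled(self, factor: int) -> "Affine":
        return Affine(
            self.a * factor, self.b, self.c, self.d, self.e * factor, self.f
        )


def _label_year(label) -> int:
    if isinstance(label, (tuple, list)):
        return int(label[0])
    return int(label)


@dataclass
class RasterStack:
    """A (time, row, col) array of NDVI or AGB values with NaN nodata."""

    values: np.ndarray
    times: list
    transform: Affine = field(default_factory=Affine.identity)
    variable: str = "ndvi"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[np.newaxis]
        if self.values.ndim != 3:
            raise GrasstrendError("stack values must be (time, row, col)")
        if len(self.times) != self.values.shape[0]:
            raise GrasstrendError(
                f"{len(self.times)} time labels for {self.values.shape[0]} layers"
            )
        years = [_label_year(t) for t in self.times]
        periods = [
            (t[1] if isinstance(t, (tuple, list)) else -1) for t in self.times
        ]
        if sorted(zip(years, periods)) != list(zip(years, periods)):
            raise GrasstrendError("time labels must be increasing")
        self.transform = Affine(*self.transform)

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def years(self) -> list[int]:
        return [_label_year(t) for t in self.times]

    def is_annual(self) -> bool:
        return all(not isinstance(t, (tuple, list)) for t in self.times)


def annual_mvc(stack: RasterStack) -> RasterStack:
    """Annual maximum-value composite: per pixel and year, the maximum over
    that year's non-nodata layers; all-nodata stays nodata.

    Idempotent on stacks that are already annual.
    """
    if stack.values.shape[0] == 0:
        raise GrasstrendError("cannot composite an empty stack")
    years = np.array(stack.years)
    out_years = sorted(set(years.tolist()))
    out = np.full((len(out_years), *stack.values.shape[1:]), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for k, yr in enumerate(out_years):
            sel = stack.values[years == yr]
            out[k] = np.nanmax(sel, axis=0)
    return RasterStack(out, out_years, stack.transform, stack.variable)


def aggregate(
    stack: RasterStack, factor: int, stat: str = "mean"
) -> RasterStack:
    """Block-aggregate each layer by ``factor`` (e.g. 10 for 1 km -> 10 km).

    Each output cell is the mean (or max/median) of the factor x factor
    block's non-nodata cells; edge blocks use the cells available; all-nodata
    blocks stay nodata. The transform's pixel size is rescaled.
    """
    if factor < 1 or int(factor) != factor:
        raise GrasstrendError("aggregation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return replace(stack, values=stack.values.copy())
    reducers = {"mean": np.nanmean, "max": np.nanmax, "median": np.nanmedian}
    if stat not in reducers:
        raise GrasstrendError(f"unknown aggregation statistic '{stat}'")
    reduce = reducers[stat]

    nt, nr, nc = stack.values.shape
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    out = np.full((nt, out_r, out_c), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        for i in range(out_r):
            for j in range(out_c):
                block = stack.values[
                    :, i * factor : (i + 1) * factor, j * factor : (j + 1) * factor
                ]
                out[:, i, j] = reduce(block, axis=(1, 2))
    return RasterStack(
        out, list(stack.times), stack.transform.rescaled(factor), stack.variable
    )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922
_GDAL_NODATA = 42113


def _geo_extratags(transform: Affine, nodata: str):
    return [
        (_GEOTIFF_PIXELSCALE, "d", 3, (abs(transform.a), abs(transform.e), 0.0)),
        (_GEOTIFF_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)),
        (_GDAL_NODATA, "s", 0, nodata),
    ]


def write_stack(path, stack: RasterStack) -> None:
    meta = {
        "variable": stack.variable,
        "times": [list(t) if isinstance(t, (tuple, list)) else t for t in stack.times],
        "transform": list(stack.transform),
    }
    tifffile.imwrite(
        path,
        stack.values.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=_geo_extratags(stack.transform, "nan"),
    )


def read_stack(path) -> RasterStack:
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray().astype(float)
        desc = tif.pages[0].description
    meta = json.loads(desc)
    times = [tuple(t) if isinstance(t, list) else t for t in meta["times"]]
    return RasterStack(
        values, times, Affine(*meta["transform"]), meta.get("variable", "ndvi")
    )


def write_raster(path, values: np.ndarray, transform: Affine, meta: dict | None = None) -> None:
    """Write a single 2-D raster (e.g. a class or type map), dtype preserved."""
    values = np.asarray(values)
    nodata = "nan" if values.dtype.kind == "f" else "0"
    info = {"transform": list(transform)}
    info.update(meta or {})
    tifffile.imwrite(
        path,
        values,
        photometric="minisblack",
        description=json.dumps(info),
        extratags=_geo_extratags(Affine(*transform), nodata),
    )


def read_raster(path) -> tuple[np.ndarray, Affine, dict]:
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    transform = Affine(*meta.pop("transform", Affine.identity()))
    return values, transform, meta


def check_aligned(shape_a, transform_a: Affine, shape_b, transform_b: Affine) -> None:
    """Raise GridMismatchError unless two rasters share grid and georeference."""
    if tuple(shape_a[-2:]) != tuple(shape_b[-2:]):
        raise GridMismatchError(
            f"grid shapes differ: {tuple(shape_a[-2:])} vs {tuple(shape_b[-2:])}"
        )
    if not np.allclose(transform_a, transform_b):
        raise GridMismatchError("georeference transforms differ")
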