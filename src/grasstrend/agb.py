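"""Grassland-type-specific NDVI -> aboveground-biomass models.

Meadow and steppe differ in structure and composition, so each grassland
type gets its own NDVI->AGB model: all four regression families are fitted
per type on plot data (x = field NDVI, y = AGB in kg/hm^2) and the best is
selected. Applied to a calibrated NDVI raster with a type map, the matching
model converts each grassland pixel; non-grassland pixels become nodata.

Two quality flags accompany the estimates: NDVI above 0.8 is outside the
surveyed range (the index saturates at dense canopy) and is converted but
flagged; negative linear-model predictions at very low NDVI are floored at
zero and flagged.

``flower_sensitivity`` rebuilds the models after excluding plots whose
large-flower coverage exceeds a threshold (default 20 %) — bright flowers on
top of the canopy inflate NDVI without adding much biomass, so contaminated
plots can bias the meadow model upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
import json
from typing import Sequence

import numpy as np

from .errors import GrasstrendError, GridMismatchError
from .field_survey import GrasslandType, PlotRecord
from .rasters import Affine, RasterStack, check_aligned
from .regression import RegressionModel, fit_all_families, predict, select_best


class TypeCode(IntEnum):
    """Encoding of the grassland-type raster."""

    NON_GRASSLAND = 0
    MEADOW = 1
    STEPPE = 2


NDVI_SATURATION = 0.8

# QA bit flags
QA_EXTRAPOLATED = 1  # NDVI above the surveyed range (> 0.8)
QA_FLOORED = 2  # negative prediction floored at 0


@dataclass(frozen=True)
class AgbModelSet:
    meadow: RegressionModel
    steppe: RegressionModel

    def for_type(self, gt: GrasslandType) -> RegressionModel:
        return self.meadow if GrasslandType(gt) == GrasslandType.MEADOW else self.steppe

    def to_dict(self) -> dict:
        return {"meadow": self.meadow.to_dict(), "steppe": self.steppe.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "AgbModelSet":
        return cls(
            meadow=RegressionModel.from_dict(d["meadow"]),
            steppe=RegressionModel.from_dict(d["steppe"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "AgbModelSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_agb_models(plots: Sequence[PlotRecord]) -> AgbModelSet:
    """Per grassland type, fit all families (x = field NDVI, y = AGB) and
    keep the best by R^2/RMSE."""
    fitted = {}
    for gt in GrasslandType:
        subset = [
            p for p in plots
            if p.grassland_type == gt and p.mean_field_ndvi is not None
        ]
        if len(subset) < 3:
            raise GrasstrendError(
                f"need at least 3 {gt.value} plots with NDVI; got {len(subset)}"
            )
        x = np.array([p.mean_field_ndvi for p in subset])
        y = np.array([p.mean_agb_kg_per_hm2 for p in subset])
        fitted[gt] = select_best(fit_all_families(x, y))
    return AgbModelSet(meadow=fitted[GrasslandType.MEADOW],
                       steppe=fitted[GrasslandType.STEPPE])


@dataclass
class AgbEstimate:
    agb: RasterStack
    qa: np.ndarray  # uint8 (time, row, col) bit flags


def estimate_agb(
    ndvi_stack: RasterStack,
    type_map: np.ndarray,
    models: AgbModelSet,
    type_transform: Affine | None = None,
) -> AgbEstimate:
    """Convert a calibrated NDVI stack to AGB using the per-type models.

    Non-grassland and nodata pixels map to nodata; negative predictions are
    floored at 0 and flagged; NDVI > 0.8 is converted but flagged.
    """
    type_map = np.asarray(type_map)
    if type_transform is not None:
        check_aligned(
            ndvi_stack.values.shape, ndvi_stack.transform,
            type_map.shape, type_transform,
        )
    elif type_map.shape != ndvi_stack.values.shape[1:]:
        raise GridMismatchError(
            f"type map {type_map.shape} does not match stack grid "
            f"{ndvi_stack.values.shape[1:]}"
        )

    out = np.full_like(ndvi_stack.values, np.nan)
    qa = np.zeros(ndvi_stack.values.shape, dtype=np.uint8)
    for code, gt in ((TypeCode.MEADOW, GrasslandType.MEADOW),
                     (TypeCode.STEPPE, GrasslandType.STEPPE)):
        model = models.for_type(gt)
        sel = (type_map == code)[np.newaxis] & ~np.isnan(ndvi_stack.values)
        if not sel.any():
            continue
        ndvi = ndvi_stack.values[sel]
        # power/log domains: non-positive NDVI cannot enter the formula;
        # treat it as bare ground (zero biomass, floored flag)
        safe = np.maximum(ndvi, 1e-12)
        pred = predict(model, safe)
        pred = np.where(ndvi <= 0, 0.0, pred)
        floored = pred < 0
        pred = np.where(floored, 0.0, pred)
        out[sel] = pred
        q = np.zeros(ndvi.shape, dtype=np.uint8)
        q[ndvi > NDVI_SATURATION] |= QA_EXTRAPOLATED
        q[floored | (ndvi <= 0)] |= QA_FLOORED
        qa[sel] = q

    agb = RasterStack(out, list(ndvi_stack.times), ndvi_stack.transform, "agb")
    return AgbEstimate(agb=agb, qa=qa)


def flower_sensitivity(
    plots: Sequence[PlotRecord], coverage_threshold: float = 0.20
) -> tuple[AgbModelSet, AgbModelSet, dict[str, int]]:
    """Refit the AGB models excluding flower-contaminated plots.

    Returns (original, refit, per-type count of excluded plots). Plots with
    ``flower_coverage`` strictly above the threshold are excluded from the
    refit.
    """
    original = fit_agb_models(plots)
    kept = [p for p in plots if p.flower_coverage <= coverage_threshold]
    excluded = {
        gt.value: sum(
            1 for p in plots
            if p.grassland_type == gt and p.flower_coverage > coverage_threshold
        )
        for gt in GrasslandType
    }
    for gt in GrasslandType:
        if sum(1 for p in kept if p.grassland_type == gt) < 3:
            raise GrasstrendError(
                f"flower exclusion leaves fewer than 3 {gt.value} plots"
            )
    refit = fit_agb_models(kept)
    return original, refit, excluded
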