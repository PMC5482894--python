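"""End-to-end orchestration: survey table -> calibration -> AGB stack ->
compositing/aggregation -> trend -> Hurst -> future-dynamics map.

`run_all` executes the stages in order from a single config, writes every
intermediate artifact into the output directory, and returns a JSON-ready
manifest (config hash, package version, per-stage summaries). Outputs are
deterministic for a fixed config, so reruns produce byte-identical rasters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .agb import TypeCode, estimate_agb, fit_agb_models, flower_sensitivity
from .calibration import apply_calibration, fit_calibration
from .errors import ConfigError, GrasstrendError, StageError
from .field_survey import read_plot_table
from .future import area_fractions, combine_maps
from .hurst import hurst_map
from .rasters import (
    RasterStack,
    aggregate,
    annual_mvc,
    read_raster,
    read_stack,
    write_raster,
    write_stack,
)
from .trend import trend_map

log = logging.getLogger("grasstrend")


@dataclass
class RunConfig:
    plots: str  # plot table CSV (needs mean_field_ndvi, modis_ndvi, AGB)
    ndvi_stack: str  # satellite NDVI stack TIFF
    type_map: str  # grassland-type raster TIFF (0/1/2)
    out_dir: str
    trend_threshold: float = 10.0
    tau_grid: Optional[list] = None
    flower_threshold: float = 0.2
    aggregate_factor: int = 1
    calibrate_by_type: bool = False
    paper_mode: bool = False
    hurst_correction: str = "none"
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"invalid run config: {exc}") from exc

    def validate(self) -> None:
        for key in ("plots", "ndvi_stack", "type_map"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"input '{key}' does not exist: {p}")

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(out_dir: Path, level: str) -> None:
    log.setLevel(level.upper())
    for h in log.handlers:
        h.close()
    log.handlers = []
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(),
              logging.FileHandler(out_dir / "run.log", mode="w")):
        h.setFormatter(fmt)
        log.addHandler(h)


def _aggregate_type_map(type_map: np.ndarray, factor: int) -> np.ndarray:
    """Block-majority downsampling of the categorical type raster."""
    nr, nc = type_map.shape
    out = np.zeros((-(-nr // factor), -(-nc // factor)), dtype=np.uint8)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            block = type_map[i * factor:(i + 1) * factor, j * factor:(j + 1) * factor]
            vals, counts = np.unique(block, return_counts=True)
            out[i, j] = vals[np.argmax(counts)]
    return out


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    manifest = {
        "config_hash": config.content_hash(),
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "artifacts": [],
    }

    def _artifact(path: Path):
        manifest["artifacts"].append(path.name)
        return path

    stage = "calibration"
    try:
        plots = read_plot_table(config.plots)
        paired = [p for p in plots if p.modis_ndvi is not None
                  and p.mean_field_ndvi is not None]
        calib = fit_calibration(paired)  # pooled model drives the raster stage
        calib_path = _artifact(out / "calib.json")
        calib.save(calib_path)
        if config.calibrate_by_type:
            by_type = fit_calibration(paired, by_type=True)
            with open(out / "calib_by_type.json", "w") as fh:
                json.dump({k.value: v.to_dict() for k, v in by_type.items()}, fh,
                          indent=2)
        manifest["stages"][stage] = {
            "family": calib.family.value, "r_squared": calib.r_squared,
            "rmse": calib.rmse, "n": calib.n,
        }
        log.info("calibration: %s R2=%.4f", calib.family.value, calib.r_squared)

        stage = "agb_models"
        models = fit_agb_models(plots)
        models.save(_artifact(out / "agb_models.json"))
        original, refit, excluded = flower_sensitivity(
            plots, coverage_threshold=config.flower_threshold
        )
        refit.save(out / "agb_models_flower_refit.json")
        manifest["stages"][stage] = {
            "meadow_family": models.meadow.family.value,
            "meadow_r_squared": models.meadow.r_squared,
            "steppe_family": models.steppe.family.value,
            "steppe_r_squared": models.steppe.r_squared,
            "flower_excluded": excluded,
        }

        stage = "ndvi_processing"
        stack = read_stack(config.ndvi_stack)
        type_map, type_transform, _ = read_raster(config.type_map)
        calibrated = apply_calibration(stack, calib)
        annual_ndvi = annual_mvc(calibrated)
        if config.aggregate_factor > 1:
            annual_ndvi = aggregate(annual_ndvi, config.aggregate_factor)
            type_map = _aggregate_type_map(type_map, config.aggregate_factor)
        manifest["stages"][stage] = {
            "n_years": len(annual_ndvi.times),
            "grid": list(annual_ndvi.values.shape[1:]),
        }

        stage = "agb_estimation"
        est = estimate_agb(annual_ndvi, type_map, models)
        write_stack(_artifact(out / "agb_annual.tif"), est.agb)
        grass = type_map != TypeCode.NON_GRASSLAND
        mean_agb = {
            "meadow": float(np.nanmean(est.agb.values[:, type_map == TypeCode.MEADOW]))
            if (type_map == TypeCode.MEADOW).any() else None,
            "steppe": float(np.nanmean(est.agb.values[:, type_map == TypeCode.STEPPE]))
            if (type_map == TypeCode.STEPPE).any() else None,
        }
        manifest["stages"][stage] = {"mean_agb": mean_agb,
                                     "qa_flagged": int((est.qa > 0).sum())}

        stage = "trend"
        tres = trend_map(est.agb, threshold=config.trend_threshold)
        write_raster(_artifact(out / "slope.tif"), tres.slope.astype(np.float32),
                     est.agb.transform)
        write_raster(
            _artifact(out / "classes.tif"), tres.trend_class, est.agb.transform,
            meta={"legend": {"1": "sig_decrease", "2": "nonsig_decrease",
                             "3": "nonsig_increase", "4": "sig_increase"}},
        )
        manifest["stages"][stage] = {
            "class_fractions": tres.class_fractions,
            "mean_slope": float(np.nanmean(tres.slope[grass])),
        }

        stage = "hurst"
        hres = hurst_map(est.agb, tau_grid=config.tau_grid,
                         correction=config.hurst_correction)
        write_raster(_artifact(out / "hurst.tif"), hres.h.astype(np.float32),
                     est.agb.transform)
        write_raster(
            _artifact(out / "sustain.tif"), hres.sustainability, est.agb.transform,
            meta={"legend": {"1": "sustainable", "2": "anti_sustainable",
                             "3": "random"}},
        )
        manifest["stages"][stage] = {
            "fraction_h_above_0.5": hres.fraction_sustainable,
            "mean_h": float(np.nanmean(hres.h[grass])),
            "tau_grid": hres.tau_grid,
        }

        stage = "future_classification"
        future = combine_maps(tres.trend_class, hres.sustainability,
                              paper_mode=config.paper_mode)
        write_raster(
            _artifact(out / "future.tif"), future, est.agb.transform,
            meta={"legend": {"1": "s_sig_decrease", "2": "s_nonsig_decrease",
                             "3": "s_nonsig_increase", "4": "s_sig_increase",
                             "5": "anti_sustainable_uncertain",
                             "6": "random_uncertain"}},
        )
        fractions = area_fractions(future, type_map)
        fractions.to_csv(_artifact(out / "fractions.csv"), index=False)
        manifest["stages"][stage] = {
            "improvement_pct": float(
                fractions.loc[fractions["class"] == "improvement", "overall_pct"].iloc[0]
            ),
            "degradation_pct": float(
                fractions.loc[fractions["class"] == "degradation", "overall_pct"].iloc[0]
            ),
        }
    except GrasstrendError as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise StageError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete: %d artifacts in %s", len(manifest["artifacts"]), out)
    return manifest
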