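"""Synthetic inputs for the whole pipeline: plot surveys with spectra,
paired field/satellite NDVI, and raster time series with prescribed trend
and Hurst structure.

The survey generator emulates the study design it stands in for: two
grassland types with disjoint NDVI ranges (meadow above 0.5, steppe below),
nine quadrats per plot, type-specific NDVI->AGB generating laws whose means
match the reported plot averages (meadow ~706.7, steppe ~498.7 kg/hm^2), a
linear field->satellite NDVI map with noise, and a share of meadow plots
whose measured NDVI is inflated by flower contamination.

The raster generator produces per-pixel series

    AGB_i = baseline + trend * i + innovation_sd * fGn_i(H)

where fGn is exact fractional Gaussian noise from circulant embedding of
the fGn autocovariance, so trend- and Hurst-recovery can be tested against
known truth. An optional 16-day mode emits within-year curves whose annual
maximum equals the annual value exactly, to exercise the maximum-value
composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .agb import TypeCode
from .errors import GrasstrendError
from .field_survey import (
    GrasslandType,
    PlotRecord,
    QuadratRecord,
    Spectrum,
    aggregate_plot,
    plots_to_frame,
    write_plot_table,
    write_spectrum_csv,
)
from .rasters import Affine, RasterStack, write_raster, write_stack
from .regression import Family, RegressionModel


def generator_model(family, a: float, b: float) -> RegressionModel:
    """A RegressionModel used as a generating law (metrics are placeholders)."""
    return RegressionModel(
        family=Family(family), a=a, b=b, r_squared=1.0, rmse=0.0, n=0,
        x_domain=(0.0, 1.0),
    )


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def _fgn_autocov(n: int, h: float) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    return 0.5 * ((k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h))


def _fgn_cholesky(n: int, h: float, rng: np.random.Generator) -> np.ndarray:
    """Exact sequential conditional-Gaussian construction (O(n^2) fallback)."""
    from scipy.linalg import cholesky, toeplitz

    gamma = _fgn_autocov(n - 1, h)
    cov = toeplitz(gamma[:n])
    L = cholesky(cov + 1e-12 * np.eye(n), lower=True)
    return L @ rng.standard_normal(n)


def simulate_fgn(
    n: int, h: float, seed: Union[int, np.random.Generator, None] = None,
    size: int = 1,
) -> np.ndarray:
    """Exact zero-mean, unit-variance fractional Gaussian noise.

    Uses circulant embedding (Davies-Harte) of the fGn autocovariance

        gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H});

    h = 0.5 reduces to i.i.d. Gaussian noise. Returns shape (n,) when
    ``size`` is 1, else (size, n). Falls back to an exact Cholesky
    construction if the embedding is numerically non-positive-definite.
    """
    if n < 2:
        raise GrasstrendError("need n >= 2")
    if not 0.0 < h < 1.0:
        raise GrasstrendError(f"Hurst parameter must be in (0, 1); got {h}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gamma = _fgn_autocov(n, h)
    row = np.concatenate([gamma, gamma[n - 1:0:-1]])  # circulant first row, len 2n
    lam = np.fft.fft(row).real
    m = 2 * n
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        out = np.stack([_fgn_cholesky(n, h, rng) for _ in range(size)])
        return out[0] if size == 1 else out
    lam = np.clip(lam, 0.0, None)

    z = rng.standard_normal((size, m))
    w = np.zeros((size, m), dtype=complex)
    w[:, 0] = np.sqrt(lam[0] / m) * z[:, 0]
    w[:, n] = np.sqrt(lam[n] / m) * z[:, 1]
    re = z[:, 2:n + 1]
    im = z[:, n + 1:2 * n]
    w[:, 1:n] = np.sqrt(lam[1:n] / (2 * m)) * (re + 1j * im)
    w[:, n + 1:] = np.conj(w[:, 1:n][:, ::-1])
    x = np.fft.fft(w, axis=1).real[:, :n]
    return x[0] if size == 1 else x


# ---------------------------------------------------------------------------
# plot survey
# ---------------------------------------------------------------------------

def build_spectrum(target_ndvi: float) -> Spectrum:
    """Construct a minimal canopy spectrum whose narrow-band NDVI equals the
    target exactly: fix R800 = 0.5 and solve for R680 (re-anchoring on R680
    when the solution leaves [0, 1])."""
    v = float(target_ndvi)
    if not -1.0 < v < 1.0:
        raise GrasstrendError(f"target NDVI {v} not attainable by reflectances")
    r_nir = 0.5
    r_red = r_nir * (1 - v) / (1 + v)
    if not 0.0 <= r_red <= 1.0:
        r_red = 0.9
        r_nir = r_red * (1 + v) / (1 - v)
        if not 0.0 <= r_nir <= 1.0:
            raise GrasstrendError(f"no feasible reflectance pair for NDVI {v}")
    shoulder = min(1.0, 0.95 * r_nir)
    return Spectrum(
        wavelengths_nm=(400, 680, 800, 1000),
        reflectance=(0.05, r_red, r_nir, shoulder),
    )


@dataclass
class SurveyConfig:
    """Study conditions for the synthetic plot survey.

    Defaults follow the emulated survey: 31 meadow and 33 steppe plots, nine
    quadrats each, meadow NDVI above 0.5 and steppe below, generating laws
    scaled so the type-mean AGB is ~706.7 (meadow) and ~498.7 (steppe)
    kg/hm^2, and satellite NDVI running higher than field NDVI.
    """

    n_meadow_plots: int = 31
    n_steppe_plots: int = 33
    n_quadrats: int = 9
    meadow_law: RegressionModel = field(
        default_factory=lambda: generator_model(Family.LINEAR, 56.7, 1000.0)
    )
    steppe_law: RegressionModel = field(
        default_factory=lambda: generator_model(Family.POWER, 4390.0, 1.8)
    )
    meadow_ndvi_range: tuple = (0.52, 0.78)
    steppe_ndvi_range: tuple = (0.08, 0.48)
    ndvi_jitter_sd: float = 0.02
    agb_noise_sd: Union[float, dict] = field(
        default_factory=lambda: {"meadow": 80.0, "steppe": 145.0}
    )
    calibration_a: float = 0.05  # satellite = a + b * field (+ noise)
    calibration_b: float = 1.1
    calibration_noise_sd: float = 0.02
    flower_fraction: float = 0.13  # share of meadow plots contaminated
    contamination_ndvi_shift: float = 0.05
    # clip-harvest weight of the flowers themselves: contaminated plots carry
    # extra biomass on top of the grass law, which is what places them above
    # the clean NDVI-AGB relation and makes the all-plots model sit higher
    # than the flower-free refit
    contamination_agb_bonus: float = 150.0
    seed: int = 0

    def noise_sd(self, gt: GrasslandType) -> float:
        if isinstance(self.agb_noise_sd, dict):
            return float(self.agb_noise_sd[GrasslandType(gt).value])
        return float(self.agb_noise_sd)

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("meadow_law", "steppe_law"):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                raw[key] = generator_model(d["family"], d["a"], d["b"])
        for key in ("meadow_ndvi_range", "steppe_ndvi_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SurveyData:
    quadrats: list  # QuadratRecord
    plots: list  # PlotRecord
    truth: pd.DataFrame  # per-plot generating values

    def write(self, out_dir) -> dict:
        """Write quadrats.csv, spectra/*.csv and plots.csv; returns paths."""
        out = Path(out_dir)
        (out / "spectra").mkdir(parents=True, exist_ok=True)
        rows = []
        for q in self.quadrats:
            ref = ""
            if q.spectrum is not None:
                ref = f"spectra/{q.plot_id}_q{q.quadrat_index}.csv"
                write_spectrum_csv(q.spectrum, out / ref)
            rows.append(
                {
                    "plot_id": q.plot_id,
                    "quadrat_index": q.quadrat_index,
                    "agb_kg_per_hm2": q.agb_kg_per_hm2,
                    "spectrum_file": ref,
                }
            )
        pd.DataFrame(rows).to_csv(out / "quadrats.csv", index=False)
        write_plot_table(self.plots, out / "plots.csv")
        self.truth.to_csv(out / "truth.csv", index=False)
        return {
            "quadrats": str(out / "quadrats.csv"),
            "plots": str(out / "plots.csv"),
            "truth": str(out / "truth.csv"),
        }

    def plots_frame(self) -> pd.DataFrame:
        return plots_to_frame(self.plots)


def simulate_survey(config: SurveyConfig | None = None) -> SurveyData:
    """Generate a full synthetic plot survey (quadrats, spectra, plot table)."""
    cfg = config or SurveyConfig()
    rng = np.random.default_rng(cfg.seed)
    quadrats: list[QuadratRecord] = []
    plots: list[PlotRecord] = []
    truth_rows = []

    specs = [(GrasslandType.MEADOW, cfg.n_meadow_plots, cfg.meadow_ndvi_range,
              cfg.meadow_law),
             (GrasslandType.STEPPE, cfg.n_steppe_plots, cfg.steppe_ndvi_range,
              cfg.steppe_law)]
    counter = 0
    for gt, n_plots, (lo, hi), law in specs:
        sd = cfg.noise_sd(gt)
        for _ in range(n_plots):
            counter += 1
            plot_id = f"P{counter:03d}"
            contaminated = (
                gt == GrasslandType.MEADOW and rng.random() < cfg.flower_fraction
            )
            plot_ndvi = rng.uniform(lo, hi)
            q_ndvi = np.clip(
                plot_ndvi + rng.normal(0.0, cfg.ndvi_jitter_sd, cfg.n_quadrats),
                lo, hi,
            )
            # contamination inflates the *measured* NDVI, not the biomass
            measured = q_ndvi + (cfg.contamination_ndvi_shift if contaminated else 0.0)
            measured = np.clip(measured, -0.99, 0.8)
            from .regression import predict

            agb = predict(law, q_ndvi) + rng.normal(0.0, sd, cfg.n_quadrats)
            if contaminated:
                agb = agb + cfg.contamination_agb_bonus
            agb = np.maximum(agb, 0.0)
            plot_quadrats = [
                QuadratRecord(
                    plot_id=plot_id,
                    quadrat_index=k + 1,
                    agb_kg_per_hm2=float(agb[k]),
                    spectrum=build_spectrum(float(measured[k])),
                )
                for k in range(cfg.n_quadrats)
            ]
            flower_cov = (
                float(rng.uniform(0.25, 0.60)) if contaminated
                else float(rng.uniform(0.0, 0.15))
            )
            record = aggregate_plot(plot_quadrats, gt, flower_coverage=flower_cov)
            modis = float(
                np.clip(
                    cfg.calibration_a
                    + cfg.calibration_b * record.mean_field_ndvi
                    + rng.normal(0.0, cfg.calibration_noise_sd),
                    -1.0, 1.0,
                )
            )
            record = PlotRecord(
                plot_id=record.plot_id,
                grassland_type=record.grassland_type,
                mean_agb_kg_per_hm2=record.mean_agb_kg_per_hm2,
                mean_field_ndvi=record.mean_field_ndvi,
                flower_coverage=record.flower_coverage,
                modis_ndvi=modis,
            )
            quadrats.extend(plot_quadrats)
            plots.append(record)
            truth_rows.append(
                {
                    "plot_id": plot_id,
                    "grassland_type": gt.value,
                    "true_plot_ndvi": plot_ndvi,
                    "contaminated": contaminated,
                }
            )
    return SurveyData(quadrats=quadrats, plots=plots, truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# raster stacks
# ---------------------------------------------------------------------------

N_PERIODS_PER_YEAR = 23  # 16-day composites


@dataclass
class StackConfig:
    """Study conditions for the synthetic raster time series."""

    n_rows: int = 20
    n_cols: int = 20
    n_years: int = 13
    start_year: int = 2000
    baseline: float = 400.0  # kg/hm^2
    trend_mean: float = 0.25  # per-pixel slope distribution (kg/hm^2/yr)
    trend_sd: float = 8.0  # 0 -> constant trend everywhere
    hurst_target: float = 0.7
    innovation_sd: float = 30.0
    type_layout: str = "halves"  # halves | meadow | steppe
    sixteen_day: bool = False
    seasonal_dip: float = 100.0  # depth of the within-year cycle (16-day mode)
    variable: str = "agb"
    clip_range: Optional[tuple] = None  # e.g. (-1, 1) for NDVI stacks
    pixel_size: float = 10000.0  # metres; 10 km grid
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StackConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "clip_range" in raw and raw["clip_range"] is not None:
            raw["clip_range"] = tuple(raw["clip_range"])
        return cls(**raw)


@dataclass
class StackData:
    stack: RasterStack  # emitted stack (annual, or 16-day when configured)
    annual_truth: RasterStack  # noise-free-of-season annual values
    type_map: np.ndarray  # uint8 TypeCode grid
    truth: pd.DataFrame  # per-pixel generating trend and Hurst target

    def write(self, stack_path, types_path=None, truth_path=None) -> None:
        write_stack(stack_path, self.stack)
        if types_path:
            write_raster(
                types_path, self.type_map, self.stack.transform,
                meta={"legend": {"0": "non_grassland", "1": "meadow", "2": "steppe"}},
            )
        if truth_path:
            self.truth.to_csv(truth_path, index=False)


def make_type_map(n_rows: int, n_cols: int, layout: str = "halves") -> np.ndarray:
    tm = np.zeros((n_rows, n_cols), dtype=np.uint8)
    if layout == "halves":
        tm[:, : n_cols // 2] = TypeCode.MEADOW
        tm[:, n_cols // 2:] = TypeCode.STEPPE
    elif layout == "meadow":
        tm[:] = TypeCode.MEADOW
    elif layout == "steppe":
        tm[:] = TypeCode.STEPPE
    else:
        raise GrasstrendError(f"unknown type layout '{layout}'")
    return tm


def simulate_stack(config: StackConfig | None = None) -> StackData:
    """Generate an annual (or 16-day) raster stack with known per-pixel
    trend and Hurst structure plus the matching truth tables."""
    cfg = config or StackConfig()
    if cfg.baseline < 0:
        raise GrasstrendError("baseline must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    nr, nc, ny = cfg.n_rows, cfg.n_cols, cfg.n_years
    npix = nr * nc

    trends = (
        np.full(npix, cfg.trend_mean)
        if cfg.trend_sd == 0
        else rng.normal(cfg.trend_mean, cfg.trend_sd, npix)
    )
    noise = simulate_fgn(ny, cfg.hurst_target, rng, size=npix)  # (npix, ny)
    i = np.arange(1, ny + 1, dtype=float)
    series = cfg.baseline + trends[:, None] * i[None, :] + cfg.innovation_sd * noise
    if cfg.clip_range is not None:
        series = np.clip(series, *cfg.clip_range)

    annual = series.T.reshape(ny, nr, nc)
    years = list(range(cfg.start_year, cfg.start_year + ny))
    transform = Affine(cfg.pixel_size, 0.0, 0.0, 0.0, -cfg.pixel_size, 0.0)
    annual_stack = RasterStack(annual, years, transform, cfg.variable)
    type_map = make_type_map(nr, nc, cfg.type_layout)
    rows, cols = np.divmod(np.arange(npix), nc)
    truth = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "trend": trends,
            "hurst": np.full(npix, cfg.hurst_target),
        }
    )

    if not cfg.sixteen_day:
        return StackData(annual_stack, annual_stack, type_map, truth)

    # within-year curve dipping below the annual value; the maximum over the
    # 23 periods equals the annual value exactly (at mid-season)
    p = np.arange(N_PERIODS_PER_YEAR)
    shape = np.sin(np.pi * (p + 0.5) / N_PERIODS_PER_YEAR)  # peak == 1 at p=11
    layers = []
    times = []
    for k, yr in enumerate(years):
        for pp in p:
            layers.append(annual[k] - cfg.seasonal_dip * (1.0 - shape[pp]))
            times.append((yr, int(pp)))
    sixteen = RasterStack(np.stack(layers), times, transform, cfg.variable)
    return StackData(sixteen, annual_stack, type_map, truth)
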