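"""Plot-survey handling: canopy spectra, narrow-band NDVI, and quadrat aggregation.

A plot is sampled with nine 1 m x 1 m quadrats. Each quadrat yields a
clip-harvested aboveground-biomass (AGB) weight and, usually, one canopy
reflectance spectrum from a handheld spectrometer (400-1000 nm, 1 nm
resolution). Narrow-band NDVI uses the 680 nm (red) and 800 nm (near
infrared) reflectances:

    NDVI = (R800 - R680) / (R800 + R680)

Plot-level values are arithmetic means over quadrats; quadrats without a
spectrum contribute to the AGB mean only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BandMissingError, DegenerateSpectrumError, GrasstrendError

RED_NM = 680
NIR_NM = 800


class GrasslandType(str, Enum):
    MEADOW = "meadow"
    STEPPE = "steppe"


@dataclass(frozen=True)
class Spectrum:
    """Canopy reflectance at integer wavelengths for one quadrat point."""

    wavelengths_nm: tuple
    reflectance: tuple

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.shape != rf.shape:
            raise GrasstrendError("wavelengths and reflectance differ in length")
        if wl.size and np.any(np.diff(wl) <= 0):
            raise GrasstrendError("wavelengths must be strictly increasing")
        if np.any(rf < 0) or np.any(rf > 1):
            raise GrasstrendError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths_nm", tuple(int(w) for w in wl))
        object.__setattr__(self, "reflectance", tuple(float(r) for r in rf))

    def reflectance_at(self, wavelength_nm: int) -> float:
        try:
            idx = self.wavelengths_nm.index(int(wavelength_nm))
        except ValueError:
            raise BandMissingError(
                f"no reflectance recorded at {wavelength_nm} nm"
            ) from None
        return self.reflectance[idx]


@dataclass(frozen=True)
class QuadratRecord:
    plot_id: str
    quadrat_index: int
    agb_kg_per_hm2: float
    spectrum: Optional[Spectrum] = None

    def __post_init__(self):
        if self.agb_kg_per_hm2 < 0:
            raise GrasstrendError(f"negative AGB for quadrat {self.quadrat_index}")


@dataclass(frozen=True)
class PlotRecord:
    plot_id: str
    grassland_type: GrasslandType
    mean_agb_kg_per_hm2: float
    mean_field_ndvi: Optional[float]
    flower_coverage: float = 0.0
    modis_ndvi: Optional[float] = None


def compute_narrowband_ndvi(spectrum: Spectrum) -> float:
    """Narrow-band NDVI from the 680 nm and 800 nm reflectances.

    Raises
    ------
    BandMissingError
        if either band is absent from the spectrum.
    DegenerateSpectrumError
        if both reflectances are zero (undefined ratio).
    """
    r_red = spectrum.reflectance_at(RED_NM)
    r_nir = spectrum.reflectance_at(NIR_NM)
    denom = r_nir + r_red
    if denom <= 0:
        raise DegenerateSpectrumError("R800 + R680 is zero; NDVI undefined")
    return (r_nir - r_red) / denom


def aggregate_plot(
    quadrats: Sequence[QuadratRecord],
    grassland_type: GrasslandType,
    flower_coverage: float = 0.0,
    modis_ndvi: Optional[float] = None,
) -> PlotRecord:
    """Aggregate quadrat records into one plot record.

    Mean AGB averages all quadrats; mean NDVI averages only quadrats that
    carry a spectrum. A plot with no spectra gets ``mean_field_ndvi=None``
    (flagged, never zero-filled).
    """
    if not quadrats:
        raise GrasstrendError("cannot aggregate an empty quadrat list")
    plot_ids = {q.plot_id for q in quadrats}
    if len(plot_ids) != 1:
        raise GrasstrendError(f"mixed plot ids in one aggregation: {sorted(plot_ids)}")
    indices = [q.quadrat_index for q in quadrats]
    if len(set(indices)) != len(indices):
        raise GrasstrendError("duplicate quadrat indices within a plot")

    mean_agb = float(np.mean([q.agb_kg_per_hm2 for q in quadrats]))
    ndvis = [
        compute_narrowband_ndvi(q.spectrum) for q in quadrats if q.spectrum is not None
    ]
    mean_ndvi = float(np.mean(ndvis)) if ndvis else None
    return PlotRecord(
        plot_id=quadrats[0].plot_id,
        grassland_type=GrasslandType(grassland_type),
        mean_agb_kg_per_hm2=mean_agb,
        mean_field_ndvi=mean_ndvi,
        flower_coverage=float(flower_coverage),
        modis_ndvi=modis_ndvi,
    )


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_spectrum_csv(path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        wavelengths_nm=tuple(df["wavelength_nm"].astype(int)),
        reflectance=tuple(df["reflectance"].astype(float)),
    )


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths_nm, "reflectance": spectrum.reflectance}
    ).to_csv(path, index=False)


def read_quadrat_table(quadrats_csv, spectra_dir=None) -> list[QuadratRecord]:
    """Read quadrat rows; ``spectrum_file`` entries resolve relative to
    ``spectra_dir`` (default: the CSV's directory)."""
    quadrats_csv = Path(quadrats_csv)
    base = Path(spectra_dir) if spectra_dir is not None else quadrats_csv.parent
    df = pd.read_csv(quadrats_csv)
    records = []
    for row in df.itertuples(index=False):
        spec = None
        ref = getattr(row, "spectrum_file", None)
        if isinstance(ref, str) and ref:
            spec = read_spectrum_csv(base / ref)
        records.append(
            QuadratRecord(
                plot_id=str(row.plot_id),
                quadrat_index=int(row.quadrat_index),
                agb_kg_per_hm2=float(row.agb_kg_per_hm2),
                spectrum=spec,
            )
        )
    return records


def plots_to_frame(plots: Sequence[PlotRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "grassland_type": [p.grassland_type.value for p in plots],
            "mean_agb_kg_per_hm2": [p.mean_agb_kg_per_hm2 for p in plots],
            "mean_field_ndvi": [p.mean_field_ndvi for p in plots],
            "flower_coverage": [p.flower_coverage for p in plots],
            "modis_ndvi": [p.modis_ndvi for p in plots],
        }
    )


def write_plot_table(plots: Sequence[PlotRecord], path) -> None:
    plots_to_frame(plots).to_csv(path, index=False)


def read_plot_table(path) -> list[PlotRecord]:
    df = pd.read_csv(path)
    plots = []
    for row in df.itertuples(index=False):
        ndvi = row.mean_field_ndvi
        modis = getattr(row, "modis_ndvi", None)
        plots.append(
            PlotRecord(
                plot_id=str(row.plot_id),
                grassland_type=GrasslandType(row.grassland_type),
                mean_agb_kg_per_hm2=float(row.mean_agb_kg_per_hm2),
                mean_field_ndvi=None if pd.isna(ndvi) else float(ndvi),
                flower_coverage=float(getattr(row, "flower_coverage", 0.0)),
                modis_ndvi=None if modis is None or pd.isna(modis) else float(modis),
            )
        )
    return plots
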