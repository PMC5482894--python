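"""Combined future-dynamics classification and per-type area fractions.

Where the trend is sustainable (H > 0.5) the observed trend class is
expected to continue, giving four "sustainable x trend" classes. Where the
series is anti-persistent (H < 0.5) the future direction is uncertain
regardless of the observed trend; H exactly 0.5 (memoryless) is kept as a
separate uncertain class, collapsible into the anti-sustainable one for
strict comparison with the four+1 scheme ("paper mode" reporting).
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
import pandas as pd

from .agb import TypeCode
from .errors import GridMismatchError, GrasstrendError
from .hurst import SustainClass
from .trend import TrendClass


class FutureClass(IntEnum):
    S_SIG_DECREASE = 1
    S_NONSIG_DECREASE = 2
    S_NONSIG_INCREASE = 3
    S_SIG_INCREASE = 4
    ANTI_SUSTAINABLE_UNCERTAIN = 5
    RANDOM_UNCERTAIN = 6


_SUSTAINABLE_MAP = {
    TrendClass.SIG_DECREASE: FutureClass.S_SIG_DECREASE,
    TrendClass.NONSIG_DECREASE: FutureClass.S_NONSIG_DECREASE,
    TrendClass.NONSIG_INCREASE: FutureClass.S_NONSIG_INCREASE,
    TrendClass.SIG_INCREASE: FutureClass.S_SIG_INCREASE,
}

IMPROVEMENT_CLASSES = (FutureClass.S_NONSIG_INCREASE, FutureClass.S_SIG_INCREASE)
DEGRADATION_CLASSES = (FutureClass.S_NONSIG_DECREASE, FutureClass.S_SIG_DECREASE)


def combine(trend_class: TrendClass, sustainability: SustainClass) -> FutureClass:
    """Combine one pixel's trend and sustainability classes."""
    sustainability = SustainClass(sustainability)
    if sustainability == SustainClass.SUSTAINABLE:
        return _SUSTAINABLE_MAP[TrendClass(trend_class)]
    if sustainability == SustainClass.ANTI_SUSTAINABLE:
        return FutureClass.ANTI_SUSTAINABLE_UNCERTAIN
    return FutureClass.RANDOM_UNCERTAIN


def combine_maps(
    trend_codes: np.ndarray, sustain_codes: np.ndarray, paper_mode: bool = False
) -> np.ndarray:
    """Vectorised combine over class-code rasters (0 = nodata in and out).

    ``paper_mode`` collapses the memoryless (H = 0.5) class into the
    anti-sustainable uncertain class."""
    trend_codes = np.asarray(trend_codes)
    sustain_codes = np.asarray(sustain_codes)
    if trend_codes.shape != sustain_codes.shape:
        raise GridMismatchError("trend and sustainability maps differ in shape")
    out = np.zeros(trend_codes.shape, dtype=np.uint8)
    sustainable = sustain_codes == SustainClass.SUSTAINABLE
    out[sustainable] = trend_codes[sustainable]  # codes 1..4 coincide by design
    out[sustain_codes == SustainClass.ANTI_SUSTAINABLE] = (
        FutureClass.ANTI_SUSTAINABLE_UNCERTAIN
    )
    out[sustain_codes == SustainClass.RANDOM] = (
        FutureClass.ANTI_SUSTAINABLE_UNCERTAIN if paper_mode
        else FutureClass.RANDOM_UNCERTAIN
    )
    out[(trend_codes == 0) | (sustain_codes == 0)] = 0
    return out


def area_fractions(class_map: np.ndarray, type_map: np.ndarray) -> pd.DataFrame:
    """Percentage of grassland pixels per future class, overall and per type.

    Adds "improvement" (sustainable increases) and "degradation"
    (sustainable decreases) aggregate rows. Percentages are over non-nodata
    grassland pixels and sum to 100 per column across the six classes.
    """
    class_map = np.asarray(class_map)
    type_map = np.asarray(type_map)
    if class_map.shape != type_map.shape:
        raise GridMismatchError("class map and type map differ in shape")

    masks = {
        "overall": (type_map != TypeCode.NON_GRASSLAND) & (class_map > 0),
        "meadow": (type_map == TypeCode.MEADOW) & (class_map > 0),
        "steppe": (type_map == TypeCode.STEPPE) & (class_map > 0),
    }
    rows = []
    for fc in FutureClass:
        row = {"class": fc.name.lower()}
        for name, mask in masks.items():
            total = int(mask.sum())
            row[f"{name}_pct"] = (
                100.0 * float(np.sum(class_map[mask] == fc)) / total if total else 0.0
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    for label, members in (
        ("improvement", IMPROVEMENT_CLASSES),
        ("degradation", DEGRADATION_CLASSES),
    ):
        agg = {"class": label}
        for name in masks:
            agg[f"{name}_pct"] = float(
                df.loc[df["class"].isin([m.name.lower() for m in members]),
                       f"{name}_pct"].sum()
            )
        df = pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
    return df
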