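"""Rescaled-range (R/S) estimation of the Hurst exponent and the
sustainability classification of trends.

For each window length tau the series is split into floor(n/tau)
consecutive non-overlapping windows. Within a window the cumulative sums of
mean-deviations are formed; R is their range (max - min) and S the
population standard deviation of the window. The rescaled range for that
tau is the mean of R/S over windows with S > 0. The Hurst exponent H is the
least-squares slope of

    log(R/S)_tau = a + H * log(tau)

over a grid of window lengths. H > 0.5 indicates a persistent series whose
trend tends to continue (sustainable), H < 0.5 an anti-persistent one
(trend-reversing), and H = 0.5 a memoryless series.

The classical R/S estimator is biased upward for small samples; an optional
Anis-Lloyd correction subtracts the bias of the expected white-noise R/S on
the same tau grid. It is off by default, and estimates from very short
series (such as 13 annual values) carry large variance regardless.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .errors import DegenerateSeriesError, EstimationFailedError, GrasstrendError
from .rasters import RasterStack


class SustainClass(IntEnum):
    SUSTAINABLE = 1
    ANTI_SUSTAINABLE = 2
    RANDOM = 3


@dataclass(frozen=True)
class RSPoint:
    tau: int
    rs: float
    n_windows: int


def default_tau_grid(n: int) -> list[int]:
    """Window lengths used when none are given.

    Short series (n < 16, e.g. 13 annual composites) use the sparse grid
    {3, 4, 6, 12, 13} clipped to [2, n]; longer series use every integer
    from 4 to n // 2 plus n itself.
    """
    if n < 16:
        return [t for t in (3, 4, 6, 12, 13) if 2 <= t <= n]
    return list(range(4, n // 2 + 1)) + [n]


def _rs_matrix(x: np.ndarray, tau: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean R/S at one tau for a batch of series.

    x has shape (m, n); returns (mean_rs, n_valid_windows) of shape (m,),
    NaN where every window is degenerate (S = 0).
    """
    m, n = x.shape
    k = n // tau
    w = x[:, : k * tau].reshape(m, k, tau)
    dev = w - w.mean(axis=2, keepdims=True)
    cs = np.cumsum(dev, axis=2)
    r = cs.max(axis=2) - cs.min(axis=2)
    s = w.std(axis=2)  # population form, divisor tau
    valid = s > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.where(valid, r / np.where(valid, s, 1.0), np.nan)
    n_valid = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_rs = np.where(n_valid > 0, np.nansum(rs, axis=1) / np.maximum(n_valid, 1), np.nan)
    return mean_rs, n_valid


def rescaled_range(series, tau: int) -> RSPoint:
    """Mean rescaled range over non-overlapping windows of length tau."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    if not 2 <= tau <= n:
        raise GrasstrendError(f"tau must be in [2, {n}]; got {tau}")
    rs, n_valid = _rs_matrix(series[np.newaxis], int(tau))
    if n_valid[0] == 0:
        raise DegenerateSeriesError(
            f"every window of length {tau} has zero variance"
        )
    return RSPoint(tau=int(tau), rs=float(rs[0]), n_windows=int(n_valid[0]))


def _anis_lloyd_expected(tau: np.ndarray) -> np.ndarray:
    """Expected R/S of i.i.d. Gaussian noise (Anis & Lloyd with Peters'
    small-sample front factor)."""
    out = np.empty(len(tau), dtype=float)
    for j, t in enumerate(tau):
        i = np.arange(1, t)
        ssum = np.sum(np.sqrt((t - i) / i))
        if t <= 340:
            front = np.exp(gammaln((t - 1) / 2) - gammaln(t / 2)) / np.sqrt(np.pi)
        else:
            front = 1.0 / np.sqrt(t * np.pi / 2)
        out[j] = (t - 0.5) / t * front * ssum
    return out


def _loglog_fit(log_tau: np.ndarray, log_rs: np.ndarray) -> tuple[float, float]:
    b, a = np.polyfit(log_tau, log_rs, 1)
    return float(b), float(a)


def hurst_exponent(
    series,
    tau_grid: Sequence[int] | None = None,
    correction: str = "none",
) -> tuple[float, float]:
    """Estimate (H, intercept) for one series by the R/S log-log fit."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    taus = sorted(set(int(t) for t in (tau_grid or default_tau_grid(n))))
    taus = [t for t in taus if 2 <= t <= n]
    if len(taus) < 3:
        raise EstimationFailedError("tau grid has fewer than 3 usable values")
    points = []
    for t in taus:
        try:
            p = rescaled_range(series, t)
        except DegenerateSeriesError:
            continue
        if p.rs > 0:
            points.append(p)
    if len(points) < 3:
        raise EstimationFailedError(
            f"only {len(points)} valid R/S points; need >= 3"
        )
    log_tau = np.log([p.tau for p in points])
    log_rs = np.log([p.rs for p in points])
    h, a = _loglog_fit(log_tau, log_rs)
    if correction == "anis-lloyd":
        expected = _anis_lloyd_expected(np.array([p.tau for p in points]))
        h_al, _ = _loglog_fit(log_tau, np.log(expected))
        h = 0.5 + h - h_al
    elif correction != "none":
        raise GrasstrendError(f"unknown correction '{correction}'")
    return h, a


def classify_sustainability(h: float, tol: float = 0.0):
    """H > 0.5 -> sustainable, H < 0.5 -> anti-sustainable, else random.

    Accepts a scalar (returns SustainClass) or an array (uint8 codes, 0
    where H is nodata)."""
    arr = np.asarray(h, dtype=float)
    codes = np.zeros(arr.shape, dtype=np.uint8)
    codes[arr > 0.5 + tol] = SustainClass.SUSTAINABLE
    codes[arr < 0.5 - tol] = SustainClass.ANTI_SUSTAINABLE
    codes[np.abs(arr - 0.5) <= tol] = SustainClass.RANDOM
    codes[np.isnan(arr)] = 0
    if np.isscalar(h) or arr.ndim == 0:
        if np.isnan(arr):
            raise GrasstrendError("cannot classify a non-finite Hurst exponent")
        return SustainClass(int(codes))
    return codes


@dataclass
class HurstResult:
    h: np.ndarray  # float, NaN nodata
    fit_intercept: np.ndarray  # a of the log-log fit
    sustainability: np.ndarray  # uint8 codes, 0 nodata
    tau_grid: list
    fraction_sustainable: float  # share of valid pixels with H > 0.5


def hurst_map(
    stack: RasterStack,
    tau_grid: Sequence[int] | None = None,
    tol: float = 0.0,
    correction: str = "none",
) -> HurstResult:
    """Per-pixel Hurst exponent and sustainability class over an annual stack.

    Pixels with any nodata year are nodata. The log-log fit is vectorised:
    per tau, the batch rescaled range is computed for all complete pixels at
    once; per-pixel OLS then uses only that pixel's valid (finite, positive)
    R/S points, requiring at least three.
    """
    v = stack.values
    nt, nr, nc = v.shape
    x = v.reshape(nt, -1).T  # (npix, nt)
    complete = ~np.any(np.isnan(x), axis=1)
    taus = sorted(set(int(t) for t in (tau_grid or default_tau_grid(nt))))
    taus = [t for t in taus if 2 <= t <= nt]
    if len(taus) < 3:
        raise EstimationFailedError("tau grid has fewer than 3 usable values")

    xc = x[complete]
    log_rs = np.full((len(taus), xc.shape[0]), np.nan)
    for j, t in enumerate(taus):
        rs, _ = _rs_matrix(xc, t)
        with np.errstate(invalid="ignore", divide="ignore"):
            log_rs[j] = np.where(rs > 0, np.log(np.where(rs > 0, rs, 1.0)), np.nan)
    log_tau = np.log(taus)[:, None]

    m = np.isfinite(log_rs)
    cnt = m.sum(axis=0).astype(float)
    lt = np.where(m, log_tau, 0.0)
    lr = np.where(m, log_rs, 0.0)
    st, sr = lt.sum(axis=0), lr.sum(axis=0)
    stt, srt = (lt**2).sum(axis=0), (lt * lr).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (cnt * srt - st * sr) / (cnt * stt - st**2)
        intercept = (sr - slope * st) / cnt
    bad = cnt < 3
    slope[bad] = np.nan
    intercept[bad] = np.nan

    if correction == "anis-lloyd":
        expected = _anis_lloyd_expected(np.array(taus))
        h_al, _ = _loglog_fit(np.log(taus), np.log(expected))
        slope = 0.5 + slope - h_al
    elif correction != "none":
        raise GrasstrendError(f"unknown correction '{correction}'")

    h = np.full(nr * nc, np.nan)
    a = np.full(nr * nc, np.nan)
    h[complete] = slope
    a[complete] = intercept
    h = h.reshape(nr, nc)
    a = a.reshape(nr, nc)
    sustain = classify_sustainability(h, tol=tol)
    valid = ~np.isnan(h)
    frac = float(np.mean(h[valid] > 0.5)) if valid.any() else 0.0
    return HurstResult(
        h=h,
        fit_intercept=a,
        sustainability=sustain,
        tau_grid=taus,
        fraction_sustainable=frac,
    )
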