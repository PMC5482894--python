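"""Two-parameter regression families and model selection.

Four families are fitted and compared on the original response scale:

    linear       y = a + b * x
    exponential  y = a * exp(b * x)
    log          y = a + b * ln(x)
    power        y = a * x ** b

Linear and log models are closed-form ordinary least squares. Exponential
and power models are fitted by nonlinear least squares in the original y
space, initialised from the log-transform closed form, so that R^2 and RMSE
are directly comparable across families. RMSE uses divisor n by default
(configurable via ``ddof``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitFailureError, GrasstrendError, SingularFitError


class Family(str, Enum):
    LINEAR = "linear"
    EXPONENTIAL = "exponential"
    LOG = "log"
    POWER = "power"


# simplicity preference used to break exact ties in model selection
_FAMILY_ORDER = {
    Family.LINEAR: 0,
    Family.POWER: 1,
    Family.EXPONENTIAL: 2,
    Family.LOG: 3,
}

_POSITIVE_X_FAMILIES = {Family.LOG, Family.POWER}


@dataclass(frozen=True)
class RegressionModel:
    family: Family
    a: float
    b: float
    r_squared: float
    rmse: float
    n: int
    x_domain: tuple

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "a": self.a,
            "b": self.b,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n": self.n,
            "x_domain": list(self.x_domain),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(
            family=Family(d["family"]),
            a=float(d["a"]),
            b=float(d["b"]),
            r_squared=float(d["r_squared"]),
            rmse=float(d["rmse"]),
            n=int(d["n"]),
            x_domain=tuple(d["x_domain"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RegressionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _formula(family: Family):
    if family == Family.LINEAR:
        return lambda x, a, b: a + b * x
    if family == Family.EXPONENTIAL:
        return lambda x, a, b: a * np.exp(b * x)
    if family == Family.LOG:
        return lambda x, a, b: a + b * np.log(x)
    if family == Family.POWER:
        return lambda x, a, b: a * np.power(x, b)
    raise GrasstrendError(f"unknown family {family}")


def predict(model: RegressionModel, x) -> np.ndarray:
    """Evaluate the family formula with the stored coefficients."""
    x = np.asarray(x, dtype=float)
    if model.family in _POSITIVE_X_FAMILIES:
        bad = x[np.isfinite(x) & (x <= 0)]
        if bad.size:
            raise DomainError(
                f"{model.family.value} model requires x > 0; offending values: "
                f"{np.unique(bad)[:10].tolist()}"
            )
    return _formula(model.family)(x, model.a, model.b)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS intercept/slope of y on x."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise SingularFitError("all x values identical; cannot fit")
    b = float(np.sum((x - xm) * (y - ym)) / sxx)
    return float(ym - b * xm), b


def _metrics(y: np.ndarray, yhat: np.ndarray, ddof: int = 0) -> tuple[float, float]:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    rmse = float(np.sqrt(ss_res / (len(y) - ddof)))
    return r2, rmse


def _transform_init(x: np.ndarray, y: np.ndarray, family: Family) -> tuple[float, float]:
    """Log-transform closed form used to initialise the nonlinear fit.

    Needs y > 0; otherwise falls back to a flat model a=mean(y), b=0.
    """
    if np.any(y <= 0):
        return float(np.mean(y)), 0.0
    ly = np.log(y)
    if family == Family.EXPONENTIAL:
        la, b = _ols(x, ly)
    else:  # power
        la, b = _ols(np.log(x), ly)
    return float(np.exp(la)), b


def fit_regression(
    x: Sequence[float], y: Sequence[float], family: Family, ddof: int = 0
) -> RegressionModel:
    """Fit one family to (x, y) and report R^2/RMSE on the original scale."""
    family = Family(family)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise GrasstrendError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise GrasstrendError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise SingularFitError("all x values identical; cannot fit")
    if family in _POSITIVE_X_FAMILIES and np.any(x <= 0):
        raise DomainError(f"{family.value} family requires strictly positive x")

    if family == Family.LINEAR:
        a, b = _ols(x, y)
    elif family == Family.LOG:
        a, b = _ols(np.log(x), y)
    else:
        a0, b0 = _transform_init(x, y, family)
        fallback_params = (a0, b0)
        try:
            (a, b), _ = curve_fit(
                _formula(family), x, y, p0=[a0, b0], maxfev=10000
            )
            a, b = float(a), float(b)
        except RuntimeError as exc:
            fa, fb = fallback_params
            r2, rmse = _metrics(y, _formula(family)(x, fa, fb), ddof)
            fallback = RegressionModel(
                family, fa, fb, r2, rmse, len(x), (float(x.min()), float(x.max()))
            )
            raise FitFailureError(
                f"nonlinear fit of {family.value} did not converge", fallback=fallback
            ) from exc

    r2, rmse = _metrics(y, _formula(family)(x, a, b), ddof)
    return RegressionModel(
        family=family,
        a=a,
        b=b,
        r_squared=r2,
        rmse=rmse,
        n=len(x),
        x_domain=(float(x.min()), float(x.max())),
    )


def fit_all_families(x, y, families=None, ddof: int = 0) -> list[RegressionModel]:
    """Fit every applicable family; families whose domain the data violate
    (x <= 0 for log/power) are silently dropped."""
    families = [Family(f) for f in (families or list(Family))]
    models = []
    for fam in families:
        try:
            models.append(fit_regression(x, y, fam, ddof=ddof))
        except (DomainError, FitFailureError):
            continue
    if not models:
        raise GrasstrendError("no family could be fitted to the data")
    return models


def select_best(models: Sequence[RegressionModel]) -> RegressionModel:
    """Pick the model with maximal R^2; ties broken by minimal RMSE, then by
    simplicity (linear < power < exponential < log)."""
    if not models:
        raise GrasstrendError("no candidate models to select from")
    return min(
        models, key=lambda m: (-m.r_squared, m.rmse, _FAMILY_ORDER[m.family])
    )
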