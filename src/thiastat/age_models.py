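"""Age dependence of enzyme activities: linear fits, exponential decay,
and age normalization.

The decay model treats an activity as a pseudo-first-order process,
``value(t) = value(0) * exp(-k * t)``, fitted by ordinary least squares on
log-transformed values; ``half_life = ln(2) / k``. Age normalization divides
an observed value by the cohort linear-regression prediction at that age, so
an animal exactly on the regression line maps to 1 (a residual-based
alternative is available).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InvalidInputError

NORMALIZE_MODES = ("ratio", "residual")


@dataclass(frozen=True)
class LinearAgeFit:
    slope: float
    intercept: float
    r_squared: float
    pearson_p: float
    n_points: int

    def predict(self, age: float) -> float:
        return self.intercept + self.slope * age

    def to_json(self) -> str:
        return json.dumps({"model": "linear", **asdict(self)})


@dataclass(frozen=True)
class DecayFit:
    """Pseudo-first-order decay parameters from a log-space linear fit."""

    k: float
    activity0: float
    half_life: float
    r_squared: float
    pearson_p: float
    n_points: int
    n_excluded: int = 0

    @property
    def no_decline(self) -> bool:
        return not (self.k > 0)

    def predict(self, age: float) -> float:
        return self.activity0 * math.exp(-self.k * age)

    def to_json(self) -> str:
        return json.dumps({"model": "exponential_decay", **asdict(self)})


def _validated_xy(
    pairs: Sequence[tuple[float, float]], minimum: int
) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < minimum:
        raise InvalidInputError(f"need at least {minimum} (age, value) pairs")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("ages and values must be finite")
    ages, values = arr[:, 0], arr[:, 1]
    if np.unique(ages).size < 2:
        raise InvalidInputError("ages are degenerate (all equal); cannot regress")
    return ages, values


def fit_linear_vs_age(pairs: Sequence[tuple[float, float]]) -> LinearAgeFit:
    """OLS of value on age with a two-sided Pearson correlation p-value."""
    ages, values = _validated_xy(pairs, minimum=3)
    if np.ptp(values) == 0:  # flat response: r undefined, report r^2=0
        return LinearAgeFit(
            slope=0.0, intercept=float(values[0]), r_squared=0.0,
            pearson_p=1.0, n_points=len(ages),
        )
    res = stats.linregress(ages, values)
    return LinearAgeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_p=float(res.pvalue),
        n_points=len(ages),
    )


def fit_exponential_decay(pairs: Sequence[tuple[float, float]]) -> DecayFit:
    """Fit ``value = activity0 * exp(-k*age)`` by OLS on (age, ln value).

    Non-positive values cannot be log-transformed and are excluded; the
    count is recorded on the fit. A non-negative log-slope yields k <= 0 and
    a non-finite half-life with the ``no_decline`` flag set.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("expected a sequence of (age, value) pairs")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("ages and values must be finite")
    usable = arr[arr[:, 1] > 0]
    n_excluded = arr.shape[0] - usable.shape[0]
    if usable.shape[0] < 3:
        raise InvalidInputError(
            f"need at least 3 pairs with positive values, have {usable.shape[0]}"
        )
    ages, values = usable[:, 0], usable[:, 1]
    if np.unique(ages).size < 2:
        raise InvalidInputError("ages are degenerate (all equal); cannot regress")
    res = stats.linregress(ages, np.log(values))
    k = -float(res.slope)
    half_life = math.log(2) / k if k > 0 else math.inf
    return DecayFit(
        k=k,
        activity0=float(math.exp(res.intercept)),
        half_life=half_life,
        r_squared=float(res.rvalue**2),
        pearson_p=float(res.pvalue),
        n_points=len(ages),
        n_excluded=n_excluded,
    )


def age_normalize(
    value: float, age: float, fit: LinearAgeFit, mode: str = "ratio"
) -> float:
    """Normalize a value for age against a cohort linear fit.

    ``ratio`` mode (default) returns value / predicted(age); ``residual``
    mode returns (value - predicted(age)) / |intercept|, a rescaled residual.
    """
    if mode not in NORMALIZE_MODES:
        raise InvalidInputError(
            f"unknown normalization mode {mode!r}; expected one of {NORMALIZE_MODES}"
        )
    predicted = fit.predict(age)
    if mode == "ratio":
        if not (predicted > 0):
            raise ConfigurationError(
                f"regression predicts non-positive value ({predicted:.4g}) at age "
                f"{age}; unusable for ratio normalization"
            )
        return value / predicted
    scale = abs(fit.intercept)
    if scale == 0:
        raise ConfigurationError("zero intercept; residual normalization unusable")
    return (value - predicted) / scale
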