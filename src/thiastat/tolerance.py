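"""One-sided tolerance limits used as deficiency cutoffs.

Two constructions are provided:

* parametric-normal, with the exact k factor from the noncentral-t
  distribution: ``k = nct.ppf(conf; df=n-1, nc=z_P*sqrt(n)) / sqrt(n)``;
* nonparametric, returning an order statistic whose index is the smallest
  one achieving the requested confidence under the binomial law.

Defaults follow the common reference-limit convention: content P = 0.90
covered with confidence 0.95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidInputError

SIDES = ("lower", "upper")
METHODS = ("parametric_normal", "nonparametric")


@dataclass(frozen=True)
class ToleranceSpec:
    content: float = 0.90
    confidence: float = 0.95
    side: str = "upper"
    method: str = "nonparametric"

    def __post_init__(self) -> None:
        if not (0 < self.content < 1):
            raise InvalidInputError(f"content must be in (0,1), got {self.content}")
        if not (0 < self.confidence < 1):
            raise InvalidInputError(f"confidence must be in (0,1), got {self.confidence}")
        if self.side not in SIDES:
            raise InvalidInputError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.method not in METHODS:
            raise InvalidInputError(f"method must be one of {METHODS}, got {self.method!r}")


@dataclass(frozen=True)
class ToleranceLimit:
    value: float
    spec: ToleranceSpec
    n_obs: int
    k_factor: float | None = None
    order_index: int | None = None  # 1-based from the smallest observation
    achieved_confidence: float | None = None


def normal_k_factor(n: int, content: float = 0.90, confidence: float = 0.95) -> float:
    """Exact one-sided normal tolerance factor via the noncentral t."""
    if n < 2:
        raise InvalidInputError(f"need n >= 2, got {n}")
    nc = stats.norm.ppf(content) * math.sqrt(n)
    return float(stats.nct.ppf(confidence, df=n - 1, nc=nc) / math.sqrt(n))


def normal_one_sided_limit(
    mean: float, sd: float, n: int, spec: ToleranceSpec
) -> ToleranceLimit:
    """``mean +/- k * sd`` with the exact noncentral-t k factor."""
    if not (sd > 0):
        raise InvalidInputError(f"sd must be > 0, got {sd}")
    if n < 2:
        raise InvalidInputError(f"need n >= 2, got {n}")
    k = normal_k_factor(n, spec.content, spec.confidence)
    sign = 1.0 if spec.side == "upper" else -1.0
    return ToleranceLimit(
        value=float(mean + sign * k * sd),
        spec=ToleranceSpec(spec.content, spec.confidence, spec.side, "parametric_normal"),
        n_obs=n,
        k_factor=k,
    )


def minimum_n(spec: ToleranceSpec) -> int:
    """Smallest n at which the extreme order statistic attains the confidence.

    For an upper limit at the sample maximum this is the smallest n with
    1 - P**n >= confidence (identical for the lower side by symmetry).
    """
    return int(math.ceil(math.log(1.0 - spec.confidence) / math.log(spec.content)))


def _upper_order_index(n: int, content: float, confidence: float) -> int | None:
    """Smallest 1-based m with BinomialCDF(m-1; n, content) >= confidence."""
    m_grid = np.arange(1, n + 1)
    cdf = stats.binom.cdf(m_grid - 1, n, content)
    hits = np.nonzero(cdf >= confidence)[0]
    if hits.size == 0:
        return None
    return int(m_grid[hits[0]])


def nonparametric_one_sided_limit(data, spec: ToleranceSpec) -> ToleranceLimit:
    """Distribution-free one-sided limit as an observed order statistic."""
    x = np.sort(np.asarray(list(data), dtype=float))
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("data must be finite")
    n = int(x.size)
    m_upper = _upper_order_index(n, spec.content, spec.confidence)
    if m_upper is None:
        need = minimum_n(spec)
        best = float(1.0 - spec.content**n)
        raise InvalidInputError(
            f"n={n} cannot attain confidence {spec.confidence} (needs n >= {need}; "
            f"extreme order statistic achieves only {best:.4f})"
        )
    achieved = float(stats.binom.cdf(m_upper - 1, n, spec.content))
    if spec.side == "upper":
        m = m_upper
    else:
        m = n + 1 - m_upper  # reflection symmetry
    return ToleranceLimit(
        value=float(x[m - 1]),
        spec=ToleranceSpec(spec.content, spec.confidence, spec.side, "nonparametric"),
        n_obs=n,
        order_index=m,
        achieved_confidence=achieved,
    )


def choose_method(best_fit_family: str) -> str:
    """Parametric-normal iff the AICc winner is the normal family."""
    return "parametric_normal" if best_fit_family == "normal" else "nonparametric"


def one_sided_limit(data, spec: ToleranceSpec, method: str) -> ToleranceLimit:
    """Dispatch on method; the parametric route estimates mean and sd (ddof=1)."""
    if method == "parametric_normal":
        x = np.asarray(list(data), dtype=float)
        sd = float(x.std(ddof=1))
        return normal_one_sided_limit(float(x.mean()), sd, int(x.size), spec)
    if method == "nonparametric":
        return nonparametric_one_sided_limit(data, spec)
    raise InvalidInputError(f"method must be one of {METHODS}, got {method!r}")
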