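"""Maximum-likelihood fitting of a catalog of continuous distributions and
AICc-based family selection.

The catalog covers the usual location-scale and positive-support families
plus the four-parameter sinh-arcsinh (SHASH) family and two- and
three-component normal mixtures. Families are ranked by the small-sample
corrected Akaike information criterion,

    AICc = -2 loglik + 2 k + 2 k (k + 1) / (n - k - 1).

SHASH uses the Jones-Pewsey parameterization

    X = xi + eta * sinh((asinh(Z) + eps) / delta),   Z ~ N(0, 1),

which reduces to Normal(xi, eta) at eps = 0, delta = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .errors import FitError, InvalidInputError

#: Fitting order; also the final tie-break for equal AICc and parameter count.
CATALOG = (
    "normal",
    "lognormal",
    "exponential",
    "gamma",
    "weibull",
    "shash",
    "normal_mixture2",
    "normal_mixture3",
)

POSITIVE_SUPPORT = frozenset({"lognormal", "exponential", "gamma", "weibull"})

_N_PARAMS = {
    "normal": 2,
    "lognormal": 2,
    "exponential": 1,
    "gamma": 2,
    "weibull": 2,
    "shash": 4,
    "normal_mixture2": 5,  # 3m - 1 free parameters for m components
    "normal_mixture3": 8,
}

_MIN_N = 8


@dataclass(frozen=True)
class ShashParams:
    """Jones-Pewsey sinh-arcsinh parameters."""

    location: float
    scale: float
    skewness: float
    tail_weight: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.tail_weight > 0):
            raise InvalidInputError("SHASH scale and tail_weight must be > 0")


@dataclass(frozen=True)
class DistributionFit:
    family: str
    params: dict
    loglik: float
    n_params: int
    n_obs: int
    aicc: float
    converged: bool = True
    failure_reason: str | None = field(default=None, compare=False)


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Corrected AIC; requires n_obs > n_params + 1."""
    if n_obs <= n_params + 1:
        raise InvalidInputError(
            f"AICc undefined: n_obs={n_obs} must exceed n_params+1={n_params + 1}"
        )
    return (
        -2.0 * loglik
        + 2.0 * n_params
        + 2.0 * n_params * (n_params + 1) / (n_obs - n_params - 1)
    )


# ---------------------------------------------------------------------------
# SHASH primitives


def shash_logpdf(x, location, scale, skewness, tail_weight):
    """Log-density of the sinh-arcsinh distribution."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # extreme params give -inf loglik, handled by fitters
        y = (x - location) / scale
        s = np.arcsinh(y)
        w = tail_weight * s - skewness
        z = np.sinh(w)
        return (
            stats.norm.logpdf(z)
            + np.log(tail_weight)
            + np.log(np.cosh(w))
            - np.log(scale)
            - 0.5 * np.log1p(y * y)
        )


def shash_ppf(q, location, scale, skewness, tail_weight):
    """Quantile function (closed form via the normal quantile)."""
    z = stats.norm.ppf(q)
    return location + scale * np.sinh((np.arcsinh(z) + skewness) / tail_weight)


def shash_rvs(location, scale, skewness, tail_weight, size, rng):
    z = rng.standard_normal(size)
    return location + scale * np.sinh((np.arcsinh(z) + skewness) / tail_weight)


def _fit_shash(data: np.ndarray, rng: np.random.Generator) -> tuple[dict, float, bool]:
    """Multi-start quasi-Newton MLE on (xi, log eta, eps, log delta)."""

    def nll(theta):
        xi, log_eta, eps, log_delta = theta
        ll = shash_logpdf(data, xi, math.exp(log_eta), eps, math.exp(log_delta))
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(ll.sum())

    center = float(np.median(data))
    spread = float(np.std(data)) or 1.0
    starts = [np.array([center, math.log(spread), 0.0, 0.0])]
    for _ in range(7):
        starts.append(
            np.array(
                [
                    center + spread * rng.normal(scale=0.5),
                    math.log(spread) + rng.normal(scale=0.5),
                    rng.normal(scale=0.5),
                    rng.normal(scale=0.3),
                ]
            )
        )
    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or res.success
    xi, log_eta, eps, log_delta = best.x
    params = {
        "location": float(xi),
        "scale": float(math.exp(log_eta)),
        "skewness": float(eps),
        "tail_weight": float(math.exp(log_delta)),
    }
    return params, -float(best.fun), any_success


# ---------------------------------------------------------------------------
# Per-family fitters


def _fit_mixture(
    data: np.ndarray, m: int, rng: np.random.Generator, n_restarts: int = 20
) -> tuple[dict, float, bool]:
    # sigma floor guards against degenerate spikes on repeated values
    floor = max(1e-4 * float(np.std(data)), 1e-12) ** 2
    gm = GaussianMixture(
        n_components=m,
        covariance_type="spherical",
        n_init=n_restarts,
        init_params="kmeans",
        tol=1e-8,
        reg_covar=floor,
        max_iter=500,
        random_state=np.random.RandomState(int(rng.integers(2**31 - 1))),
    )
    X = data.reshape(-1, 1)
    import warnings

    with warnings.catch_warnings():
        # non-convergence is reported via converged_, not as noise on stderr
        warnings.simplefilter("ignore")
        gm.fit(X)
    order = np.argsort(gm.means_.ravel())
    params = {
        "weights": gm.weights_[order].tolist(),
        "means": gm.means_.ravel()[order].tolist(),
        "sds": np.sqrt(gm.covariances_[order]).tolist(),
    }
    loglik = float(gm.score(X) * len(data))
    return params, loglik, bool(gm.converged_)


def mixture_logpdf(x, weights, means, sds):
    """Log-density of a normal mixture."""
    from scipy.special import logsumexp

    x = np.asarray(x, dtype=float)[:, None]
    comp = stats.norm.logpdf(x, loc=np.asarray(means), scale=np.asarray(sds))
    return logsumexp(comp + np.log(np.asarray(weights)), axis=1)


def fit_family(
    data,
    family: str,
    random_state: int | np.random.Generator | None = None,
    n_restarts: int = 20,
) -> DistributionFit:
    """ML fit of a single family.

    Closed-form estimates where they exist (normal, lognormal, exponential),
    scipy numerical MLE for gamma/weibull, seeded multi-start optimisation
    for SHASH, and EM (k-means init, 20 restarts) for the normal mixtures.
    Positivity violations for positive-support families and optimizer
    non-convergence are reported on the returned fit, not raised.
    """
    if family not in CATALOG:
        raise InvalidInputError(f"unknown family {family!r}; catalog: {CATALOG}")
    x = np.asarray(list(data), dtype=float)
    if x.size < _MIN_N:
        raise InvalidInputError(f"need at least {_MIN_N} observations, have {x.size}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("data must be finite")
    n = int(x.size)
    k = _N_PARAMS[family]
    rng = np.random.default_rng(random_state)

    def failed(reason: str) -> DistributionFit:
        return DistributionFit(
            family=family, params={}, loglik=math.nan, n_params=k, n_obs=n,
            aicc=math.inf, converged=False, failure_reason=reason,
        )

    if family in POSITIVE_SUPPORT and np.any(x <= 0):
        return failed("requires strictly positive data")

    converged = True
    if family == "normal":
        mu, sigma = float(x.mean()), float(x.std())  # ML uses 1/n
        if sigma == 0:
            return failed("zero variance")
        params = {"mean": mu, "sd": sigma}
        loglik = float(stats.norm.logpdf(x, mu, sigma).sum())
    elif family == "lognormal":
        lx = np.log(x)
        mu, sigma = float(lx.mean()), float(lx.std())
        if sigma == 0:
            return failed("zero variance on log scale")
        params = {"log_mean": mu, "log_sd": sigma}
        loglik = float(stats.lognorm.logpdf(x, s=sigma, scale=math.exp(mu)).sum())
    elif family == "exponential":
        rate = 1.0 / float(x.mean())
        params = {"rate": rate}
        loglik = float(stats.expon.logpdf(x, scale=1.0 / rate).sum())
    elif family == "gamma":
        try:
            shape, _, scale = stats.gamma.fit(x, floc=0)
        except Exception as exc:  # scipy can fail on pathological data
            return failed(f"optimizer failure: {exc}")
        params = {"shape": float(shape), "scale": float(scale)}
        loglik = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
    elif family == "weibull":
        try:
            shape, _, scale = stats.weibull_min.fit(x, floc=0)
        except Exception as exc:
            return failed(f"optimizer failure: {exc}")
        params = {"shape": float(shape), "scale": float(scale)}
        loglik = float(stats.weibull_min.logpdf(x, shape, scale=scale).sum())
    elif family == "shash":
        if float(np.std(x)) == 0:
            return failed("zero variance")
        params, loglik, converged = _fit_shash(x, rng)
        if not converged:
            return failed("optimizer did not converge from any start")
    else:  # normal mixtures
        m = 2 if family == "normal_mixture2" else 3
        if np.unique(x).size < m:
            return failed(f"fewer than {m} distinct values")
        try:
            params, loglik, converged = _fit_mixture(x, m, rng, n_restarts)
        except Exception as exc:
            return failed(f"EM failure: {exc}")
        if not converged:
            return failed("EM did not converge")

    if not math.isfinite(loglik):
        return failed("non-finite log-likelihood")
    return DistributionFit(
        family=family, params=params, loglik=loglik, n_params=k, n_obs=n,
        aicc=aicc(loglik, k, n), converged=True,
    )


def select_best(
    data,
    families: tuple[str, ...] | list[str] | None = None,
    random_state: int | np.random.Generator | None = None,
    n_restarts: int = 20,
) -> list[DistributionFit]:
    """Fit every requested family and rank by ascending AICc.

    Ties break by fewer parameters, then catalog order. Failed fits are
    kept at the end of the list (aicc = inf) for provenance; if every fit
    fails a :class:`FitError` naming each reason is raised.
    """
    families = tuple(families) if families is not None else CATALOG
    unknown = set(families) - set(CATALOG)
    if unknown:
        raise InvalidInputError(f"unknown families {sorted(unknown)}")
    rng = np.random.default_rng(random_state)
    fits = [fit_family(data, fam, rng, n_restarts=n_restarts) for fam in families]
    ok = [f for f in fits if f.converged]
    if not ok:
        reasons = "; ".join(f"{f.family}: {f.failure_reason}" for f in fits)
        raise FitError(f"all distribution fits failed ({reasons})")
    fits.sort(key=lambda f: (f.aicc, f.n_params, CATALOG.index(f.family)))
    return fits


def ranking_table(fits: list[DistributionFit]):
    """Ranking as a DataFrame (family, loglik, AICc, delta AICc, converged)."""
    import pandas as pd

    best = min((f.aicc for f in fits if f.converged), default=math.nan)
    return pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "params": [repr(f.params) for f in fits],
            "loglik": [f.loglik for f in fits],
            "n_params": [f.n_params for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta_aicc": [f.aicc - best for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
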