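"""Erythrocyte enzyme kinetics: specific activities and B1 activation indices.

Raw spectrophotometric rates (dA340/min) are converted to specific activities
(U/mg protein, 1 U = 1 umol/min) using the NADH extinction coefficient, and
transketolase activities measured at three thiamine-diphosphate (TDP) levels
are combined into the classic activation indices:

* ``par`` — primary activation ratio, activity at 0.3 mM TDP over basal.
* ``far`` — further activation ratio, activity at 3 mM over 0.3 mM TDP.
* ``sar`` — selective activation ratio, ``far / par``.
* ``sad`` — selective activation difference, ``far - par``.
* ``latency`` — percent stimulation by 0.3 mM TDP (pluggable formula).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

#: NADH molar extinction coefficient at 340 nm, per mM per cm.
EXTINCTION_MM = 6.22

#: Assumed cuvette path length, cm.
PATH_LENGTH_CM = 1.0

#: TDP concentrations (mM) at which transketolase is assayed.
ALLOWED_TDP_LEVELS = (0.0, 0.3, 3.0)

#: Default replicate coefficient-of-variation QC threshold, percent.
CV_QC_THRESHOLD = 15.0

#: Latency formula names accepted by :func:`compute_b1_indices`.
LATENCY_FORMULAS = ("baseline", "stimulated")


@dataclass(frozen=True)
class KineticReading:
    """One enzyme assay: replicate rates plus the protein normalisation.

    ``tdp_level`` is the in-vitro TDP concentration in mM for transketolase
    readings and ``None`` for glutathione-reductase readings.
    """

    replicate_rates: tuple[float, ...]
    protein_conc: float
    dilution_factor: float = 1.0
    tdp_level: float | None = None

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.replicate_rates)
        if len(rates) == 0:
            raise InvalidInputError("at least one replicate rate is required")
        if not all(math.isfinite(r) for r in rates):
            raise InvalidInputError(f"non-finite replicate rate in {rates}")
        if not (self.protein_conc > 0):
            raise InvalidInputError(
                f"protein concentration must be > 0, got {self.protein_conc}"
            )
        if self.dilution_factor < 1:
            raise InvalidInputError(
                f"dilution factor must be >= 1, got {self.dilution_factor}"
            )
        if self.tdp_level is not None and self.tdp_level not in ALLOWED_TDP_LEVELS:
            raise InvalidInputError(
                f"tdp_level must be one of {ALLOWED_TDP_LEVELS}, got {self.tdp_level}"
            )
        object.__setattr__(self, "replicate_rates", rates)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean rate and replicate scatter; ``cv_percent`` is None when undefined."""

    mean: float
    cv_percent: float | None
    n: int

    def exceeds(self, threshold: float = CV_QC_THRESHOLD) -> bool:
        """True when the CV is defined and above the QC threshold."""
        return self.cv_percent is not None and self.cv_percent > threshold


@dataclass(frozen=True)
class ActivityProfile:
    """Specific activities (U/mg): transketolase at 0 / 0.3 / 3 mM TDP plus GR."""

    a0: float
    a03: float
    a3: float
    gr: float


@dataclass(frozen=True)
class B1Indices:
    """The five derived B1 indices; all NaN with a diagnostic when undefined."""

    par: float
    far: float
    sar: float
    sad: float
    latency: float
    diagnostic: str | None = field(default=None, compare=False)

    @property
    def valid(self) -> bool:
        return self.diagnostic is None


def specific_activity(
    rate: float,
    protein_conc: float,
    dilution_factor: float = 1.0,
    *,
    extinction_mM: float = EXTINCTION_MM,
    path_length_cm: float = PATH_LENGTH_CM,
) -> float:
    """Convert a kinetic rate (dA340/min) to specific activity in U/mg.

    ``(rate / (extinction * path)) * dilution / protein_conc`` with the
    defaults 6.22 (mM cm)^-1 and a 1 cm path. Negative rates are allowed
    (QC handles them upstream); non-positive protein is an error.
    """
    if not (protein_conc > 0):
        raise InvalidInputError(f"protein concentration must be > 0, got {protein_conc}")
    if not math.isfinite(rate):
        raise InvalidInputError(f"rate must be finite, got {rate}")
    return (rate / (extinction_mM * path_length_cm)) * dilution_factor / protein_conc


def aggregate_replicates(rates: Sequence[float]) -> ReplicateSummary:
    """Arithmetic mean and CV% of technical replicates.

    CV uses the sample standard deviation (ddof=1) and is reported as missing
    (None) for a single replicate or a zero mean.
    """
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot aggregate an empty replicate list")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"non-finite replicate rate in {list(arr)}")
    mean = float(arr.mean())
    if arr.size < 2 or mean == 0.0:
        cv = None
    else:
        cv = float(100.0 * arr.std(ddof=1) / abs(mean))
    return ReplicateSummary(mean=mean, cv_percent=cv, n=int(arr.size))


def _latency(a0: float, a03: float, formula: str) -> float:
    if formula == "baseline":
        return 100.0 * (a03 - a0) / a0
    if formula == "stimulated":
        return 100.0 * (a03 - a0) / a03
    raise InvalidInputError(
        f"unknown latency formula {formula!r}; expected one of {LATENCY_FORMULAS}"
    )


def compute_b1_indices(
    profile: ActivityProfile, latency_formula: str = "baseline"
) -> B1Indices:
    """Derive the activation indices from a full transketolase profile.

    Requires positive basal (``a0``) and 0.3 mM (``a03``) activities; when
    either is non-positive the indices are returned as NaN with a diagnostic
    rather than silently propagating NaN.
    """
    if latency_formula not in LATENCY_FORMULAS:
        raise InvalidInputError(
            f"unknown latency formula {latency_formula!r}; expected one of "
            f"{LATENCY_FORMULAS}"
        )
    if not (profile.a0 > 0 and profile.a03 > 0):
        return B1Indices(
            par=math.nan,
            far=math.nan,
            sar=math.nan,
            sad=math.nan,
            latency=math.nan,
            diagnostic=(
                f"non-positive activity: a0={profile.a0}, a03={profile.a03}"
            ),
        )
    par = profile.a03 / profile.a0
    far = profile.a3 / profile.a03
    return B1Indices(
        par=par,
        far=far,
        sar=far / par,
        sad=far - par,
        latency=_latency(profile.a0, profile.a03, latency_formula),
    )


def profile_from_readings(
    tkt_readings: Sequence[KineticReading],
    gr_reading: KineticReading,
    *,
    cv_threshold: float = CV_QC_THRESHOLD,
    extinction_mM: float = EXTINCTION_MM,
    path_length_cm: float = PATH_LENGTH_CM,
) -> tuple[ActivityProfile, list[str]]:
    """Aggregate raw readings into an :class:`ActivityProfile` plus QC flags.

    Replicates are averaged first and the mean rate is converted to a
    specific activity. Returns the profile and a list of QC flag strings
    (high replicate CV, negative rates); flags never raise.
    """
    by_level: dict[float, KineticReading] = {}
    for reading in tkt_readings:
        if reading.tdp_level is None:
            raise InvalidInputError("transketolase readings must carry a tdp_level")
        if reading.tdp_level in by_level:
            raise InvalidInputError(f"duplicate reading at TDP {reading.tdp_level} mM")
        by_level[reading.tdp_level] = reading
    missing = set(ALLOWED_TDP_LEVELS) - set(by_level)
    if missing:
        raise InvalidInputError(f"missing transketolase readings at TDP {sorted(missing)} mM")

    flags: list[str] = []

    def _activity(reading: KineticReading, label: str) -> float:
        summary = aggregate_replicates(reading.replicate_rates)
        if summary.exceeds(cv_threshold):
            flags.append(f"{label}: replicate CV {summary.cv_percent:.1f}% > {cv_threshold}%")
        if summary.mean < 0:
            flags.append(f"{label}: negative mean rate {summary.mean:.4g} retained")
        return specific_activity(
            summary.mean,
            reading.protein_conc,
            reading.dilution_factor,
            extinction_mM=extinction_mM,
            path_length_cm=path_length_cm,
        )

    profile = ActivityProfile(
        a0=_activity(by_level[0.0], "tkt@0mM"),
        a03=_activity(by_level[0.3], "tkt@0.3mM"),
        a3=_activity(by_level[3.0], "tkt@3mM"),
        gr=_activity(gr_reading, "gr"),
    )
    return profile, flags
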