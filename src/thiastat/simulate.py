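"""Synthetic cohort generator.

Emulates the statistical structure needed to exercise every pipeline stage
offline: ages from a truncated three-component normal mixture, a discretized
sinh-arcsinh body-condition score centered at 5, a ~44:16 female:male split,
enzyme activities declining exponentially with age at configurable
half-lives (defaults 8.7, 10.7 and 43.3 years for basal transketolase,
TDP-stimulated transketolase and glutathione reductase), and planted
deficiency endophenotypes (low-TDP and high-TDP B1 subtypes plus one B2
case) injected multiplicatively on the activities.

Healthy activation-index baselines are invented defaults (no published
healthy raw values exist); everything is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assay import EXTINCTION_MM
from .distributions import shash_rvs
from .errors import ConfigurationError, InvalidInputError

OBSERVABLE_COLUMNS = (
    "cat_id", "sex", "age_years", "bcs",
    "stkt_u_mg", "tkt_tdp03_u_mg", "tkt_tdp3_u_mg", "gr_u_mg",
)
TRUTH_COLUMNS = ("truth_status", "truth_subtype")


@dataclass(frozen=True)
class AgeMixture:
    weights: tuple[float, ...] = (0.30, 0.30, 0.40)
    means: tuple[float, ...] = (1.7, 4.5, 9.5)
    sds: tuple[float, ...] = (0.5, 1.3, 3.0)
    lower: float = 1.0
    upper: float = 17.0


@dataclass(frozen=True)
class BcsLaw:
    """SHASH parameters, discretized to integers and clipped to 1-9."""

    location: float = 4.8
    scale: float = 0.85
    skewness: float = 0.35
    tail_weight: float = 1.2


@dataclass(frozen=True)
class DeficiencyPlan:
    n_b1_low_tdp: int = 8
    n_b1_high_tdp: int = 7
    n_b2: int = 1
    low_tdp_factor: float = 0.5  # multiplies basal activity (raises PAR, latency)
    high_tdp_factor: float = 2.0  # multiplies 3 mM activity (raises FAR, SAR, SAD)
    b2_factor: float = 0.4  # multiplies GR activity

    @property
    def total(self) -> int:
        return self.n_b1_low_tdp + self.n_b1_high_tdp + self.n_b2


@dataclass(frozen=True)
class CohortConfig:
    n_animals: int = 60
    seed: int = 0
    female_fraction: float = 44 / 60
    age_mixture: AgeMixture = field(default_factory=AgeMixture)
    bcs_law: BcsLaw = field(default_factory=BcsLaw)
    # specific activities (U/mg) extrapolated to age 0
    stkt_base: float = 0.25
    par_center: float = 1.25
    far_center: float = 1.15
    far_sd: float = 0.07
    gr_base: float = 6.0
    half_lives_years: dict = field(
        default_factory=lambda: {"stkt": 8.7, "tkt_tdp": 10.7, "gr": 43.3}
    )
    noise_sigma_log: float = 0.2
    ratio_jitter_sigma_log: float = 0.05  # decorrelates basal vs stimulated TKT
    deficiency_plan: DeficiencyPlan = field(default_factory=DeficiencyPlan)
    round_ages: bool = False

    def validate(self) -> None:
        problems = []
        if self.n_animals < 1:
            problems.append("n_animals must be >= 1")
        if not np.isclose(sum(self.age_mixture.weights), 1.0):
            problems.append("age mixture weights must sum to 1")
        if len({len(self.age_mixture.weights), len(self.age_mixture.means),
                len(self.age_mixture.sds)}) != 1:
            problems.append("age mixture component lengths differ")
        if any(h <= 0 for h in self.half_lives_years.values()):
            problems.append("half-lives must be > 0")
        if not (0 <= self.female_fraction <= 1):
            problems.append("female_fraction must be in [0, 1]")
        if self.deficiency_plan.total > self.n_animals:
            problems.append("planted deficiency counts exceed n_animals")
        if min(self.stkt_base, self.gr_base, self.par_center, self.far_center) <= 0:
            problems.append("activity bases and index centers must be > 0")
        if self.noise_sigma_log < 0 or self.ratio_jitter_sigma_log < 0:
            problems.append("noise sigmas must be >= 0")
        if problems:
            raise ConfigurationError("; ".join(problems))


@dataclass(frozen=True)
class SyntheticCohort:
    table: pd.DataFrame
    config: CohortConfig

    @property
    def observable(self) -> pd.DataFrame:
        return self.table[list(OBSERVABLE_COLUMNS)].copy()


def _sample_truncated_mixture(mix: AgeMixture, n: int, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = (n - filled) * 2 + 8
        comp = rng.choice(len(mix.weights), size=m, p=np.asarray(mix.weights))
        draw = rng.normal(np.asarray(mix.means)[comp], np.asarray(mix.sds)[comp])
        keep = draw[(draw >= mix.lower) & (draw <= mix.upper)]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def generate(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort table; byte-identical for the same config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_animals

    ages = _sample_truncated_mixture(config.age_mixture, n, rng)
    if config.round_ages:
        ages = np.clip(np.round(ages), config.age_mixture.lower, config.age_mixture.upper)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    bcs_raw = shash_rvs(
        config.bcs_law.location, config.bcs_law.scale,
        config.bcs_law.skewness, config.bcs_law.tail_weight, n, rng,
    )
    bcs = np.clip(np.rint(bcs_raw), 1, 9).astype(int)

    hl = config.half_lives_years
    common = np.exp(rng.normal(0.0, config.noise_sigma_log, n))
    jitter0 = np.exp(rng.normal(0.0, config.ratio_jitter_sigma_log, n))
    jitter03 = np.exp(rng.normal(0.0, config.ratio_jitter_sigma_log, n))
    a0 = config.stkt_base * 2.0 ** (-ages / hl["stkt"]) * common * jitter0
    a03 = (
        config.stkt_base * config.par_center
        * 2.0 ** (-ages / hl["tkt_tdp"]) * common * jitter03
    )
    far = config.far_center + (
        rng.normal(0.0, config.far_sd, n) if config.far_sd > 0 else 0.0
    )
    far = np.clip(far, 0.5, None)
    a3 = a03 * far
    gr = config.gr_base * 2.0 ** (-ages / hl["gr"]) * np.exp(
        rng.normal(0.0, config.noise_sigma_log, n)
    )

    plan = config.deficiency_plan
    status = np.array(["healthy"] * n, dtype=object)
    subtype = np.array(["none"] * n, dtype=object)
    chosen = rng.choice(n, size=plan.total, replace=False)
    low_ids = chosen[: plan.n_b1_low_tdp]
    high_ids = chosen[plan.n_b1_low_tdp: plan.n_b1_low_tdp + plan.n_b1_high_tdp]
    b2_ids = chosen[plan.n_b1_low_tdp + plan.n_b1_high_tdp:]
    a0[low_ids] *= plan.low_tdp_factor
    status[low_ids], subtype[low_ids] = "B1_deficient", "low_TDP"
    a3[high_ids] *= plan.high_tdp_factor
    status[high_ids], subtype[high_ids] = "B1_deficient", "high_TDP"
    gr[b2_ids] *= plan.b2_factor
    status[b2_ids], subtype[b2_ids] = "B2_deficient", "none"

    table = pd.DataFrame(
        {
            "cat_id": [f"cat{i + 1:03d}" for i in range(n)],
            "sex": sex,
            "age_years": ages,
            "bcs": bcs,
            "stkt_u_mg": a0,
            "tkt_tdp03_u_mg": a03,
            "tkt_tdp3_u_mg": a3,
            "gr_u_mg": gr,
            "truth_status": status,
            "truth_subtype": subtype,
        }
    )
    return SyntheticCohort(table=table, config=config)


def to_raw_schema(cohort: SyntheticCohort, protein_mg_ml: float = 2.0,
                  dilution: float = 1.0, replicate_cv: float = 0.02) -> pd.DataFrame:
    """Re-express activities as triplicate kinetic rates (raw input schema).

    Rates invert the specific-activity formula at the given protein
    concentration; replicate jitter is multiplicative lognormal with the
    given log-sigma, seeded from the cohort seed for reproducibility.
    """
    rng = np.random.default_rng(cohort.config.seed + 10_000)
    t = cohort.table
    n = len(t)
    out = t[["cat_id", "sex", "age_years", "bcs"]].copy()
    for col, prefix in (
        ("stkt_u_mg", "tkt_rate_0"),
        ("tkt_tdp03_u_mg", "tkt_rate_03"),
        ("tkt_tdp3_u_mg", "tkt_rate_3"),
        ("gr_u_mg", "gr_rate"),
    ):
        mean_rate = t[col].to_numpy() * EXTINCTION_MM * protein_mg_ml / dilution
        for rep in (1, 2, 3):
            out[f"{prefix}_rep{rep}"] = mean_rate * np.exp(
                rng.normal(0.0, replicate_cv, n)
            )
    out["protein_mg_ml"] = protein_mg_ml
    out["dilution"] = dilution
    for col in TRUTH_COLUMNS:
        out[col] = t[col]
    return out


def truth_evaluation(calls, cohort: SyntheticCohort) -> dict:
    """Sensitivity/specificity of deficiency calls against planted truth."""
    truth = cohort.table.set_index("cat_id")
    call_ids = {c.cat_id for c in calls}
    if call_ids != set(truth.index):
        raise InvalidInputError("call ids do not match cohort ids")

    def _rates(truth_pos, pred_pos):
        tp = sum(1 for c in calls if truth_pos(c.cat_id) and pred_pos(c))
        fn = sum(1 for c in calls if truth_pos(c.cat_id) and not pred_pos(c))
        fp = sum(1 for c in calls if not truth_pos(c.cat_id) and pred_pos(c))
        tn = sum(1 for c in calls if not truth_pos(c.cat_id) and not pred_pos(c))
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return {"tp": tp, "fn": fn, "fp": fp, "tn": tn,
                "sensitivity": sens, "specificity": spec}

    return {
        "any_deficient": _rates(
            lambda i: truth.at[i, "truth_status"] != "healthy",
            lambda c: c.status != "not_deficient",
        ),
        "low_TDP": _rates(
            lambda i: truth.at[i, "truth_subtype"] == "low_TDP",
            lambda c: c.status == "B1_deficient" and c.subtype == "low_TDP",
        ),
        "high_TDP": _rates(
            lambda i: truth.at[i, "truth_subtype"] == "high_TDP",
            lambda c: c.status == "B1_deficient" and c.subtype == "high_TDP",
        ),
        "B2": _rates(
            lambda i: truth.at[i, "truth_status"] == "B2_deficient",
            lambda c: c.status == "B2_deficient",
        ),
    }


def with_overrides(config: CohortConfig, **kwargs) -> CohortConfig:
    """Convenience wrapper around dataclasses.replace with validation."""
    new = replace(config, **kwargs)
    new.validate()
    return new
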