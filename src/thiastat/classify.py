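"""Cohort cutoff derivation and per-animal deficiency classification.

Eight markers are thresholded: the three age-normalized activities
(basal transketolase, transketolase with 0.3 mM TDP, glutathione reductase)
and the five activation indices. For each marker the distribution catalog is
fitted, the AICc winner decides between the parametric-normal and
nonparametric tolerance limit, and the limit is taken on the configured side.

Classification rules:

* any abnormal B1 marker -> ``B1_deficient``; subtype ``low_TDP`` for
  {agenorm_stkt, agenorm_tkt_tdp, par, latency}, ``high_TDP`` for
  {far, sar, sad};
* abnormal ``agenorm_gr`` alone -> ``B2_deficient``;
* abnormal in both a B1 marker and GR -> B1 with a co-flag note.

Comparisons are strict, so a nonparametric cutoff (an observed data point)
never flags itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import CATALOG, select_best
from .errors import InvalidInputError
from .tolerance import ToleranceLimit, ToleranceSpec, choose_method, one_sided_limit

MARKERS = (
    "agenorm_stkt",
    "agenorm_tkt_tdp",
    "agenorm_gr",
    "par",
    "latency",
    "far",
    "sar",
    "sad",
)

#: Default side per marker: deficiency lowers the normalized activities and
#: raises the activation indices (the normalized TDP-stimulated activity is
#: bounded from above as configured).
DEFAULT_SIDES = {
    "agenorm_stkt": "lower",
    "agenorm_gr": "lower",
    "agenorm_tkt_tdp": "upper",
    "par": "upper",
    "latency": "upper",
    "far": "upper",
    "sar": "upper",
    "sad": "upper",
}

LOW_TDP_MARKERS = ("agenorm_stkt", "agenorm_tkt_tdp", "par", "latency")
HIGH_TDP_MARKERS = ("far", "sar", "sad")
B1_MARKERS = LOW_TDP_MARKERS + HIGH_TDP_MARKERS


@dataclass(frozen=True)
class MarkerThreshold:
    marker: str
    limit: ToleranceLimit
    side: str
    method: str
    best_family: str

    def is_abnormal(self, value: float) -> bool:
        if value is None or not math.isfinite(value):
            return False
        if self.side == "upper":
            return value > self.limit.value
        return value < self.limit.value


@dataclass(frozen=True)
class ThresholdSet:
    thresholds: dict[str, MarkerThreshold]
    rankings: dict[str, list] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        missing = set(MARKERS) - set(self.thresholds)
        if missing:
            raise InvalidInputError(f"thresholds missing for markers {sorted(missing)}")

    def __getitem__(self, marker: str) -> MarkerThreshold:
        return self.thresholds[marker]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for marker in MARKERS:
            t = self.thresholds[marker]
            rows.append(
                {
                    "marker": marker,
                    "method": t.method,
                    "side": t.side,
                    "content": t.limit.spec.content,
                    "confidence": t.limit.spec.confidence,
                    "n": t.limit.n_obs,
                    "limit": t.limit.value,
                    "k_factor": t.limit.k_factor,
                    "order_index": t.limit.order_index,
                    "achieved_confidence": t.limit.achieved_confidence,
                    "best_family": t.best_family,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeficiencyCall:
    cat_id: str
    flags: dict[str, bool]
    status: str  # not_deficient | B1_deficient | B2_deficient
    subtype: str  # low_TDP | high_TDP | none
    markers_triggered: tuple[str, ...]
    notes: tuple[str, ...] = field(default=())


def derive_thresholds(
    cohort_markers: pd.DataFrame,
    content: float = 0.90,
    confidence: float = 0.95,
    sides: dict[str, str] | None = None,
    families: tuple[str, ...] | None = None,
    random_state: int | None = 0,
) -> ThresholdSet:
    """Fit the catalog per marker and derive the one-sided cutoffs.

    Rows with missing values are dropped per marker. Failures (too few
    animals, zero variance) propagate with the marker name attached.
    """
    sides = {**DEFAULT_SIDES, **(sides or {})}
    families = families if families is not None else CATALOG
    thresholds: dict[str, MarkerThreshold] = {}
    rankings: dict[str, list] = {}
    for marker in MARKERS:
        if marker not in cohort_markers.columns:
            raise InvalidInputError(f"marker column {marker!r} missing from table")
        values = cohort_markers[marker].dropna().to_numpy(dtype=float)
        if values.size and float(np.std(values)) == 0.0:
            raise InvalidInputError(
                f"threshold derivation failed for {marker!r}: zero variance (sd = 0)"
            )
        try:
            ranking = select_best(values, families, random_state=random_state)
            best = ranking[0]
            method = choose_method(best.family)
            spec = ToleranceSpec(content, confidence, sides[marker], method)
            limit = one_sided_limit(values, spec, method)
        except Exception as exc:
            raise InvalidInputError(f"threshold derivation failed for {marker!r}: {exc}") from exc
        thresholds[marker] = MarkerThreshold(
            marker=marker, limit=limit, side=sides[marker], method=method,
            best_family=best.family,
        )
        rankings[marker] = ranking
    return ThresholdSet(thresholds, rankings=rankings)


def classify(animal_markers: dict, thresholds: ThresholdSet) -> DeficiencyCall:
    """Flag one animal against the cohort thresholds (deterministic).

    Missing marker values are non-informative: they cannot trigger a flag
    and are recorded in the call's notes.
    """
    cat_id = str(animal_markers.get("cat_id", ""))
    flags: dict[str, bool] = {}
    notes: list[str] = []
    for marker in MARKERS:
        value = animal_markers.get(marker)
        if value is None or (isinstance(value, float) and not math.isfinite(value)):
            flags[marker] = False
            notes.append(f"{marker}: missing, not testable")
            continue
        flags[marker] = thresholds[marker].is_abnormal(float(value))

    triggered = tuple(m for m in MARKERS if flags[m])
    b1_triggered = [m for m in B1_MARKERS if flags[m]]
    gr_flag = flags["agenorm_gr"]

    if b1_triggered:
        status = "B1_deficient"
        low = any(flags[m] for m in LOW_TDP_MARKERS)
        high = any(flags[m] for m in HIGH_TDP_MARKERS)
        if low and high:
            subtype = "low_TDP"
            notes.append("both low- and high-TDP markers abnormal; subtype set by low-TDP priority")
        else:
            subtype = "low_TDP" if low else "high_TDP"
        if gr_flag:
            notes.append("co-flagged on agenorm_gr (B2 marker) alongside B1 markers")
    elif gr_flag:
        status, subtype = "B2_deficient", "none"
    else:
        status, subtype = "not_deficient", "none"

    return DeficiencyCall(
        cat_id=cat_id,
        flags=flags,
        status=status,
        subtype=subtype,
        markers_triggered=triggered,
        notes=tuple(notes),
    )


def classify_cohort(
    cohort_markers: pd.DataFrame, thresholds: ThresholdSet
) -> list[DeficiencyCall]:
    records = cohort_markers.to_dict("records")
    return [classify(rec, thresholds) for rec in records]


def calls_to_frame(calls: list[DeficiencyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"cat_id": c.cat_id, "status": c.status, "subtype": c.subtype,
               "markers_triggered": ";".join(c.markers_triggered),
               "notes": ";".join(c.notes)}
        row.update({f"flag_{m}": c.flags[m] for m in MARKERS})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_calls(
    calls: list[DeficiencyCall], covariates: pd.DataFrame | None = None
) -> dict:
    """Cohort-level summary: counts by status/subtype, most frequent
    triggering marker per subtype, and (optionally) demographics of the
    flagged group from a covariate table keyed by ``cat_id``."""
    if not calls:
        raise InvalidInputError("need at least one call to summarize")
    status_counts = {s: 0 for s in ("not_deficient", "B1_deficient", "B2_deficient")}
    subtype_counts = {"low_TDP": 0, "high_TDP": 0}
    marker_counts: dict[str, dict[str, int]] = {
        "low_TDP": {m: 0 for m in LOW_TDP_MARKERS},
        "high_TDP": {m: 0 for m in HIGH_TDP_MARKERS},
    }
    flagged_ids = []
    for c in calls:
        status_counts[c.status] += 1
        if c.subtype in subtype_counts:
            subtype_counts[c.subtype] += 1
        if c.status != "not_deficient":
            flagged_ids.append(c.cat_id)
        for m in LOW_TDP_MARKERS:
            if c.flags.get(m):
                marker_counts["low_TDP"][m] += 1
        for m in HIGH_TDP_MARKERS:
            if c.flags.get(m):
                marker_counts["high_TDP"][m] += 1

    def _top(counts: dict[str, int]):
        if max(counts.values(), default=0) == 0:
            return None
        return max(counts, key=lambda m: (counts[m], m))

    summary = {
        "n_calls": len(calls),
        "n_flagged": len(flagged_ids),
        "status_counts": status_counts,
        "subtype_counts": subtype_counts,
        "marker_counts": marker_counts,
        "top_marker": {k: _top(v) for k, v in marker_counts.items()},
        "flagged_ids": flagged_ids,
    }
    if covariates is not None and flagged_ids:
        sub = covariates[covariates["cat_id"].astype(str).isin(flagged_ids)]
        demo = {}
        if "age_years" in sub:
            demo["age_mean"] = float(sub["age_years"].mean())
            demo["age_sd"] = float(sub["age_years"].std(ddof=1)) if len(sub) > 1 else math.nan
        if "bcs" in sub:
            demo["bcs_mean"] = float(sub["bcs"].mean())
        if "sex" in sub:
            demo["pct_female"] = float(100.0 * (sub["sex"] == "F").mean())
        summary["flagged_demographics"] = demo
    return summary
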