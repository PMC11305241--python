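import numpy as np
import pandas as pd
import pytest

from thiastat.classify import (
    DEFAULT_SIDES,
    HIGH_TDP_MARKERS,
    LOW_TDP_MARKERS,
    MARKERS,
    MarkerThreshold,
    ThresholdSet,
    classify,
    classify_cohort,
    derive_thresholds,
    summarize_calls,
)
from thiastat.errors import InvalidInputError
from thiastat.tolerance import ToleranceLimit, ToleranceSpec, normal_k_factor

FAST_FAMILIES = ("normal", "lognormal", "gamma", "weibull", "exponential")


def marker_frame(rng, generator):
    df = pd.DataFrame({m: generator(rng) for m in MARKERS})
    df.insert(0, "cat_id", [f"c{i:03d}" for i in range(len(df))])
    return df


def manual_thresholds(limits: dict[str, float]) -> ThresholdSet:
    ths = {}
    for m in MARKERS:
        side = DEFAULT_SIDES[m]
        spec = ToleranceSpec(side=side, method="parametric_normal")
        ths[m] = MarkerThreshold(
            marker=m,
            limit=ToleranceLimit(value=limits[m], spec=spec, n_obs=60, k_factor=1.6),
            side=side,
            method="parametric_normal",
            best_family="normal",
        )
    return ThresholdSet(ths)


BASE_LIMITS = {
    "agenorm_stkt": 0.5, "agenorm_tkt_tdp": 2.0, "agenorm_gr": 0.5,
    "par": 2.0, "latency": 100.0, "far": 2.0, "sar": 2.0, "sad": 1.0,
}


class TestDeriveThresholds:
    def test_parametric_limit_matches_oracle_formula(self):
        rng = np.random.default_rng(0)
        df = marker_frame(rng, lambda r: r.normal(1, 0.1, 60))
        ths = derive_thresholds(df, families=FAST_FAMILIES, random_state=0)
        t = ths["agenorm_stkt"]
        assert t.best_family == "normal" and t.method == "parametric_normal"
        x = df["agenorm_stkt"].to_numpy()
        expected = x.mean() - normal_k_factor(60) * x.std(ddof=1)
        assert t.limit.value == pytest.approx(expected, rel=1e-12)
        assert t.limit.value == pytest.approx(0.84, abs=0.04)

    def test_weibull_marker_goes_nonparametric_majority(self):
        nonpar = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            df = marker_frame(rng, lambda r: r.weibull(2.0, 60))
            ths = derive_thresholds(df, families=FAST_FAMILIES, random_state=0)
            nonpar += ths["par"].method == "nonparametric"
        assert nonpar > 5

    def test_constant_marker_errors_with_name(self):
        rng = np.random.default_rng(1)
        df = marker_frame(rng, lambda r: r.normal(1, 0.1, 60))
        df["sad"] = 1.0
        with pytest.raises(InvalidInputError, match="sad"):
            derive_thresholds(df, families=FAST_FAMILIES, random_state=0)

    def test_missing_marker_column(self):
        df = pd.DataFrame({"par": np.ones(40)})
        with pytest.raises(InvalidInputError, match="agenorm_stkt"):
            derive_thresholds(df)

    def test_provenance_attached(self):
        rng = np.random.default_rng(2)
        df = marker_frame(rng, lambda r: r.normal(1, 0.1, 60))
        ths = derive_thresholds(df, families=FAST_FAMILIES, random_state=0)
        frame = ths.to_frame()
        assert set(frame["marker"]) == set(MARKERS)
        assert frame["n"].eq(60).all()
        assert ths.rankings["par"][0].converged


class TestClassify:
    def test_medians_not_deficient(self):
        row = {"cat_id": "x", "agenorm_stkt": 1.0, "agenorm_tkt_tdp": 1.0,
               "agenorm_gr": 1.0, "par": 1.2, "latency": 20.0, "far": 1.1,
               "sar": 1.0, "sad": -0.1}
        call = classify(row, manual_thresholds(BASE_LIMITS))
        assert call.status == "not_deficient" and call.subtype == "none"
        assert call.markers_triggered == ()

    def test_par_above_limit_is_low_tdp(self):
        row = {"cat_id": "x", "agenorm_stkt": 1.0, "agenorm_tkt_tdp": 1.0,
               "agenorm_gr": 1.0, "par": 2.5, "latency": 20.0, "far": 1.1,
               "sar": 1.0, "sad": -0.1}
        call = classify(row, manual_thresholds(BASE_LIMITS))
        assert call.status == "B1_deficient" and call.subtype == "low_TDP"
        assert call.markers_triggered == ("par",)

    def test_far_family_is_high_tdp(self):
        for marker in HIGH_TDP_MARKERS:
            row = {"cat_id": "x", "agenorm_stkt": 1.0, "agenorm_tkt_tdp": 1.0,
                   "agenorm_gr": 1.0, "par": 1.2, "latency": 20.0, "far": 1.1,
                   "sar": 1.0, "sad": -0.1}
            row[marker] = BASE_LIMITS[marker] + 1.0
            call = classify(row, manual_thresholds(BASE_LIMITS))
            assert call.subtype == "high_TDP", marker

    def test_gr_only_is_b2(self):
        row = {"cat_id": "x", "agenorm_stkt": 1.0, "agenorm_tkt_tdp": 1.0,
               "agenorm_gr": 0.3, "par": 1.2, "latency": 20.0, "far": 1.1,
               "sar": 1.0, "sad": -0.1}
        call = classify(row, manual_thresholds(BASE_LIMITS))
        assert call.status == "B2_deficient"

    def test_b1_and_gr_coflag_is_b1_with_note(self):
        row = {"cat_id": "x", "agenorm_stkt": 0.2, "agenorm_tkt_tdp": 1.0,
               "agenorm_gr": 0.3, "par": 1.2, "latency": 20.0, "far": 1.1,
               "sar": 1.0, "sad": -0.1}
        call = classify(row, manual_thresholds(BASE_LIMITS))
        assert call.status == "B1_deficient"
        assert any("co-flag" in n for n in call.notes)

    def test_value_at_exact_cutoff_not_flagged(self):
        # strict comparison: the cutoff datum never self-flags
        row = {"cat_id": "x", "agenorm_stkt": 1.0, "agenorm_tkt_tdp": 1.0,
               "agenorm_gr": 1.0, "par": BASE_LIMITS["par"], "latency": 20.0,
               "far": 1.1, "sar": 1.0, "sad": -0.1}
        call = classify(row, manual_thresholds(BASE_LIMITS))
        assert call.status == "not_deficient"

    def test_missing_markers_degrade_not_raise(self):
        row = {"cat_id": "x", "par": 2.5}
        call = classify(row, manual_thresholds(BASE_LIMITS))
        assert call.status == "B1_deficient"
        assert sum("missing" in n for n in call.notes) == 7

    def test_rescaling_invariance(self):
        # order-preserving rescale of a marker and its threshold leaves calls fixed
        row = {"cat_id": "x", "agenorm_stkt": 1.0, "agenorm_tkt_tdp": 1.0,
               "agenorm_gr": 1.0, "par": 2.5, "latency": 20.0, "far": 1.1,
               "sar": 1.0, "sad": -0.1}
        base = classify(row, manual_thresholds(BASE_LIMITS))
        scaled_limits = dict(BASE_LIMITS, par=BASE_LIMITS["par"] * 10)
        scaled_row = dict(row, par=row["par"] * 10)
        scaled = classify(scaled_row, manual_thresholds(scaled_limits))
        assert scaled.status == base.status and scaled.subtype == base.subtype


class TestNullFlagRates:
    def test_flag_rate_respects_content_guarantee(self):
        # i.i.d. null markers: per-marker flag rate <= 10% in >= 95% of cohorts
        ok = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            df = marker_frame(rng, lambda r: r.normal(1, 0.1, 60))
            ths = derive_thresholds(df, families=("normal",), random_state=0)
            calls = classify_cohort(df, ths)
            rates = [
                np.mean([c.flags[m] for c in calls]) for m in MARKERS
            ]
            ok += all(r <= 0.10 for r in rates)
        assert ok / reps >= 0.95


class TestPlantedEffects:
    def test_sensitivity_monotone_in_effect_size(self):
        from thiastat.simulate import CohortConfig, DeficiencyPlan, generate
        from thiastat.pipeline import build_marker_table
        from thiastat.io import indices_table

        detections = []
        for factor in (0.8, 0.5, 0.25):
            hits = 0
            for seed in range(8):
                cfg = CohortConfig(
                    seed=seed,
                    deficiency_plan=DeficiencyPlan(1, 0, 0, low_tdp_factor=factor),
                )
                cohort = generate(cfg)
                table, _ = build_marker_table(indices_table(cohort.observable))
                ths = derive_thresholds(table, families=FAST_FAMILIES, random_state=0)
                calls = classify_cohort(table, ths)
                truth_id = cohort.table.loc[
                    cohort.table.truth_subtype == "low_TDP", "cat_id"
                ].item()
                call = next(c for c in calls if c.cat_id == truth_id)
                hits += call.subtype == "low_TDP"
            detections.append(hits)
        assert detections[0] <= detections[1] <= detections[2]
        assert detections[2] >= 6  # large effects are reliably caught


class TestSummarize:
    def _call(self, cat_id, status="not_deficient", subtype="none", markers=()):
        flags = {m: m in markers for m in MARKERS}
        from thiastat.classify import DeficiencyCall

        return DeficiencyCall(cat_id, flags, status, subtype, tuple(markers))

    def test_zero_flagged(self):
        s = summarize_calls([self._call("a"), self._call("b")])
        assert s["n_flagged"] == 0
        assert s["status_counts"]["B1_deficient"] == 0
        assert s["top_marker"] == {"low_TDP": None, "high_TDP": None}

    def test_single_b2(self):
        s = summarize_calls([self._call("a", "B2_deficient", markers=("agenorm_gr",))])
        assert s["status_counts"]["B2_deficient"] == 1

    def test_top_marker_counting(self):
        calls = [
            self._call("a", "B1_deficient", "low_TDP", ("par",)),
            self._call("b", "B1_deficient", "low_TDP", ("par", "latency")),
            self._call("c", "B1_deficient", "high_TDP", ("far",)),
        ]
        s = summarize_calls(calls)
        assert s["top_marker"]["low_TDP"] == "par"
        assert s["marker_counts"]["low_TDP"]["par"] == 2
        assert s["top_marker"]["high_TDP"] == "far"

    def test_demographics(self):
        cov = pd.DataFrame(
            {"cat_id": ["a", "b"], "sex": ["F", "M"],
             "age_years": [4.0, 8.0], "bcs": [5, 6]}
        )
        calls = [
            self._call("a", "B1_deficient", "low_TDP", ("par",)),
            self._call("b"),
        ]
        s = summarize_calls(calls, covariates=cov)
        assert s["flagged_demographics"]["pct_female"] == 100.0
        assert s["flagged_demographics"]["age_mean"] == 4.0

    def test_empty_raises(self):
        with pytest.raises(InvalidInputError):
            summarize_calls([])
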