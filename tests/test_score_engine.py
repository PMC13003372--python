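import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewsbench.errors import ConfigurationError, InvalidRecordError, MissingDataError
from ewsbench.score_engine import (
    compute_all_scores,
    compute_score,
    derive_map,
    load_definition,
    score_component,
    validate_definition,
)

from .conftest import random_records
from .helpers import oracle_score


class TestValidateDefinition:
    def test_fixtures_valid(self, definitions):
        for name, defn in definitions.items():
            assert validate_definition(defn) == [], name

    def test_coverage_gap_detected(self, raw_definitions):
        news = copy.deepcopy(raw_definitions["NEWS"])
        hr = next(c for c in news["components"] if c["variable"] == "hr")
        hr["bands"] = [b for b in hr["bands"] if b != [51, 90, 0]]
        with pytest.raises(ConfigurationError, match="coverage gap"):
            load_definition(news)

    def test_overlap_detected(self, raw_definitions):
        mews = copy.deepcopy(raw_definitions["MEWS"])
        rr = next(c for c in mews["components"] if c["variable"] == "rr")
        rr["bands"].insert(2, [10, 12, 1])
        with pytest.raises(ConfigurationError, match="overlap"):
            load_definition(mews)


class TestScoreComponent:
    def test_news_hr_80(self, definitions):
        comp = next(c for c in definitions["NEWS"].components if c.variable == "hr")
        assert score_component(80, comp) == 0

    def test_news_spo2_92(self, definitions):
        comp = next(c for c in definitions["NEWS"].components if c.variable == "spo2")
        assert score_component(92, comp) == 2

    def test_mews_avpu_u(self, definitions):
        comp = next(c for c in definitions["MEWS"].components if c.variable == "avpu")
        assert score_component("U", comp) == 3

    def test_unknown_category_is_config_error(self, definitions):
        comp = next(c for c in definitions["MEWS"].components if c.variable == "avpu")
        with pytest.raises(ConfigurationError, match="avpu"):
            score_component("X", comp)

    def test_missing_value(self, definitions):
        comp = next(c for c in definitions["NEWS"].components if c.variable == "hr")
        with pytest.raises(MissingDataError):
            score_component(float("nan"), comp)


class TestDeriveMap:
    def test_simple(self):
        assert derive_map(120, 60) == pytest.approx(80.0)

    def test_equal_pressures(self):
        assert derive_map(100, 100) == pytest.approx(100.0)

    def test_cohort_medians(self):
        assert derive_map(139, 75) == pytest.approx(96.33, abs=0.005)

    def test_inverted_raises(self):
        with pytest.raises(InvalidRecordError):
            derive_map(60, 120)


class TestComputeScore:
    def test_normal_record_news_zero(self, definitions, normal_record):
        assert compute_score(normal_record, definitions["NEWS"]).total == 0

    def test_normal_record_rems_age_floor(self, definitions, normal_record):
        res = compute_score(normal_record, definitions["REMS"])
        assert res.total == 6
        assert res.breakdown["age"] == 6

    def test_scale2_example(self, definitions, normal_record):
        rec = dict(normal_record, spo2=90.0, on_oxygen=True, t2rf_risk=True)
        news = compute_score(rec, definitions["NEWS"])
        assert news.breakdown["spo2"] + news.breakdown["on_oxygen"] == 5
        news2 = compute_score(rec, definitions["NEWS2"])
        assert news2.breakdown["spo2"] == 0
        assert news2.breakdown["on_oxygen"] == 2

    def test_total_is_sum_of_breakdown(self, definitions, normal_record):
        for defn in definitions.values():
            res = compute_score(normal_record, defn)
            assert res.total == sum(res.breakdown.values())

    def test_missing_field_raises(self, definitions, normal_record):
        rec = dict(normal_record, rr=float("nan"))
        with pytest.raises(MissingDataError):
            compute_score(rec, definitions["NEWS"])

    def test_news2_equals_news_without_t2rf(self, definitions):
        recs = random_records(300, seed=42)
        recs["t2rf_risk"] = False
        scores = compute_all_scores(recs, definitions)
        assert (scores["NEWS"] == scores["NEWS2"]).all()


class TestComputeAllScores:
    def test_composition(self, definitions, normal_record):
        import pandas as pd

        rows = [dict(normal_record),
                dict(normal_record, hr=120.0, avpu="V", gcs=13),
                dict(normal_record, spo2=85.0, on_oxygen=True)]
        df = pd.DataFrame(rows)
        table = compute_all_scores(df, definitions)
        assert table.shape == (3, 5)
        for i, row in enumerate(rows):
            for name, defn in definitions.items():
                assert table.iloc[i][name] == compute_score(row, defn).total

    def test_empty_cohort(self, definitions):
        import pandas as pd

        out = compute_all_scores(pd.DataFrame(), definitions)
        assert out.shape[0] == 0

    def test_within_theoretical_range(self, definitions):
        recs = random_records(2000, seed=3)
        scores = compute_all_scores(recs, definitions)
        for name, defn in definitions.items():
            lo, hi = defn.theoretical_range
            assert scores[name].between(lo, hi).all()

    def test_rems_age_floor_property(self, default_scores):
        assert (default_scores["REMS"] >= 6).all()


class TestOracleEquivalence:
    def test_grid_equivalence(self, definitions, raw_definitions):
        recs = random_records(10_000, seed=11)
        table = compute_all_scores(recs, definitions)
        for name in definitions:
            expected = np.array(
                [oracle_score(row, raw_definitions[name])
                 for row in recs.to_dict("records")]
            )
            np.testing.assert_array_equal(table[name].to_numpy(), expected, err_msg=name)


class TestMonotoneDominance:
    WORST = {
        "hr": 250.0, "rr": 60.0, "sbp": 45.0, "temp": 30.0, "spo2": 60.0,
        "gcs": 3, "avpu": "U",
    }

    def test_extreme_derangement_never_decreases(self, definitions, normal_record):
        base = {n: compute_score(normal_record, d).total
                for n, d in definitions.items()}
        for var, bad in self.WORST.items():
            rec = dict(normal_record, **{var: bad})
            if var == "gcs":
                rec["avpu"] = "U"
            if var == "avpu":
                rec["gcs"] = 3
            if var == "sbp":
                rec["dbp"] = 40.0
            for name, defn in definitions.items():
                assert compute_score(rec, defn).total >= base[name], (var, name)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_single_band_worsening(self, definitions, seed):
        """Moving one vital into a higher-point band of a score never lowers
        that score."""
        rng = np.random.default_rng(seed)
        rec = {
            "age": int(rng.integers(80, 100)), "sex": "male",
            "hr": float(rng.integers(40, 140)), "rr": float(rng.integers(8, 30)),
            "sbp": float(rng.integers(80, 200)), "dbp": 60.0, "map": np.nan,
            "temp": float(np.round(rng.uniform(34, 40), 1)),
            "spo2": float(rng.integers(85, 100)), "gcs": 15, "avpu": "A",
            "on_oxygen": False, "t2rf_risk": False,
        }
        for name in ("NEWS", "MEWS", "REMS"):
            defn = definitions[name]
            before = compute_score(rec, defn)
            for comp in defn.components:
                if comp.bands is None or comp.variable in ("age", "map"):
                    continue
                worst_band = max(comp.bands, key=lambda b: b.points)
                anchor = worst_band.lower if worst_band.lower is not None else worst_band.upper
                worse = dict(rec, **{comp.variable: float(anchor)})
                after = compute_score(worse, defn)
                assert after.total >= before.total
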