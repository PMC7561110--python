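"""MME conversion, prescription cleaning, and exposure-timeline construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import opioidtraj as ot
from opioidtraj.exposure import (
    OFF,
    REASON_BAD_DATE,
    REASON_UNKNOWN_INGREDIENT,
    REASON_ZERO_QUANTITY,
    build_timeline,
)


def rec(ingredient, strength, daily, route="oral"):
    return {"ingredient": ingredient, "route": route, "unit_strength": strength, "daily_count": daily}


class TestComputeMME:
    @pytest.mark.parametrize(
        "record, expected",
        [
            (rec("codeine", 30, 4), 18.0),  # 30 mg × 4/day × 0.15
            (rec("oxycodone", 40, 4), 240.0),  # 40 mg × 4/day × 1.5
            (rec("morphine", 10, 3), 30.0),  # identity factor
            (rec("fentanyl", 25, None, route="transdermal"), 60.0),  # 25 µg/h × 2.4
        ],
    )
    def test_worked_examples(self, conversion_table, record, expected):
        assert ot.compute_mme_per_day(record, conversion_table) == pytest.approx(expected)

    def test_missing_entry_names_ingredient(self, conversion_table):
        with pytest.raises(ot.ConversionLookupError, match="loperamide"):
            ot.compute_mme_per_day(rec("loperamide", 2, 4), conversion_table)

    def test_transdermal_ignores_daily_count(self, conversion_table):
        a = ot.compute_mme_per_day(rec("fentanyl", 25, 1, route="transdermal"), conversion_table)
        b = ot.compute_mme_per_day(rec("fentanyl", 25, 99, route="transdermal"), conversion_table)
        assert a == b == 60.0

    @given(scale=st.floats(min_value=0.25, max_value=8, allow_nan=False))
    def test_scale_equivariance(self, conversion_table, scale):
        base = ot.compute_mme_per_day(rec("oxycodone", 10, 2), conversion_table)
        scaled = ot.compute_mme_per_day(rec("oxycodone", 10 * scale, 2), conversion_table)
        assert scaled == pytest.approx(scale * base, rel=1e-12)


def raw_row(pid="P1", ingredient="codeine", qty=112, daily=4, date="2010-01-01", strength=30, route="oral"):
    return {
        "patient_id": pid,
        "prescriber_id": "S1",
        "ingredient": ingredient,
        "route": route,
        "unit_strength": strength,
        "quantity": qty,
        "daily_count": daily,
        "issue_date": date,
    }


class TestCleaning:
    def test_duration_arithmetic(self):
        clean, log = ot.clean_prescriptions(pd.DataFrame([raw_row(qty=112, daily=4)]))
        assert len(log) == 0
        assert clean.loc[0, "duration_days"] == 28
        # daily dose is 4 × 30 mg = 120 mg
        assert clean.loc[0, "unit_strength"] * clean.loc[0, "daily_count"] == 120

    def test_missing_daily_count_imputed_from_same_patient(self):
        rows = [raw_row(date="2010-01-01"), raw_row(daily=None, date="2010-03-01")]
        clean, log = ot.clean_prescriptions(pd.DataFrame(rows))
        assert len(log) == 0
        assert clean.loc[1, "daily_count"] == 4

    def test_missing_daily_count_falls_back_to_population_median(self):
        rows = [
            raw_row(pid="A", daily=2),
            raw_row(pid="B", daily=2),
            raw_row(pid="C", daily=None),
        ]
        clean, _ = ot.clean_prescriptions(pd.DataFrame(rows))
        assert clean.set_index("patient_id").loc["C", "daily_count"] == 2

    def test_zero_quantity_dropped_with_reason(self):
        clean, log = ot.clean_prescriptions(pd.DataFrame([raw_row(qty=0)]))
        assert len(clean) == 0
        assert list(log["reason"]) == [REASON_ZERO_QUANTITY]

    def test_bad_date_logged_not_silent(self):
        clean, log = ot.clean_prescriptions(pd.DataFrame([raw_row(date="not-a-date")]))
        assert len(clean) == 0
        assert list(log["reason"]) == [REASON_BAD_DATE]

    def test_unknown_ingredient_dropped(self, conversion_table):
        clean, log = ot.clean_prescriptions(
            pd.DataFrame([raw_row(ingredient="loperamide")]), conversion=conversion_table
        )
        assert list(log["reason"]) == [REASON_UNKNOWN_INGREDIENT]

    def test_duration_cap_and_floor(self):
        rows = [raw_row(qty=4000, daily=4), raw_row(qty=1, daily=4)]
        clean, _ = ot.clean_prescriptions(pd.DataFrame(rows))
        assert clean.loc[0, "duration_days"] == 183
        assert clean.loc[1, "duration_days"] == 1

    def test_cleaning_never_invents_exposure(self, small_study, conversion_table):
        raw = small_study.therapy
        clean, _ = ot.clean_prescriptions(raw, conversion=conversion_table)
        raw_qty = pd.to_numeric(raw["quantity"], errors="coerce").clip(lower=0).fillna(0)
        raw_mg = (raw_qty * raw["unit_strength"]).sum()
        clean_mg = (clean["quantity"] * clean["unit_strength"]).sum()
        assert clean_mg <= raw_mg + 1e-9


def mme_rec(ingredient, day, duration, mme, pid="P1"):
    return {
        "patient_id": pid,
        "ingredient": ingredient,
        "day": day,
        "duration_days": duration,
        "mme_per_day": mme,
    }


class TestTimeline:
    def test_overlap_of_different_ingredients_sums(self):
        df = pd.DataFrame([mme_rec("codeine", 0, 28, 18.0), mme_rec("tramadol", 10, 30, 20.0)])
        tl = build_timeline(df, 60)
        assert np.all(tl.values[10:28] == 38.0)
        assert np.all(tl.values[0:10] == 18.0)
        assert np.all(tl.values[28:40] == 20.0)
        assert np.all(tl.values[40:] == 0.0)

    def test_single_record(self):
        tl = build_timeline(pd.DataFrame([mme_rec("codeine", 5, 10, 18.0)]), 30)
        assert np.all(tl.values[5:15] == 18.0)
        assert tl.values.sum() == pytest.approx(18.0 * 10)
        assert tl.episodes == [(5, 15, 18.0)]

    def test_same_day_duplicates_stockpile_not_double(self):
        df = pd.DataFrame([mme_rec("codeine", 0, 28, 18.0), mme_rec("codeine", 0, 28, 18.0)])
        tl = build_timeline(df, 80)
        assert np.all(tl.values[0:56] == 18.0)
        assert np.all(tl.values[56:] == 0.0)

    def test_clipping_outside_bounds(self):
        df = pd.DataFrame([mme_rec("codeine", -5, 10, 18.0), mme_rec("tramadol", 95, 20, 20.0)])
        tl = build_timeline(df, 100)
        assert np.all(tl.values[0:5] == 18.0)
        assert np.all(tl.values[95:100] == 20.0)

    def test_brute_force_oracle_equivalence(self):
        """Vectorised timelines match a naive per-day loop on random patients."""
        rng = np.random.default_rng(2024)
        ingredients = ["codeine", "tramadol", "morphine", "oxycodone"]
        for _ in range(1000):
            n_rx = rng.integers(1, 8)
            rows = [
                mme_rec(
                    rng.choice(ingredients),
                    int(rng.integers(-10, 120)),
                    int(rng.integers(1, 60)),
                    float(rng.integers(1, 30)) * 2.0,
                )
                for _ in range(n_rx)
            ]
            df = pd.DataFrame(rows)
            n_days = 150
            tl = build_timeline(df, n_days)
            # oracle: sequential same-ingredient stockpiling, then a per-day scan
            expected = np.zeros(n_days)
            for ing in sorted(df["ingredient"].unique()):
                grp = df[df["ingredient"] == ing].sort_values(["day", "duration_days"], kind="stable")
                cursor = -(10**9)
                for r in grp.itertuples(index=False):
                    start = max(int(r.day), cursor)
                    end = start + int(r.duration_days)
                    cursor = end
                    for d in range(max(start, 0), min(end, n_days)):
                        expected[d] += r.mme_per_day
            np.testing.assert_allclose(tl.values, expected)

    @given(seed=st.integers(0, 10_000))
    def test_cross_ingredient_additivity(self, seed):
        """A combined timeline equals the sum of per-ingredient timelines."""
        rng = np.random.default_rng(seed)
        rows = [
            mme_rec(ing, int(rng.integers(0, 60)), int(rng.integers(1, 40)), 10.0 * (k + 1))
            for k, ing in enumerate(["codeine", "tramadol", "morphine"])
            for _ in range(rng.integers(1, 4))
        ]
        df = pd.DataFrame(rows)
        combined = build_timeline(df, 120)
        parts = sum(
            build_timeline(df[df["ingredient"] == ing], 120).values
            for ing in df["ingredient"].unique()
        )
        np.testing.assert_allclose(combined.values, parts)


class TestWindowAverage:
    def test_full_coverage_constant(self):
        tl = ot.ExposureTimeline("P", np.full(100, 60.0))
        assert ot.window_average_mme(tl, 0, 100) == 60.0

    def test_covered_days_convention(self):
        values = np.zeros(182)
        values[:30] = 100.0
        tl = ot.ExposureTimeline("P", values)
        assert ot.window_average_mme(tl, 0, 182) == 100.0
        assert ot.window_average_mme(tl, 0, 182, convention="calendar") == pytest.approx(3000 / 182)

    def test_no_coverage_is_off(self):
        tl = ot.ExposureTimeline("P", np.zeros(50))
        assert ot.window_average_mme(tl, 0, 50) == OFF

    def test_empty_window_raises(self):
        tl = ot.ExposureTimeline("P", np.zeros(50))
        with pytest.raises(ValueError, match="empty window"):
            ot.window_average_mme(tl, 10, 10)
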