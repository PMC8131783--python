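"""Diet quantification: occupancy, acceptance rules, correction factors,
aggregation, period summaries, and consumption-year classification."""

import math

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ursadiet import diet as dq
from ursadiet.diet import (DegenerateInputError, ConfigurationError, DietProfile,
                           FoodItemTable, ScatRecord)


def table(**items) -> FoodItemTable:
    """Shorthand taxonomy: item -> (category, cf_d, cf_e[, hair])."""
    return FoodItemTable(
        category={k: v[0] for k, v in items.items()},
        cf_d={k: v[1] for k, v in items.items() if v[0] != "nonfood"},
        cf_e={k: v[2] for k, v in items.items() if v[0] != "nonfood"},
        bear_hair=frozenset(k for k, v in items.items() if len(v) > 3 and v[3]),
    )


UNIT = table(a=("plants", 1, 1), b=("salmon", 1, 1), junk=("nonfood", 1, 1))


class TestOccupancy:
    @pytest.mark.parametrize("counts,expected", [
        ({"pine": 150, "ants": 50}, {"pine": 75.0, "ants": 25.0}),
        ({"salmon": 200}, {"salmon": 100.0}),
        ({"a": 120, "b": 60, "c": 20}, {"a": 60.0, "b": 30.0, "c": 10.0}),
    ])
    def test_proportions(self, counts, expected):
        assert compute(counts) == pytest.approx(expected)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            dq.compute_occupancy({"a": 0, "b": 0})

    @given(st.dictionaries(
        st.sampled_from("abcdefg"), st.integers(0, 500), min_size=1, max_size=7,
    ).filter(lambda d: sum(d.values()) > 0))
    def test_sums_to_100(self, counts):
        profile = dq.compute_occupancy(counts)
        assert math.isclose(profile.total(), 100.0, abs_tol=1e-6)
        assert all(v >= 0 for v in profile.values.values())


def compute(counts):
    return dq.compute_occupancy(counts).values


class TestAcceptScat:
    def make(self, counts, weight=120.0):
        return ScatRecord(scat_id="s", year=2015, month=8, method="point_frame",
                          point_counts=counts, wet_weight_g=weight)

    def test_enough_points_accepted(self):
        sal = table(a=("plants", 1, 1), salmon=("salmon", 1, 1))
        assert dq.accept_scat(self.make({"a": 250}), sal).accepted

    def test_too_few_points_no_salmon_rejected(self):
        sal = table(a=("plants", 1, 1), salmon=("salmon", 1, 1))
        decision = dq.accept_scat(self.make({"a": 180}, weight=120.0), sal)
        assert not decision.accepted
        assert "180" in decision.reason

    def test_salmon_exception(self):
        sal = table(a=("plants", 1, 1), salmon=("salmon", 1, 1))
        record = self.make({"a": 100, "salmon": 50}, weight=60.0)
        decision = dq.accept_scat(record, sal)
        assert decision.accepted
        assert "salmon" in decision.reason

    def test_salmon_but_light_rejected(self):
        sal = table(a=("plants", 1, 1), salmon=("salmon", 1, 1))
        assert not dq.accept_scat(self.make({"salmon": 150}, weight=30.0), sal).accepted

    def test_visual_record_not_applicable(self):
        record = ScatRecord(scat_id="v", year=2012, month=7, method="visual",
                            vfv={"a": 100.0})
        with pytest.raises(ValueError, match="point-frame"):
            dq.accept_scat(record, UNIT)


class TestNonfoodRules:
    HAIRY = table(a=("plants", 1, 1), hair=("mammals", 1, 1, True),
                  junk=("nonfood", 1, 1))

    def test_trace_hair_is_nonfood(self):
        prof = DietProfile("occupancy", "item", {"a": 99.7, "hair": 0.3})
        out = dq.apply_nonfood_rules(prof, self.HAIRY)
        assert out.nonfood_items == {"hair"}

    def test_substantial_hair_is_food(self):
        prof = DietProfile("occupancy", "item", {"a": 96.0, "hair": 4.0})
        out = dq.apply_nonfood_rules(prof, self.HAIRY)
        assert out.nonfood_items == frozenset()

    def test_no_nonfood_unchanged(self):
        prof = DietProfile("occupancy", "item", {"a": 100.0})
        out = dq.apply_nonfood_rules(prof, self.HAIRY)
        assert out.values == prof.values and out.nonfood_items == frozenset()

    def test_nonfood_category_flagged(self):
        prof = DietProfile("occupancy", "item", {"a": 90.0, "junk": 10.0})
        assert dq.apply_nonfood_rules(prof, self.HAIRY).nonfood_items == {"junk"}


def corrected(values, taxonomy, fn=dq.compute_edc):
    prof = dq.apply_nonfood_rules(DietProfile("occupancy", "item", values), taxonomy)
    return fn(prof, taxonomy).values


class TestCorrectionFactors:
    def test_unit_cf_identity(self):
        assert corrected({"a": 70.0, "b": 30.0}, UNIT) == pytest.approx(
            {"a": 70.0, "b": 30.0})

    def test_edc_hand_arithmetic(self):
        tax = table(a=("plants", 0.5, 1), b=("salmon", 2.0, 1))
        assert corrected({"a": 50.0, "b": 50.0}, tax) == pytest.approx(
            {"a": 20.0, "b": 80.0})

    def test_nonfood_renormalized(self):
        assert corrected({"a": 45.0, "b": 45.0, "junk": 10.0}, UNIT) == pytest.approx(
            {"a": 50.0, "b": 50.0})

    def test_edec_equals_edc_under_unit_cfe(self):
        tax = table(a=("plants", 0.7, 1), b=("salmon", 3.0, 1))
        assert corrected({"a": 60.0, "b": 40.0}, tax, dq.compute_edec) == pytest.approx(
            corrected({"a": 60.0, "b": 40.0}, tax))

    def test_edec_hand_arithmetic(self):
        tax = table(a=("plants", 1, 3.0), b=("salmon", 1, 1.0))
        assert corrected({"a": 50.0, "b": 50.0}, tax, dq.compute_edec) == pytest.approx(
            {"a": 75.0, "b": 25.0})

    def test_single_food_item_is_100(self):
        tax = table(a=("plants", 0.123, 7.7))
        assert corrected({"a": 42.0}, tax, dq.compute_edec) == pytest.approx({"a": 100.0})

    def test_missing_cf_is_configuration_error(self):
        tax = FoodItemTable(category={"a": "plants", "b": "salmon"},
                            cf_d={"a": 1.0}, cf_e={"a": 1.0})
        with pytest.raises(ConfigurationError):
            corrected({"a": 50.0, "b": 50.0}, tax)

    def test_all_nonfood_degenerate(self):
        with pytest.raises(DegenerateInputError):
            corrected({"junk": 100.0}, UNIT)

    @given(st.floats(0.2, 5.0), st.floats(0.2, 5.0), st.floats(1.01, 10.0),
           st.floats(5.0, 95.0))
    def test_raising_cf_d_shifts_share_toward_item(self, cfa, cfb, bump, va):
        """Increasing one item's CF_D strictly increases its EDC and
        strictly decreases the other's."""
        tax_lo = table(a=("plants", cfa, 1), b=("salmon", cfb, 1))
        tax_hi = table(a=("plants", cfa * bump, 1), b=("salmon", cfb, 1))
        values = {"a": va, "b": 100.0 - va}
        lo, hi = corrected(values, tax_lo), corrected(values, tax_hi)
        assert hi["a"] > lo["a"] and hi["b"] < lo["b"]

    @given(st.dictionaries(st.sampled_from("abcd"), st.floats(0.1, 100.0),
                           min_size=2, max_size=4))
    def test_edc_sums_to_100(self, values):
        tax = table(a=("plants", 0.5, 2), b=("salmon", 6.0, 1.2),
                    c=("insects", 1.1, 1.6), d=("berries", 1.2, 1.0))
        assert sum(corrected(values, tax).values()) == pytest.approx(100.0, abs=1e-6)


class TestAggregation:
    TAX = table(Formicidae=("insects", 1, 1), Vespidae=("insects", 1, 1),
                pine=("pine_nuts", 1, 1))

    def test_members_sum(self):
        prof = DietProfile("edc", "item", {"Formicidae": 10.0, "Vespidae": 2.0},
                           nonfood_items=frozenset())
        assert dq.aggregate_categories(prof, self.TAX).values == {"insects": 12.0}

    def test_unknown_item_errors(self):
        prof = DietProfile("edc", "item", {"mystery": 100.0}, frozenset())
        with pytest.raises(ConfigurationError):
            dq.aggregate_categories(prof, self.TAX)

    @given(st.dictionaries(st.sampled_from(["Formicidae", "Vespidae", "pine"]),
                           st.floats(0, 100), min_size=1))
    def test_total_conserved(self, values):
        prof = DietProfile("edc", "item", values, frozenset())
        out = dq.aggregate_categories(prof, self.TAX)
        assert sum(out.values.values()) == pytest.approx(sum(values.values()), abs=1e-9)


class TestSummarizePeriod:
    def scat(self, i, month=7, half="early", year=2015):
        return ScatRecord(scat_id=f"s{i}", year=year, month=month, half=half,
                          method="point_frame", point_counts={"a": 200})

    def test_mean_and_fo(self):
        records = [self.scat(0), self.scat(1)]
        profiles = [DietProfile("edc", "category", {"a": 100.0}),
                    DietProfile("edc", "category", {"a": 0.0, "b": 100.0})]
        out = dq.summarize_period(records, profiles, "month")
        by_key = out.set_index("key")
        assert by_key.loc["a", "mean"] == 50.0 and by_key.loc["b", "mean"] == 50.0
        assert by_key.loc["a", "fo"] == 50.0 and by_key.loc["b", "fo"] == 50.0
        assert (out["n"] == 2).all()

    def test_single_scat_mean_is_profile(self):
        out = dq.summarize_period([self.scat(0)],
                                  [DietProfile("edc", "category", {"a": 33.0, "b": 67.0})],
                                  "month")
        assert dict(zip(out["key"], out["mean"])) == {"a": 33.0, "b": 67.0}

    def test_unknown_half_excluded_from_semimonthly_only(self):
        records = [self.scat(0, half="early"), self.scat(1, half="unknown")]
        profiles = [DietProfile("edc", "category", {"a": 100.0})] * 2
        assert dq.summarize_period(records, profiles, "month")["n"].iloc[0] == 2
        assert dq.summarize_period(records, profiles, "semimonth")["n"].iloc[0] == 1

    def test_formatting(self):
        assert dq.format_percent(0.0) == "—"
        assert dq.format_percent(0.04) == "tr"
        assert dq.format_percent(12.34) == "12.3"


class TestClassifyYears:
    def test_strict_mean_threshold_pine(self):
        pine = {2012: 19.7, 2013: 47.4, 2014: 47.5, 2015: 19.7, 2016: 47.3,
                2017: 19.7, 2018: 42.9}
        salmon = {y: 30.0 for y in pine}
        salmon.update({2013: 54.4, 2016: 65.4, 2018: 72.2})
        out = dq.classify_years(pine, salmon)
        assert {y for y, c in out.years.items() if c.pine_high} == {2013, 2014, 2016, 2018}
        assert out.diet1_years() == {2013, 2016, 2018}
        assert out.diet2_years() == {2012, 2015, 2017}
        assert out.pine_mean == pytest.approx(34.9, abs=0.1)

    def test_all_equal_no_year_high(self):
        years = {2012: 10.0, 2013: 10.0, 2014: 10.0}
        out = dq.classify_years(years, dict(years))
        assert not any(c.pine_high or c.salmon_high for c in out.years.values())
        assert out.diet2_years() == set(years)

    def test_mismatched_years_error(self):
        with pytest.raises(ConfigurationError):
            dq.classify_years({2012: 1.0, 2013: 2.0}, {2012: 1.0, 2014: 2.0})
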