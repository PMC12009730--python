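"""The three average-daily-dose models and their algebraic relationships."""

import numpy as np
import pytest

from mesodose.add_models import (
    add_method1,
    add_method2,
    add_method3,
    annualize,
    body_weight_for,
    estimate_cohort,
    results_to_frame,
)
from mesodose.domain_types import (
    BodyWeightBracket,
    BodyWeightTable,
    DomainError,
    MesoActivity,
    Season,
    Sex,
)
from mesodose.ingestion_rates import build_rate_set
from tests.test_domain_types import make_record

A = MesoActivity


class TestMethod1:
    def test_ef_equal_to_at_cancels(self):
        # 400 mg/kg x 378e-6 kg/day / 80 kg = 1.89e-3 mg/kgBW/day
        r = add_method1(400, 378, 30.5, 80)
        assert r.add_total == pytest.approx(1.89e-3, rel=1e-12)

    def test_zero_days_is_zero_dose(self):
        assert add_method1(400, 378, 0, 80).add_total == 0.0

    def test_five_day_week_hand_computation(self):
        # frozen independent arithmetic: (400 x 378e-6 x 21.75)/(65 x 30.5)
        r = add_method1(400, 378, 21.75, 65)
        assert r.add_total == pytest.approx(0.001658814627994956, rel=1e-12)

    def test_non_positive_bw_raises(self):
        with pytest.raises(DomainError):
            add_method1(400, 378, 20, 0)


class TestMethod2:
    def test_indoor_only(self):
        r = add_method2(400, 45.25, 1.375, 0.0, 80)
        assert r.add_outdoor == 0.0
        assert r.add_total == pytest.approx(1.65e-4, rel=1e-12)

    def test_outdoor_only(self):
        r = add_method2(400, 45.25, 1.375, 730.8, 80)
        assert r.add_indoor == 0.0
        assert r.add_total == pytest.approx(5.43e-3, rel=1e-12)

    def test_mixed_hours_hand_computation(self):
        # frozen two-term sum at 174 h outdoors (8 h x 5 d x 4.35), BW 70
        r = add_method2(400, 45.25, 1.375, 174.0, 70)
        assert r.add_total == pytest.approx(0.0016212244897959188, rel=1e-12)
        assert r.add_total == r.add_outdoor + r.add_indoor

    def test_hours_beyond_averaging_time_cannot_be_clamped(self):
        with pytest.raises(DomainError):
            add_method2(400, 45.25, 1.375, 731.0, 80)

    def test_complement_conservation_is_exact(self):
        rng = np.random.default_rng(1)
        for h in rng.uniform(0, 730.8, size=500):
            r = add_method2(400, 45.25, 1.375, h, 80)
            outdoor_hours = h
            indoor_hours = 730.8 - h
            assert outdoor_hours + indoor_hours == 730.8


class TestMethod3:
    def test_all_zero_task_hours_reduces_to_indoor_only_method2(self, rate_set):
        r3 = add_method3(400, rate_set, {a: 0.0 for a in A}, 80)
        r2 = add_method2(400, rate_set.hourly_outdoor, rate_set.hourly_indoor, 0.0, 80)
        assert r3.add_total == pytest.approx(r2.add_total, rel=1e-12)

    def test_single_unit_scaled_task_equals_method2(self):
        rs = build_rate_set(contact_means={a: 0.5 for a in A})  # all scale 1.0
        r3 = add_method3(400, rs, {A.WEEDING: 120.0}, 80)
        r2 = add_method2(400, rs.hourly_outdoor, rs.hourly_indoor, 120.0, 80)
        assert r3.add_total == pytest.approx(r2.add_total, rel=1e-12)

    def test_two_task_hand_computation(self, rate_set):
        # frozen three-term arithmetic: 20 h transplanting + 30 h weeding
        # at 90.5 mg/h each, 680.8 h indoors at 1.375 mg/h, BW 75
        r = add_method3(400, rate_set, {A.TRANSPLANTING: 20.0, A.WEEDING: 30.0}, 75)
        assert r.add_total == pytest.approx(0.0009565145046524358, rel=1e-12)
        assert r.add_outdoor == pytest.approx(sum(r.add_by_task.values()), rel=1e-12)

    def test_excess_task_hours_clamp_indoor_term_with_flag(self, rate_set):
        r = add_method3(400, rate_set, {a: 200.0 for a in A}, 80)
        assert "indoor_hours_clamped" in r.flags
        assert r.add_indoor == 0.0
        assert r.add_total == pytest.approx(r.add_outdoor)

    def test_negative_task_hours_raise(self, rate_set):
        with pytest.raises(DomainError):
            add_method3(400, rate_set, {A.WEEDING: -1.0}, 80)


def test_doses_are_homogeneous_in_concentration_and_inverse_bw(rate_set):
    base = add_method3(400, rate_set, {A.WEEDING: 50.0}, 80)
    assert add_method3(800, rate_set, {A.WEEDING: 50.0}, 80).add_total == pytest.approx(
        2 * base.add_total, rel=1e-12
    )
    assert add_method3(400, rate_set, {A.WEEDING: 50.0}, 160).add_total == pytest.approx(
        base.add_total / 2, rel=1e-12
    )


class TestBodyWeightLookup:
    table = BodyWeightTable(
        mode="median_lookup",
        brackets=(BodyWeightBracket(Sex.MALE, 30, 50, 88.8),),
    )

    def test_direct_lookup(self):
        grower = make_record(sex=Sex.MALE, age=40)
        assert body_weight_for(grower, self.table) == 88.8

    def test_explicit_weight_overrides_table(self):
        grower = make_record(sex=Sex.MALE, age=40, body_weight=70.0)
        assert body_weight_for(grower, self.table) == 70.0

    def test_uncovered_age_names_the_gap(self):
        grower = make_record(sex=Sex.MALE, age=20)
        with pytest.raises(DomainError, match="age=20"):
            body_weight_for(grower, self.table)


class TestAnnualize:
    @staticmethod
    def seasonal(values):
        return [
            add_method1(400, 378, 30.5 * v / 1.89e-3, 80, grower_id="g", season=s)
            for s, v in zip(Season, values)
        ]

    def test_equal_seasons(self):
        results = self.seasonal([1e-3] * 4)
        summary = annualize(results)
        assert summary.cumulative == pytest.approx(4e-3, rel=1e-9)
        assert summary.time_weighted_mean == pytest.approx(1e-3, rel=1e-9)

    def test_one_nonzero_season(self):
        summary = annualize(self.seasonal([2e-3, 0, 0, 0]))
        assert summary.cumulative == pytest.approx(4 * summary.time_weighted_mean)

    def test_mixed_seasons(self):
        summary = annualize(self.seasonal([1e-3, 2e-3, 5e-4, 5e-4]))
        assert summary.cumulative == pytest.approx(4e-3, rel=1e-9)
        assert summary.time_weighted_mean == pytest.approx(1e-3, rel=1e-9)

    def test_missing_season_is_an_error(self):
        with pytest.raises(DomainError):
            annualize(self.seasonal([1e-3] * 4)[:3])


def test_estimate_cohort_emits_tidy_frame(small_cohort, lookup_table):
    results = estimate_cohort(small_cohort, lookup_table, 3)
    frame = results_to_frame(results)
    assert set(frame["component"]) == {"total", "outdoor", "indoor"} | {a.value for a in A}
    totals = frame[frame["component"] == "total"]
    assert (totals["add_mg_per_kgbw_day"] >= 0).all()
    assert len(totals) == sum(len(r.seasons) for r in small_cohort)
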