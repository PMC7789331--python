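"""Productivity losses: PV engine vs brute force, employer/home/presenteeism."""

from __future__ import annotations

import numpy as np
import pytest

import oshburden as ob
from oshburden.indirect import pv_earnings_to_retirement

from .conftest import make_cohort, make_profile


def pv_bruteforce(age, sex, profile, params):
    """Independent year-by-year discounted sum over earnings to retirement."""
    horizon = params.retirement_age - age
    total, k = 0.0, 0
    while horizon > 1e-12:
        w = min(1.0, horizon)
        year = params.reference_year + k
        growth = (1.0 + params.productivity_growth) ** max(
            0, year - (params.growth_from_year - 1)
        )
        disc = (1.0 + params.discount_rate) ** (-k)
        total += profile.annual_earnings.value(age + k, sex, clamp=True) * w * growth * disc
        horizon -= w
        k += 1
    return total


class TestPresentValueEngine:
    def test_matches_bruteforce_on_random_cases(self, synth_bundle, default_params):
        _, profile, _ = synth_bundle
        rng = np.random.default_rng(42)
        for _ in range(1000):
            age = rng.uniform(16.0, 64.9)
            sex = "F" if rng.random() < 0.5 else "M"
            params = default_params.model_copy(
                update={
                    "discount_rate": float(rng.choice([0.0, 0.01, 0.03, 0.05])),
                    "productivity_growth": float(rng.choice([0.0, 0.01, 0.02])),
                }
            )
            engine = pv_earnings_to_retirement(age, sex, profile, params)
            oracle = pv_bruteforce(age, sex, profile, params)
            assert engine == pytest.approx(oracle, rel=1e-9)

    def test_strictly_decreasing_in_discount_rate(self, zero_discount_params):
        profile = make_profile()
        rates = [0.0, 0.01, 0.03, 0.07]
        pvs = [
            pv_earnings_to_retirement(
                40.0, "M", profile,
                zero_discount_params.model_copy(update={"discount_rate": r}),
            )
            for r in rates
        ]
        assert all(a > b for a, b in zip(pvs, pvs[1:]))

    def test_growth_only_beyond_2017(self, zero_discount_params):
        # With zero discount, growth at 1% adds nothing in 2015-2017.
        params = zero_discount_params.model_copy(
            update={"productivity_growth": 0.01}
        )
        profile = make_profile()
        pv3 = pv_earnings_to_retirement(62.0, "M", profile, params)  # 2015-2017
        assert pv3 == pytest.approx(3 * 40_000.0)


class TestLifetimeEarningsLoss:
    def test_no_lost_days_no_loss(self, default_params):
        cohort = make_cohort(band_id="no_lost_days")
        assert ob.lifetime_earnings_loss(cohort, make_profile(), default_params) == 0.0

    def test_temporary_daily_earnings_rule(self, zero_discount_params):
        # 9 lost days at 40,000/230 per day, no fringe
        cohort = make_cohort(band_id="4-14")
        loss = ob.lifetime_earnings_loss(cohort, make_profile(), zero_discount_params)
        assert loss == pytest.approx(9 * 40_000.0 / 230.0)

    def test_permanent_impairment_closed_form(self, zero_discount_params):
        # age 60, flat 40,000/yr, no fringe/growth/discount: 0.35 x 40,000 x 5
        cohort = make_cohort(band_id="never_return", age=60.0)
        loss = ob.lifetime_earnings_loss(cohort, make_profile(), zero_discount_params)
        assert loss == pytest.approx(70_000.0)

    def test_fatal_with_finnish_fringe_rate(self, zero_discount_params):
        cohort = make_cohort(band_id="fatal", age=64.0)
        profile = make_profile(fringe_rate=0.22)
        loss = ob.lifetime_earnings_loss(cohort, profile, zero_discount_params)
        assert loss == pytest.approx(48_800.0)

    def test_monotone_in_lost_days_impairment_and_fringe(self, zero_discount_params):
        profile = make_profile()
        by_days = [
            ob.lifetime_earnings_loss(
                make_cohort(band_id=b, age=40.0), profile, zero_discount_params
            )
            for b in ("0-3", "4-14", "15-90", "91-180")
        ]
        assert all(a <= b for a, b in zip(by_days, by_days[1:]))
        perm = make_cohort(band_id="never_return", age=40.0)
        for lo, hi in [(0.33, 0.38), (0.35, 0.5)]:
            assert ob.lifetime_earnings_loss(
                perm, profile,
                zero_discount_params.model_copy(update={"impairment_output_loss": lo}),
            ) <= ob.lifetime_earnings_loss(
                perm, profile,
                zero_discount_params.model_copy(update={"impairment_output_loss": hi}),
            )
        assert ob.lifetime_earnings_loss(
            perm, make_profile(fringe_rate=0.28), zero_discount_params
        ) > ob.lifetime_earnings_loss(perm, profile, zero_discount_params)


class TestEmployerAdjustment:
    def test_half_managerial_day_plus_clerical_hours(self):
        cohort = make_cohort(band_id="4-14")
        profile = make_profile(managerial_daily_wage=400.0, clerical_hourly_wage=20.0)
        assert ob.employer_adjustment_cost(cohort, profile) == 250.0

    def test_below_four_lost_days_costs_nothing(self):
        cohort = make_cohort(band_id="0-3")
        assert ob.employer_adjustment_cost(cohort, make_profile()) == 0.0

    def test_fatal_six_months_of_wages_and_benefits(self):
        profile = make_profile(
            annual_earnings=ob.AgeTable(brackets=[(15, 64)], F=[50_000.0], M=[50_000.0])
        )
        cohort = make_cohort(band_id="fatal", age=40.0)
        assert ob.employer_adjustment_cost(cohort, profile) == 25_000.0


class TestHomeProduction:
    def test_no_lost_days_no_loss(self, default_params):
        cohort = make_cohort(band_id="no_lost_days")
        assert ob.home_production_loss(cohort, make_profile(), default_params) == 0.0

    def test_temporary_hours_times_days(self, zero_discount_params):
        # 2 h/day x 17 expected lost days x 12 €/h
        cohort = make_cohort(kind="disease", band_id="4-30")
        loss = ob.home_production_loss(cohort, make_profile(), zero_discount_params)
        assert loss == pytest.approx(2.0 * 17.0 * 12.0)

    def test_permanent_full_remaining_life(self, zero_discount_params):
        # 2 h/day x 365 x 12 €/h x 10 remaining years, zero discount
        cohort = make_cohort(band_id="never_return", age=60.0)
        loss = ob.home_production_loss(cohort, make_profile(), zero_discount_params)
        assert loss == pytest.approx(87_600.0)


class TestPresenteeism:
    def test_zero_ratio_zero_cost(self, zero_discount_params):
        params = zero_discount_params.model_copy(
            update={"presenteeism_ratio_default": 0.0}
        )
        cohort = make_cohort(band_id="4-14")
        assert ob.presenteeism_cost(cohort, make_profile(), params) == 0.0

    def test_injury_post_return_window(self, zero_discount_params):
        # ratio 0.2 x 20 working days x 150 €/day
        params = zero_discount_params.model_copy(
            update={"presenteeism_ratio_default": 0.2, "presenteeism_window_days": 20.0}
        )
        profile = make_profile(
            annual_earnings=ob.AgeTable(brackets=[(15, 64)], F=[34_500.0], M=[34_500.0])
        )
        cohort = make_cohort(band_id="4-14")
        assert ob.presenteeism_cost(cohort, profile, params) == pytest.approx(600.0)

    def test_disease_counts_both_windows(self, zero_discount_params):
        params = zero_discount_params.model_copy(
            update={"presenteeism_ratio_default": 0.2, "presenteeism_window_days": 20.0}
        )
        profile = make_profile(
            annual_earnings=ob.AgeTable(brackets=[(15, 64)], F=[34_500.0], M=[34_500.0])
        )
        injury = ob.presenteeism_cost(make_cohort(band_id="4-14"), profile, params)
        disease = ob.presenteeism_cost(
            make_cohort(kind="disease", band_id="4-30"), profile, params
        )
        assert disease == pytest.approx(2 * injury)

    def test_excluded_for_fatal_and_never_return(self, default_params):
        profile = make_profile()
        for band in ("fatal", "never_return"):
            assert ob.presenteeism_cost(
                make_cohort(band_id=band), profile, default_params
            ) == 0.0


class TestInsuranceAdmin:
    @pytest.mark.parametrize(
        "wages,pct,expected",
        [(1_000.0, 0.122, 122.0), (0.0, 0.101, 0.0), (10_000.0, 0.115, 1_150.0)],
    )
    def test_percentage_of_lost_wages(self, wages, pct, expected):
        assert ob.insurance_admin_cost(wages, pct) == pytest.approx(expected)
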