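"""Shared fixtures: hand-computable profiles and synthetic bundles."""

from __future__ import annotations

import pytest

import oshburden as ob


def make_profile(**overrides) -> ob.CountryProfile:
    """Flat-earnings single-bracket profile for closed-form checks."""
    base = dict(
        country_code="TST",
        gdp=2.0e11,
        employed_persons=2.4e6,
        annual_earnings=ob.AgeTable(
            brackets=[(15.0, 64.0)], F=[40_000.0], M=[40_000.0]
        ),
        fringe_rate=0.0,
        price_adjustment_ratio=1.0,
        managerial_daily_wage=400.0,
        clerical_hourly_wage=20.0,
        caregiver_hourly_wage=15.0,
        domestic_hourly_wage=12.0,
        home_production_hours=ob.AgeTable(
            brackets=[(15.0, 64.0)], F=[2.0], M=[2.0]
        ),
        healthcare_unit_cost={"injury": 2000.0, "musculoskeletal": 2000.0},
        out_of_pocket_pct=0.0,
        healthcare_admin_pct=0.0,
        insurance_admin_pct=0.0,
        replacement_rate=0.8,
        conditional_life_expectancy=ob.AgeCurve(
            ages=[15.0, 105.0], F=[10.0, 10.0], M=[10.0, 10.0]
        ),
        fatal_per_nonfatal_injury=0.001,
    )
    base.update(overrides)
    return ob.CountryProfile(**base)


def make_cohort(
    kind="injury",
    band_id=None,
    age=60.0,
    sex="M",
    count=1.0,
    condition_group=None,
) -> ob.CaseCohort:
    if band_id is None:
        band_id = "4-14" if kind == "injury" else "4-30"
    if condition_group is None:
        condition_group = "injury" if kind == "injury" else "musculoskeletal"
    return ob.CaseCohort(
        kind=kind,
        condition_group=condition_group,
        band_id=band_id,
        age_low=age,
        age_high=age,
        sex=sex,
        count=count,
    )


@pytest.fixture(scope="session")
def default_params() -> ob.ModelParameters:
    return ob.default_parameters()


@pytest.fixture(scope="session")
def zero_discount_params(default_params) -> ob.ModelParameters:
    return default_params.model_copy(
        update={"discount_rate": 0.0, "productivity_growth": 0.0}
    )


@pytest.fixture(scope="session")
def synth_bundle():
    """Finland-like synthetic bundle, fixed seed, shared across tests."""
    spec = ob.SynthSpec(seed=123)
    profile, cohorts = ob.generate_bundle(spec)
    return spec, profile, cohorts
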