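"""Indirect (productivity-related) costs per case cohort.

Productivity losses follow a human-capital approach: the value of lost
market output is the present value of foregone gross earnings (wages plus
payroll/fringe benefits).  Temporary absences lose daily earnings for the
expected lost workdays; cases off work for more than six months are treated
as permanently impaired, losing a fixed fraction of annual earnings until
the standard retirement age of 65; fatalities lose full earnings from death
to retirement.  A productivity growth factor applies to earnings beyond
2017 and all values are discounted to the 2015 reference year.

The same present-value engine prices home-production losses over remaining
life expectancy.  Employer adjustment, presenteeism and insurance
administration complete the indirect category.
"""

from __future__ import annotations

import math

import numpy as np

from .types import CaseCohort, CountryProfile, ModelParameters

_EPS = 1e-12


def discount_growth_factors(
    n_years: int, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Per-year growth and discount factors for year offsets 0..n-1.

    Offset 0 is the reference year.  Growth compounds only for calendar
    years from ``growth_from_year`` onward; discounting compounds from the
    reference year.
    """
    k = np.arange(n_years, dtype=float)
    years = params.reference_year + k
    growth_years = np.maximum(0.0, years - (params.growth_from_year - 1))
    g = (1.0 + params.productivity_growth) ** growth_years
    d = (1.0 + params.discount_rate) ** (-k)
    return g, d


def present_value(
    annual_amounts, horizon_years: float, params: ModelParameters,
    apply_growth: bool = True,
) -> float:
    """Present value of an annual stream over a (possibly fractional) horizon.

    ``annual_amounts`` is either a scalar (constant stream) or a callable
    mapping the integer year offset to that year's undiscounted,
    ungrown amount.  The final partial year is weighted by its fraction.
    """
    if horizon_years <= 0:
        return 0.0
    n_full = int(math.floor(horizon_years))
    frac = horizon_years - n_full
    n = n_full + (1 if frac > _EPS else 0)
    if callable(annual_amounts):
        amounts = np.array([annual_amounts(k) for k in range(n)], dtype=float)
    else:
        amounts = np.full(n, float(annual_amounts))
    weights = np.ones(n)
    if frac > _EPS:
        weights[-1] = frac
    g, d = discount_growth_factors(n, params)
    if not apply_growth:
        g = np.ones(n)
    return float(np.sum(amounts * weights * g * d))


def pv_earnings_to_retirement(
    age: float, sex: str, profile: CountryProfile, params: ModelParameters
) -> float:
    """PV of one worker's gross annual earnings from ``age`` to retirement.

    Earnings follow the profile's age-bracket table as the worker ages
    (clamped to the last bracket beyond the table), exclude the fringe
    uplift (applied by the caller), and include growth and discounting.
    """
    horizon = params.retirement_age - age
    return present_value(
        lambda k: profile.annual_earnings.value(age + k, sex, clamp=True),
        horizon,
        params,
    )


def lifetime_earnings_loss(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> float:
    """Present value of lost gross earnings for the cohort, incl. fringe.

    Temporary cases (at least one full lost day, under six months) lose
    daily earnings per lost workday; cases with only a fractional day lost
    lose nothing; permanent impairments lose ``impairment_output_loss`` of
    annual earnings to retirement; fatalities lose everything to retirement.
    """
    band = cohort.severity
    age, sex = cohort.midpoint_age, cohort.sex
    annual = profile.annual_earnings.value(age, sex)  # raises if stratum missing
    uplift = 1.0 + profile.fringe_rate
    if band.fatal:
        base = pv_earnings_to_retirement(age, sex, profile, params)
    elif band.permanent:
        base = params.impairment_output_loss * pv_earnings_to_retirement(
            age, sex, profile, params
        )
    else:
        days = band.expected_lost_days
        if days < 1.0:
            return 0.0  # fractional-day cases: no productivity loss
        base = annual / params.working_days_per_year * days
    return cohort.count * base * uplift


def employer_adjustment_cost(
    cohort: CaseCohort, profile: CountryProfile
) -> float:
    """Employer friction costs of replacing or covering for the worker.

    Non-fatal cases with four or more lost days incur half a managerial day
    of production disturbance plus 2.5 clerical hours of administration;
    shorter absences incur nothing.  A fatality costs six months of the
    worker's wages and benefits.
    """
    band = cohort.severity
    if band.fatal:
        annual = profile.annual_earnings.value(cohort.midpoint_age, cohort.sex)
        return cohort.count * 0.5 * annual * (1.0 + profile.fringe_rate)
    if band.lost_days_low >= 4:
        per_case = (
            0.5 * profile.managerial_daily_wage + 2.5 * profile.clerical_hourly_wage
        )
        return cohort.count * per_case
    return 0.0


def home_production_loss(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> float:
    """Value of lost household production, priced at the domestic-services wage.

    Temporary cases lose their daily home-production hours for each lost
    day; permanent impairments and fatalities lose them for the remainder of
    a standard life (conditional life expectancy), discounted like earnings.
    """
    band = cohort.severity
    age, sex = cohort.midpoint_age, cohort.sex
    hours = profile.home_production_hours.value(age, sex, clamp=True)
    wage = profile.domestic_hourly_wage
    if band.fatal or band.permanent:
        horizon = profile.conditional_life_expectancy.value(age, sex)
        base = present_value(hours * 365.0 * wage, horizon, params)
    else:
        base = hours * band.expected_lost_days * wage
    return cohort.count * base


def presenteeism_cost(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> float:
    """Reduced on-the-job productivity around the absence.

    The configured output-loss ratio applies over a fixed working-day window
    valued at daily earnings: after return to work for injuries, both before
    and after the absence for diseases.  Fatalities and permanent cases that
    never return incur no presenteeism.
    """
    band = cohort.severity
    if band.fatal or not band.returns_to_work:
        return 0.0
    if band.expected_lost_days < 1.0:
        return 0.0  # no absence spell, no return-to-work window
    ratio = params.presenteeism_ratio_for(cohort.condition_group)
    windows = 1 if cohort.kind == "injury" else 2
    daily = (
        profile.annual_earnings.value(cohort.midpoint_age, cohort.sex)
        / params.working_days_per_year
    )
    return cohort.count * ratio * windows * params.presenteeism_window_days * daily


def insurance_admin_cost(lost_wages: float, insurance_admin_pct: float) -> float:
    """Insurance administration as a fraction of lost wages."""
    if insurance_admin_pct < 0:
        raise ValueError("insurance admin fraction must be non-negative")
    return lost_wages * insurance_admin_pct


def indirect_cost_items(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> dict[str, float]:
    """All five indirect cost items for a cohort, in euros."""
    earnings = lifetime_earnings_loss(cohort, profile, params)
    return {
        "earnings_loss": earnings,
        "employer_adjustment": employer_adjustment_cost(cohort, profile),
        "home_production": home_production_loss(cohort, profile, params),
        "presenteeism": presenteeism_cost(cohort, profile, params),
        "insurance_admin": insurance_admin_cost(earnings, profile.insurance_admin_pct),
    }
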