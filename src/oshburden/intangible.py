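"""Intangible costs: health-related quality-of-life losses in QALYs.

Quality-of-life losses are counted only for cases with three or more lost
days.  Temporary cases lose a severity-dependent fraction of a full QALY
pro-rated over the lost-time spell; permanent impairments lose that fraction
for every remaining year of conditional life expectancy; fatalities lose one
full QALY per remaining expected life year.  QALYs are monetized at a fixed
willingness-to-pay value (£30,000 ~ €41,100 by default), which makes the
monetized total exactly linear in the QALY value — the property the
sensitivity analysis exploits.
"""

from __future__ import annotations

from .indirect import present_value
from .types import CaseCohort, CountryProfile, ModelParameters


def qaly_loss(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> float:
    """Quality-adjusted life years lost by the cohort (undiscounted by default)."""
    band = cohort.severity
    age, sex = cohort.midpoint_age, cohort.sex
    if band.fatal:
        years = profile.conditional_life_expectancy.value(age, sex)
        per_case = _year_stream(1.0, years, params)
    elif band.permanent:
        mult = _multiplier(params, "permanent")
        years = profile.conditional_life_expectancy.value(age, sex)
        per_case = _year_stream(mult, years, params)
    else:
        if band.expected_lost_days < params.qaly_min_lost_days:
            return 0.0
        mult = _multiplier(params, band.qaly_class)
        per_case = mult * band.expected_lost_days / 365.0
    return cohort.count * per_case


def monetize_qalys(qalys: float, qaly_value: float) -> float:
    """Monetary value of a QALY loss: a pure product."""
    if qaly_value <= 0:
        raise ValueError("QALY value must be positive")
    return qalys * qaly_value


def intangible_cost(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> float:
    """Monetized QALY loss for the cohort, in euros."""
    return monetize_qalys(qaly_loss(cohort, profile, params), params.qaly_value_eur)


def _multiplier(params: ModelParameters, qaly_class: str | None) -> float:
    if qaly_class is None:
        return 0.0
    try:
        return params.qaly_multiplier[qaly_class]
    except KeyError:
        raise KeyError(f"no QALY multiplier for severity class {qaly_class!r}") from None


def _year_stream(annual_qalys: float, years: float, params: ModelParameters) -> float:
    """Sum of an annual QALY stream, optionally discounted (off by default)."""
    if not params.discount_qalys:
        return annual_qalys * max(years, 0.0)
    return present_value(annual_qalys, years, params, apply_growth=False)
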