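"""Direct (healthcare-related) costs per case cohort.

Four items: formal healthcare treatment, patients' out-of-pocket spending,
informal caregiving time, and healthcare administration.  Treatment unit
costs originate from a source country's tariff data and are transferred to
the target country with a hospital-services price adjustment ratio; minor
injuries (three or fewer days lost) instead receive a nominal €100 per case,
which is not price-adjusted.
"""

from __future__ import annotations

from .types import CaseCohort, CountryProfile, ModelParameters


def formal_healthcare_cost(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> float:
    """Formal treatment cost for the cohort.

    Minor injuries (<= 3 days lost) cost the nominal per-case amount.  All
    other cases cost ``unit_cost x price_adjustment_ratio x episode_years``,
    where the treatment episode is capped at one year for injuries and
    short-episode diseases and at two years otherwise.
    """
    band = cohort.severity
    if cohort.kind == "injury" and band.severity_class == "minor":
        return cohort.count * params.minor_injury_healthcare_cost
    try:
        unit = profile.healthcare_unit_cost[cohort.condition_group]
    except KeyError:
        raise KeyError(
            f"no healthcare unit cost for condition group "
            f"{cohort.condition_group!r} (cohort band {cohort.band_id!r})"
        ) from None
    years = params.episode_years(cohort.kind, cohort.condition_group)
    return cohort.count * unit * profile.price_adjustment_ratio * years


def out_of_pocket_cost(formal_cost: float, out_of_pocket_pct: float) -> float:
    """Out-of-pocket spending as a fraction of public-sector treatment cost."""
    if not 0 <= out_of_pocket_pct <= 1:
        raise ValueError("out-of-pocket fraction must lie in [0, 1]")
    return formal_cost * out_of_pocket_pct


def informal_caregiving_cost(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> float:
    """Informal caregiving time valued at the caregiving-services wage.

    Non-fatal cases receive ``caregiving_hours_per_day`` for each lost day,
    capped at six months (183 days by default); fatalities receive care only
    for days survived (default zero).
    """
    band = cohort.severity
    if band.fatal:
        days = params.fatal_caregiving_days
    else:
        cap = params.caregiving_cap_days[cohort.kind]
        days = min(band.expected_lost_days, cap)
    return (
        cohort.count
        * params.caregiving_hours_per_day
        * days
        * profile.caregiver_hourly_wage
    )


def healthcare_admin_cost(formal_cost: float, admin_pct: float) -> float:
    """Healthcare administration as a fraction of treatment cost."""
    if not 0 <= admin_pct <= 1:
        raise ValueError("healthcare admin fraction must lie in [0, 1]")
    return formal_cost * admin_pct


def direct_cost_items(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> dict[str, float]:
    """All four direct cost items for a cohort, in euros."""
    formal = formal_healthcare_cost(cohort, profile, params)
    return {
        "formal_healthcare": formal,
        "out_of_pocket": out_of_pocket_cost(formal, profile.out_of_pocket_pct),
        "informal_caregiving": informal_caregiving_cost(cohort, profile, params),
        "healthcare_admin": healthcare_admin_cost(formal, profile.healthcare_admin_pct),
    }
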