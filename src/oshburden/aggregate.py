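"""National aggregation: burden summaries and stakeholder totals.

Comparison metrics ground the burden at the macro level: percentage of GDP,
cost per incident case, and cost per employed person.
"""

from __future__ import annotations

from .types import (
    CATEGORIES,
    STAKEHOLDERS,
    BurdenSummary,
    CostBreakdown,
    CountryProfile,
)

_CONSERVATION_RTOL = 1e-6


def aggregate_burden(
    cohort_costs: list[CostBreakdown] | CostBreakdown,
    profile: CountryProfile,
) -> BurdenSummary:
    """Assemble cohort cost breakdowns into a national burden summary.

    Raises ``ValueError`` for the ratios that are undefined (zero GDP, zero
    cases, zero employment).
    """
    if isinstance(cohort_costs, CostBreakdown):
        total_bd = cohort_costs
    else:
        total_bd = CostBreakdown()
        for bd in cohort_costs:
            total_bd = total_bd + bd
    by_category = {c: total_bd.category_total(c) for c in CATEGORIES}
    total = sum(by_category.values())
    if profile.gdp <= 0:
        raise ValueError("GDP must be positive to express the burden as %GDP")
    if total_bd.n_cases <= 0:
        raise ValueError("per-case cost undefined for zero cases")
    if profile.employed_persons <= 0:
        raise ValueError("per-employed cost undefined for zero employment")
    stakeholder_totals, societal = allocate_stakeholders(total_bd, profile)
    shares = {
        s: (stakeholder_totals[s] / societal if societal > 0 else 0.0)
        for s in STAKEHOLDERS
    }
    return BurdenSummary(
        total_cost=total,
        by_category=by_category,
        pct_gdp=total / profile.gdp * 100.0,
        per_case=total / total_bd.n_cases,
        per_employed=total / profile.employed_persons,
        stakeholder_shares=shares,
        case_total=total_bd.n_cases,
    )


def allocate_stakeholders(
    breakdown: CostBreakdown, profile: CountryProfile
) -> tuple[dict[str, float], float]:
    """Stakeholder totals and the societal total, with transfers counted once.

    The breakdown already nets wage replacement out of the worker's burden
    and books it against the system as the payer, so stakeholder totals must
    sum to the societal total; a violation beyond rounding tolerance is an
    internal consistency error.
    """
    totals = {s: breakdown.stakeholder_total(s) for s in STAKEHOLDERS}
    societal = breakdown.societal_total
    if societal > 0 and abs(sum(totals.values()) - societal) > _CONSERVATION_RTOL * societal:
        raise RuntimeError(
            "stakeholder totals do not sum to the societal total: "
            f"{sum(totals.values()):.2f} vs {societal:.2f}"
        )
    return totals, societal


def employed_population_from_rate(case_count: float, rate_per_100k: float) -> float:
    """Invert an incidence rate per 100,000 employed persons to a workforce size."""
    if rate_per_100k <= 0:
        raise ValueError("incidence rate must be positive")
    return case_count / rate_per_100k * 100_000.0


def summary_from_category_totals(
    direct: float,
    indirect: float,
    intangible: float,
    case_total: float,
    gdp: float,
    employed_persons: float,
    stakeholder_totals: dict[str, float] | None = None,
) -> BurdenSummary:
    """Burden summary from pre-aggregated category totals (in euros).

    Used when national category totals are available (e.g. published
    estimates) without the underlying cohort-level breakdown.
    """
    by_category = {"direct": direct, "indirect": indirect, "intangible": intangible}
    total = sum(by_category.values())
    if gdp <= 0 or case_total <= 0 or employed_persons <= 0:
        raise ValueError("gdp, case_total and employed_persons must be positive")
    if stakeholder_totals:
        denom = sum(stakeholder_totals.values())
        shares = {s: stakeholder_totals.get(s, 0.0) / denom for s in STAKEHOLDERS}
    else:
        shares = {s: 0.0 for s in STAKEHOLDERS}
    return BurdenSummary(
        total_cost=total,
        by_category=by_category,
        pct_gdp=total / gdp * 100.0,
        per_case=total / case_total,
        per_employed=total / employed_persons,
        stakeholder_shares=shares,
        case_total=case_total,
    )
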