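"""Cohort costing pipeline: subcategory costs and stakeholder attribution.

Every euro of societal cost is attributed to exactly one of three
stakeholders — workers and their families, employers, or the system/public
sector.  Wage replacement moves part of the earnings loss from the worker to
the system: the replaced share is borne by the system as the payer and the
rest by the worker, so stakeholder totals always sum to the societal total,
and the replaced share is additionally recorded as a transfer.
"""

from __future__ import annotations

from .direct import direct_cost_items
from .indirect import indirect_cost_items
from .intangible import intangible_cost
from .types import CaseCohort, CostBreakdown, CountryProfile, ModelParameters

#: Fixed stakeholder attribution of each subcategory except earnings_loss,
#: which is split by the wage-replacement rate.
_ALLOCATION: dict[str, str] = {
    "formal_healthcare": "system_public",
    "out_of_pocket": "worker_family",
    "informal_caregiving": "worker_family",
    "healthcare_admin": "system_public",
    "employer_adjustment": "employer",
    "home_production": "worker_family",
    "presenteeism": "employer",
    "insurance_admin": "system_public",
    "qaly_loss": "worker_family",
}


def cohort_cost_items(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> dict[str, float]:
    """All ten cost subcategories for a cohort, in euros."""
    items = direct_cost_items(cohort, profile, params)
    items.update(indirect_cost_items(cohort, profile, params))
    items["qaly_loss"] = intangible_cost(cohort, profile, params)
    return items


def breakdown_for_cohort(
    cohort: CaseCohort, profile: CountryProfile, params: ModelParameters
) -> CostBreakdown:
    """Cost the cohort and attribute each subcategory to stakeholders."""
    items = cohort_cost_items(cohort, profile, params)
    bd = CostBreakdown(n_cases=cohort.count)
    rr = profile.replacement_rate
    for sub, amount in items.items():
        if amount == 0.0:
            continue
        if sub == "earnings_loss":
            bd.add(sub, "worker_family", (1.0 - rr) * amount)
            if rr * amount > 0.0:
                bd.add(sub, "system_public", rr * amount)
                bd.transfers["wage_replacement"] = (
                    bd.transfers.get("wage_replacement", 0.0) + rr * amount
                )
        else:
            bd.add(sub, _ALLOCATION[sub], amount)
    return bd


def cost_bundle(
    profile: CountryProfile,
    cohorts: list[CaseCohort],
    params: ModelParameters,
) -> CostBreakdown:
    """Total national cost breakdown across all cohorts."""
    total = CostBreakdown()
    for cohort in cohorts:
        total = total + breakdown_for_cohort(cohort, profile, params)
    return total
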