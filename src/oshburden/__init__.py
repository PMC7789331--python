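"""oshburden: societal economic burden of work injuries and diseases.

An incidence-based, bottom-up costing framework: incident case cohorts are
costed over their lifetime across direct healthcare, indirect productivity
and intangible quality-of-life categories, attributed to workers/families,
employers and the system/public sector, and aggregated into national burden
metrics (% of GDP, per case, per employed person) with one-way sensitivity
analysis for the key assumptions.
"""

from importlib import resources as _resources
import json as _json

from .aggregate import (
    aggregate_burden,
    allocate_stakeholders,
    employed_population_from_rate,
    summary_from_category_totals,
)
from .bands import BANDS, NONFATAL_BAND_IDS, SeverityBand, get_band
from .direct import (
    direct_cost_items,
    formal_healthcare_cost,
    healthcare_admin_cost,
    informal_caregiving_cost,
    out_of_pocket_cost,
)
from .incidence import (
    UnderreportingBenchmark,
    adjust_injury_underreporting,
    allocate_severity,
    estimate_attributable_cases,
)
from .indirect import (
    employer_adjustment_cost,
    home_production_loss,
    indirect_cost_items,
    insurance_admin_cost,
    lifetime_earnings_loss,
    presenteeism_cost,
    present_value,
    pv_earnings_to_retirement,
)
from .intangible import intangible_cost, monetize_qalys, qaly_loss
from .io import (
    load_bundle_dir,
    load_country_bundle,
    validate_bundle,
    write_burden_report,
    write_country_bundle,
)
from .pipeline import breakdown_for_cohort, cohort_cost_items, cost_bundle
from .sensitivity import (
    ScenarioResult,
    ScenarioSpec,
    apply_scenario,
    gdp_change_pct,
    load_scenario_library,
    qaly_revaluation_change_pct,
    round_half_even,
    run_one_way,
)
from .synthetic import (
    SynthSpec,
    build_profile,
    default_parameters,
    generate_bundle,
    generate_known_answer_bundle,
)
from .types import (
    AgeCurve,
    AgeTable,
    BurdenSummary,
    CaseCohort,
    CostBreakdown,
    CountryProfile,
    ModelParameters,
    StratumError,
)

__version__ = "0.1.0"


def load_default_parameters() -> ModelParameters:
    """Model parameters from the shipped configuration file."""
    text = _resources.files("oshburden.data").joinpath(
        "default_parameters.json"
    ).read_text()
    return ModelParameters.model_validate(_json.loads(text))
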