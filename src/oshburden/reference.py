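"""Published national burden estimates for the five study countries.

The package ships the printed country-level results — incidence counts with
rates per 100,000 employed persons, burden totals by cost category,
stakeholder totals, and the willingness-to-pay bounds used for QALY
revaluation — as an input table.  These numbers let the aggregation and
sensitivity arithmetic be exercised against real national magnitudes
without any access to the underlying registers: category totals must sum to
the printed total, derived per-case and per-employed metrics must reproduce
the printed ones, and the QALY-revaluation scenario is fully determined by
the category composition.
"""

from __future__ import annotations

import json
from importlib import resources

from .aggregate import employed_population_from_rate, summary_from_category_totals
from .sensitivity import qaly_revaluation_change_pct
from .types import BurdenSummary


def load_reference_tables() -> dict:
    """The shipped reference table as a nested dict keyed by country code."""
    text = (
        resources.files("oshburden.data").joinpath("reference_tables.json").read_text()
    )
    return json.loads(text)


def reference_employed_persons(country: dict) -> float:
    """Workforce size from inverting the non-fatal injury incidence rate."""
    inc = country["incidence"]
    return employed_population_from_rate(
        inc["injury_nonfatal"], inc["injury_nonfatal_per_100k"]
    )


def reference_summary(country: dict) -> BurdenSummary:
    """Rebuild a country's burden summary from its printed components.

    Category totals (printed in M€) are aggregated by the package's own
    arithmetic; the workforce comes from rate inversion and GDP from the
    printed baseline %GDP.
    """
    b = country["burden"]
    return summary_from_category_totals(
        direct=b["direct_meur"] * 1e6,
        indirect=b["indirect_meur"] * 1e6,
        intangible=b["intangible_meur"] * 1e6,
        case_total=b["cases"],
        gdp=country["gdp_meur_implied"] * 1e6,
        employed_persons=reference_employed_persons(country),
        stakeholder_totals={
            k: v * 1e6 for k, v in country["stakeholders_meur"].items()
        },
    )


def qaly_scenario_changes(country: dict, tables: dict) -> tuple[float, float]:
    """(low, high) GDP-change % from revaluing QALYs at the printed GBP bounds.

    Uses the printed intangible and total figures (M€) directly — the
    monetized QALY linearity makes the change scale-invariant, so millions
    of euros work as well as euros.
    """
    b = country["burden"]
    base = tables["qaly_value_gbp"]["baseline"]
    low_ratio = tables["qaly_value_gbp"]["low"] / base
    high_ratio = tables["qaly_value_gbp"]["high"] / base
    return (
        qaly_revaluation_change_pct(b["intangible_meur"], b["total_meur"], low_ratio),
        qaly_revaluation_change_pct(b["intangible_meur"], b["total_meur"], high_ratio),
    )
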