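"""One-way sensitivity analysis over the full costing pipeline.

Each scenario replaces a single input with its lower and upper bound,
re-runs the whole pipeline, and reports the burden as % of GDP plus the
percentage change in total cost relative to baseline (equivalently the
change in %GDP at fixed GDP).  Changes are reported to two decimals with
round-half-even.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from importlib import resources

import yaml

from .aggregate import aggregate_burden
from .pipeline import cost_bundle
from .types import BurdenSummary, CaseCohort, CountryProfile, ModelParameters

#: Parameters the one-way engine understands, with the transformation each
#: bound applies to the (profile, cohorts, params) bundle.
KNOWN_PARAMETERS = (
    "disease_incidence_scale",
    "injury_incidence_scale",
    "minor_injury_addon_cases",
    "qaly_value_gbp",
    "healthcare_cost_scale",
    "impairment_output_loss",
    "caregiving_cap_days",
    "replacement_rate",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """A one-way scenario: one parameter, a lower and an upper bound."""

    name: str
    parameter: str
    low: float
    high: float
    scope: str = "both"  # injuries | diseases | both

    def __post_init__(self) -> None:
        if self.parameter not in KNOWN_PARAMETERS:
            raise ValueError(f"unknown scenario parameter {self.parameter!r}")
        if self.low > self.high:
            raise ValueError("scenario low bound exceeds high bound")
        if self.scope not in ("injuries", "diseases", "both"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class ScenarioResult:
    """%GDP at each bound and the % change in total cost vs baseline."""

    name: str
    pct_gdp_low: float
    pct_gdp_high: float
    gdp_change_low: float
    gdp_change_high: float


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-even, the reporting convention for % figures."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def _scope_kinds(scope: str) -> tuple[str, ...]:
    return {
        "injuries": ("injury",),
        "diseases": ("disease",),
        "both": ("injury", "disease"),
    }[scope]


def apply_scenario(
    profile: CountryProfile,
    cohorts: list[CaseCohort],
    params: ModelParameters,
    parameter: str,
    value: float,
    scope: str = "both",
) -> tuple[CountryProfile, list[CaseCohort], ModelParameters]:
    """Return a bundle with one parameter set to a scenario value."""
    kinds = _scope_kinds(scope)
    if parameter == "disease_incidence_scale":
        cohorts = [
            c.with_count(c.count * value) if c.kind == "disease" else c
            for c in cohorts
        ]
    elif parameter == "injury_incidence_scale":
        # Underreporting adjustment scales non-fatal injuries with >= 4 days lost.
        cohorts = [
            c.with_count(c.count * value)
            if (
                c.kind == "injury"
                and not c.severity.fatal
                and c.severity.lost_days_low >= 4
            )
            else c
            for c in cohorts
        ]
    elif parameter == "minor_injury_addon_cases":
        cohorts = list(cohorts)
        if value > 0:
            # Injuries without any workday lost: nominal healthcare cost only.
            cohorts.append(
                CaseCohort(
                    kind="injury",
                    condition_group="injury",
                    band_id="no_lost_days",
                    age_low=profile.annual_earnings.brackets[0][0],
                    age_high=profile.annual_earnings.brackets[0][1],
                    sex="M",
                    count=value,
                )
            )
    elif parameter == "qaly_value_gbp":
        params = params.model_copy(update={"qaly_value_gbp": value})
    elif parameter == "healthcare_cost_scale":
        profile = profile.model_copy(
            update={
                "healthcare_unit_cost": {
                    k: v * value for k, v in profile.healthcare_unit_cost.items()
                }
            }
        )
        params = params.model_copy(
            update={
                "minor_injury_healthcare_cost": params.minor_injury_healthcare_cost
                * value
            }
        )
    elif parameter == "impairment_output_loss":
        params = params.model_copy(update={"impairment_output_loss": value})
    elif parameter == "caregiving_cap_days":
        caps = dict(params.caregiving_cap_days)
        for kind in kinds:
            caps[kind] = value
        params = params.model_copy(update={"caregiving_cap_days": caps})
    elif parameter == "replacement_rate":
        profile = profile.model_copy(update={"replacement_rate": value})
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ValueError(f"unknown scenario parameter {parameter!r}")
    return profile, cohorts, params


def run_one_way(
    profile: CountryProfile,
    cohorts: list[CaseCohort],
    params: ModelParameters,
    scenario: ScenarioSpec,
    baseline: BurdenSummary | None = None,
) -> ScenarioResult:
    """Recompute the full pipeline at each scenario bound."""
    if baseline is None:
        baseline = aggregate_burden(cost_bundle(profile, cohorts, params), profile)
    results = {}
    for label, value in (("low", scenario.low), ("high", scenario.high)):
        p, c, m = apply_scenario(
            profile, cohorts, params, scenario.parameter, value, scenario.scope
        )
        summary = aggregate_burden(cost_bundle(p, c, m), p)
        results[label] = summary
    return ScenarioResult(
        name=scenario.name,
        pct_gdp_low=results["low"].pct_gdp,
        pct_gdp_high=results["high"].pct_gdp,
        gdp_change_low=gdp_change_pct(baseline.total_cost, results["low"].total_cost),
        gdp_change_high=gdp_change_pct(baseline.total_cost, results["high"].total_cost),
    )


def gdp_change_pct(baseline_total: float, scenario_total: float) -> float:
    """Percentage change in total cost vs baseline, to two decimals."""
    if baseline_total <= 0:
        raise ValueError("baseline total must be positive")
    return round_half_even(
        (scenario_total - baseline_total) / baseline_total * 100.0, 2
    )


def qaly_revaluation_change_pct(
    intangible_total: float, total_cost: float, value_ratio: float
) -> float:
    """GDP-change % when the QALY value is rescaled by ``value_ratio``.

    Monetized intangible cost is exactly linear in the QALY value, so
    revaluing QALYs changes the total by ``(ratio - 1) x intangible share``.
    The full pipeline reproduces this number; the closed form lets the
    scenario be evaluated from published category totals alone.
    """
    if total_cost <= 0:
        raise ValueError("total cost must be positive")
    return round_half_even(
        (value_ratio - 1.0) * intangible_total / total_cost * 100.0, 2
    )


def load_scenario_library(path=None) -> list[ScenarioSpec]:
    """Scenario families shipped with the package (or from a YAML file)."""
    if path is None:
        text = (
            resources.files("oshburden.data").joinpath("scenarios.yaml").read_text()
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return [ScenarioSpec(**entry) for entry in raw["scenarios"]]
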