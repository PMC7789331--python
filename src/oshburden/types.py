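"""Domain types: case cohorts, country profiles, model parameters, results.

All monetary values are expressed in reference-year (2015) euros.  The one
exception is the monetary value of a QALY, which is carried in GBP with a
fixed conversion factor so that the published willingness-to-pay scenario
bounds (£20,000 / £30,000 / £45,000) scale results by exact ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .bands import SeverityBand, get_band

Kind = Literal["injury", "disease"]
Sex = Literal["F", "M"]

STAKEHOLDERS = ("worker_family", "employer", "system_public")
CATEGORIES = ("direct", "indirect", "intangible")

#: Subcategory -> cost category.
CATEGORY_OF: dict[str, str] = {
    "formal_healthcare": "direct",
    "out_of_pocket": "direct",
    "informal_caregiving": "direct",
    "healthcare_admin": "direct",
    "earnings_loss": "indirect",
    "employer_adjustment": "indirect",
    "home_production": "indirect",
    "presenteeism": "indirect",
    "insurance_admin": "indirect",
    "qaly_loss": "intangible",
}


class StratumError(LookupError):
    """A cohort stratum cannot be resolved against the country profile."""


class AgeTable(BaseModel):
    """Step-function lookup of a quantity by age bracket and sex."""

    model_config = ConfigDict(extra="ignore")

    brackets: list[tuple[float, float]]
    F: list[float]
    M: list[float]

    @model_validator(mode="after")
    def _check_lengths(self) -> "AgeTable":
        if len(self.F) != len(self.brackets) or len(self.M) != len(self.brackets):
            raise ValueError("F/M value lists must match the bracket list length")
        for lo, hi in self.brackets:
            if lo > hi:
                raise ValueError(f"bracket ({lo}, {hi}) has low > high")
        return self

    def value(self, age: float, sex: str, clamp: bool = False) -> float:
        """Value for ``age``/``sex``.

        With ``clamp=True`` ages outside the covered range take the nearest
        bracket's value (used when ageing a cohort into the future); with
        ``clamp=False`` an uncovered age raises :class:`StratumError`.
        """
        vals = getattr(self, sex, None)
        if vals is None:
            raise StratumError(f"no values for sex {sex!r}")
        for (lo, hi), v in zip(self.brackets, vals):
            if lo <= age <= hi:
                return v
        if clamp:
            if age < self.brackets[0][0]:
                return vals[0]
            return vals[-1]
        raise StratumError(
            f"age {age} not covered by any bracket {self.brackets}"
        )


class AgeCurve(BaseModel):
    """Piecewise-linear lookup by exact age and sex (life-expectancy style)."""

    model_config = ConfigDict(extra="ignore")

    ages: list[float]
    F: list[float]
    M: list[float]

    @model_validator(mode="after")
    def _check(self) -> "AgeCurve":
        if len(self.F) != len(self.ages) or len(self.M) != len(self.ages):
            raise ValueError("F/M value lists must match the age grid length")
        if sorted(self.ages) != list(self.ages):
            raise ValueError("age grid must be increasing")
        return self

    def value(self, age: float, sex: str) -> float:
        vals = getattr(self, sex, None)
        if vals is None:
            raise StratumError(f"no values for sex {sex!r}")
        return float(np.interp(age, self.ages, vals))


class CaseCohort(BaseModel):
    """A stratum of incident cases.

    Cases are homogeneous in kind, condition group, severity band, age
    bracket and sex; ``count`` may be fractional (attributable-fraction
    estimates are carried at full precision until reporting).
    """

    model_config = ConfigDict(extra="ignore", frozen=True)

    kind: Kind
    condition_group: str
    band_id: str
    age_low: float
    age_high: float
    sex: Sex
    count: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "CaseCohort":
        get_band(self.kind, self.band_id)  # raises on unknown band
        if self.age_low > self.age_high:
            raise ValueError("age_low > age_high")
        return self

    @property
    def severity(self) -> SeverityBand:
        return get_band(self.kind, self.band_id)

    @property
    def midpoint_age(self) -> float:
        return 0.5 * (self.age_low + self.age_high)

    def with_count(self, count: float) -> "CaseCohort":
        return self.model_copy(update={"count": count})


class CountryProfile(BaseModel):
    """Country-specific demographic and economic parameters (2015 euros)."""

    model_config = ConfigDict(extra="ignore")

    country_code: str
    gdp: float = Field(gt=0, description="nominal GDP, reference-year €")
    employed_persons: float = Field(gt=0)
    annual_earnings: AgeTable
    fringe_rate: float = Field(ge=0, le=1)
    price_adjustment_ratio: float = Field(gt=0)
    managerial_daily_wage: float = Field(ge=0)
    clerical_hourly_wage: float = Field(ge=0)
    caregiver_hourly_wage: float = Field(ge=0)
    domestic_hourly_wage: float = Field(ge=0)
    home_production_hours: AgeTable
    healthcare_unit_cost: dict[str, float]
    out_of_pocket_pct: float = Field(ge=0, le=1)
    healthcare_admin_pct: float = Field(ge=0, le=1)
    insurance_admin_pct: float = Field(ge=0, le=1)
    replacement_rate: float = Field(ge=0, le=1)
    conditional_life_expectancy: AgeCurve
    fatal_per_nonfatal_injury: float = Field(ge=0)

    @field_validator("healthcare_unit_cost")
    @classmethod
    def _nonneg_costs(cls, v: dict[str, float]) -> dict[str, float]:
        for k, c in v.items():
            if c < 0:
                raise ValueError(f"healthcare unit cost for {k!r} is negative")
        return v


class ModelParameters(BaseModel):
    """Global costing assumptions.

    Defaults are the baseline assumptions of the framework: €100 nominal
    healthcare for minor injuries, 35 % permanent output loss to retirement
    age 65, one hour of informal care per day capped at six months, 1 %
    productivity growth beyond 2017, values discounted to 2015, and a QALY
    valued at £30,000 (€41,100 at the fixed 1.37 €/£ conversion).
    """

    model_config = ConfigDict(extra="ignore")

    reference_year: int = 2015
    discount_rate: float = Field(default=0.03, ge=0)
    productivity_growth: float = 0.01
    growth_from_year: int = 2018  # growth applies to earnings beyond 2017
    retirement_age: float = 65.0
    impairment_output_loss: float = Field(default=0.35, ge=0, le=1)
    caregiving_hours_per_day: float = Field(default=1.0, ge=0)
    caregiving_cap_days: dict[str, float] = Field(
        default_factory=lambda: {"injury": 183.0, "disease": 183.0}
    )
    fatal_caregiving_days: float = Field(default=0.0, ge=0)
    qaly_value_gbp: float = Field(default=30_000.0, gt=0)
    gbp_to_eur: float = Field(default=1.37, gt=0)
    qaly_min_lost_days: float = 3.0
    discount_qalys: bool = False
    minor_injury_healthcare_cost: float = Field(default=100.0, ge=0)
    qaly_multiplier: dict[str, float] = Field(
        default_factory=lambda: {
            "temporary_minor": 0.1,
            "temporary_serious": 0.3,
            "permanent": 0.4,
        }
    )
    presenteeism_ratio: dict[str, float] = Field(default_factory=dict)
    presenteeism_ratio_default: float = 0.25
    presenteeism_window_days: float = Field(default=30.0, ge=0)
    treatment_episode_years: dict[str, float] = Field(default_factory=dict)
    treatment_episode_years_default: float = 1.0
    working_days_per_year: float = Field(default=230.0, gt=0)

    @field_validator("treatment_episode_years")
    @classmethod
    def _episode_bounds(cls, v: dict[str, float]) -> dict[str, float]:
        for k, y in v.items():
            if not 0 <= y <= 2:
                raise ValueError(f"treatment episode for {k!r} outside [0, 2] years")
        return v

    @field_validator("caregiving_cap_days")
    @classmethod
    def _cap_positive(cls, v: dict[str, float]) -> dict[str, float]:
        for k, d in v.items():
            if d <= 0:
                raise ValueError(f"caregiving cap for {k!r} must be positive")
        return v

    @property
    def qaly_value_eur(self) -> float:
        return self.qaly_value_gbp * self.gbp_to_eur

    def episode_years(self, kind: str, condition_group: str) -> float:
        """Treatment-episode length in years; injuries capped at one year."""
        years = self.treatment_episode_years.get(
            condition_group, self.treatment_episode_years_default
        )
        if kind == "injury":
            years = min(years, 1.0)
        return years

    def presenteeism_ratio_for(self, condition_group: str) -> float:
        return self.presenteeism_ratio.get(
            condition_group, self.presenteeism_ratio_default
        )


@dataclass
class CostBreakdown:
    """Costs by subcategory and stakeholder for a cohort or a country.

    ``amounts[subcategory][stakeholder]`` holds euros borne by each
    stakeholder, with every euro of societal cost attributed exactly once.
    ``transfers`` records payments that move money between stakeholders
    (wage replacement): they are part of a payer's burden composition but
    never add to the societal total.
    """

    amounts: dict[str, dict[str, float]] = field(default_factory=dict)
    transfers: dict[str, float] = field(default_factory=dict)
    n_cases: float = 0.0

    def add(self, subcategory: str, stakeholder: str, amount: float) -> None:
        if amount < 0:
            raise ValueError(f"negative amount for {subcategory}/{stakeholder}")
        if subcategory not in CATEGORY_OF:
            raise KeyError(f"unknown subcategory {subcategory!r}")
        sub = self.amounts.setdefault(subcategory, {})
        sub[stakeholder] = sub.get(stakeholder, 0.0) + amount

    def subcategory_total(self, subcategory: str) -> float:
        return sum(self.amounts.get(subcategory, {}).values())

    def category_total(self, category: str) -> float:
        return sum(
            self.subcategory_total(s)
            for s, c in CATEGORY_OF.items()
            if c == category
        )

    def stakeholder_total(self, stakeholder: str) -> float:
        return sum(v.get(stakeholder, 0.0) for v in self.amounts.values())

    @property
    def societal_total(self) -> float:
        return sum(self.category_total(c) for c in CATEGORIES)

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        out = CostBreakdown(n_cases=self.n_cases + other.n_cases)
        for src in (self, other):
            for sub, by_stk in src.amounts.items():
                for stk, amt in by_stk.items():
                    out.add(sub, stk, amt)
            for name, amt in src.transfers.items():
                out.transfers[name] = out.transfers.get(name, 0.0) + amt
        return out


@dataclass
class BurdenSummary:
    """National burden totals and comparison metrics (2015 euros)."""

    total_cost: float
    by_category: dict[str, float]
    pct_gdp: float
    per_case: float
    per_employed: float
    stakeholder_shares: dict[str, float]
    case_total: float

    def category_share(self, category: str) -> float:
        return self.by_category[category] / self.total_cost if self.total_cost else 0.0
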