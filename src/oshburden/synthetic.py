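"""Synthetic country bundles with the structure the costing model assumes.

The generator emulates what national statistical sources provide: incident
case counts stratified by severity band, age bracket and sex (multinomially
sampled so totals are conserved exactly), an age-sex earnings curve, wage
rates for the four priced labour types, and a fatal:non-fatal injury ratio
in the range observed across European countries.  Defaults are calibrated
to Finland-like magnitudes — about 63,400 non-fatal injuries (35 fatal) and
68,400 diseases in a workforce of 2.44 million — the smallest of the study
countries.

A single integer seed drives one ``numpy.random.default_rng`` stream; draws
are made in a fixed order (injuries first, then diseases, each as one
multinomial over the full condition x band x age x sex grid), so bundles
are bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .bands import NONFATAL_BAND_IDS, get_band
from .types import (
    AgeCurve,
    AgeTable,
    BurdenSummary,
    CaseCohort,
    CountryProfile,
    ModelParameters,
)

#: Condition groups with treatment episodes of 1 to 2 years (chronic
#: management); all other groups are capped at one year.
LONG_EPISODE_GROUPS = (
    "cardiovascular",
    "respiratory",
    "musculoskeletal",
    "mental_health",
    "cancer",
)

_DEFAULT_DISEASE_GROUPS = {
    "musculoskeletal": 0.40,
    "mental_health": 0.15,
    "respiratory": 0.10,
    "hearing": 0.10,
    "skin": 0.08,
    "cardiovascular": 0.07,
    "cancer": 0.05,
    "infectious": 0.05,
}

_DEFAULT_UNIT_COSTS = {
    "injury": 2500.0,
    "musculoskeletal": 2000.0,
    "mental_health": 3000.0,
    "respiratory": 4000.0,
    "hearing": 1500.0,
    "skin": 800.0,
    "cardiovascular": 8000.0,
    "cancer": 15000.0,
    "infectious": 1000.0,
}


class SynthSpec(BaseModel):
    """Specification of a synthetic country bundle."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_injury_cases: int = Field(default=63_407, ge=0)
    n_disease_cases: int = Field(default=68_423, ge=0)
    severity_probs: dict[str, list[float]] = Field(
        default_factory=lambda: {
            "injury": [0.30, 0.40, 0.235, 0.045, 0.013, 0.007],
            "disease": [0.15, 0.40, 0.22, 0.21, 0.02],
        }
    )
    fatal_rate: dict[str, float] = Field(
        default_factory=lambda: {
            "injury": 35 / 63_407,
            "disease": 628 / 68_423,
        }
    )
    disease_group_probs: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_DISEASE_GROUPS)
    )
    age_brackets: list[tuple[float, float]] = Field(
        default_factory=lambda: [(15, 24), (25, 34), (35, 44), (45, 54), (55, 64)]
    )
    age_distribution: list[float] = Field(
        default_factory=lambda: [0.10, 0.22, 0.25, 0.25, 0.18]
    )
    sex_split: float = Field(default=0.40, ge=0, le=1)  # share of cases female
    earnings_base: float = Field(default=38_000.0, gt=0)
    earnings_age_factors: list[float] = Field(
        default_factory=lambda: [0.60, 0.90, 1.05, 1.10, 1.05]
    )
    earnings_sex_gap: float = Field(default=0.16, ge=0, lt=1)
    fringe_rate: float = Field(default=0.22, ge=0, le=1)
    wage_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "managerial_daily": 400.0,
            "clerical_hourly": 20.0,
            "caregiver_hourly": 15.0,
            "domestic_hourly": 12.0,
        }
    )
    employed_persons: float = Field(default=2_436_856.0, gt=0)
    gdp_per_worker: float = Field(default=86_000.0, gt=0)
    healthcare_unit_cost: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_UNIT_COSTS)
    )
    price_adjustment_ratio: float = Field(default=1.2, gt=0)
    out_of_pocket_pct: float = Field(default=0.15, ge=0, le=1)
    healthcare_admin_pct: float = Field(default=0.04, ge=0, le=1)
    insurance_admin_pct: float = Field(default=0.101, ge=0, le=1)
    replacement_rate: float = Field(default=0.8, ge=0, le=1)
    home_production_hours: tuple[float, float] = (2.5, 1.5)  # (F, M) h/day

    @model_validator(mode="after")
    def _check_probs(self) -> "SynthSpec":
        for kind, probs in self.severity_probs.items():
            if kind not in NONFATAL_BAND_IDS:
                raise ValueError(f"unknown kind {kind!r} in severity_probs")
            if len(probs) != len(NONFATAL_BAND_IDS[kind]):
                raise ValueError(
                    f"severity_probs[{kind!r}] must have "
                    f"{len(NONFATAL_BAND_IDS[kind])} entries"
                )
            _validate_prob_vector(probs, f"severity_probs[{kind!r}]")
        _validate_prob_vector(self.age_distribution, "age_distribution")
        if len(self.age_distribution) != len(self.age_brackets):
            raise ValueError("age_distribution must match age_brackets")
        if len(self.earnings_age_factors) != len(self.age_brackets):
            raise ValueError("earnings_age_factors must match age_brackets")
        _validate_prob_vector(
            list(self.disease_group_probs.values()), "disease_group_probs"
        )
        for kind, rate in self.fatal_rate.items():
            if not 0 <= rate < 1:
                raise ValueError(f"fatal_rate[{kind!r}] must lie in [0, 1)")
        return self


def _validate_prob_vector(probs: list[float], name: str) -> None:
    if any(p < 0 for p in probs):
        raise ValueError(f"{name} has negative entries")
    s = sum(probs)
    if s <= 0:
        raise ValueError(f"{name} is degenerate (all zero)")
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {s})")


def build_profile(spec: SynthSpec) -> CountryProfile:
    """Country profile implied by the spec (deterministic, no sampling)."""
    male = [spec.earnings_base * f for f in spec.earnings_age_factors]
    female = [m * (1.0 - spec.earnings_sex_gap) for m in male]
    hours_f, hours_m = spec.home_production_hours
    n = len(spec.age_brackets)
    # Remaining life expectancy: linear-ish decline, women outliving men.
    ages = [15.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0, 95.0, 105.0]
    le_f = [69.0, 59.5, 50.0, 40.7, 31.6, 21.5, 13.5, 7.0, 3.0, 1.0]
    le_m = [65.0, 55.6, 46.2, 37.0, 28.2, 18.6, 11.4, 5.8, 2.5, 1.0]
    return CountryProfile(
        country_code="SYN",
        gdp=spec.gdp_per_worker * spec.employed_persons,
        employed_persons=spec.employed_persons,
        annual_earnings=AgeTable(brackets=spec.age_brackets, F=female, M=male),
        fringe_rate=spec.fringe_rate,
        price_adjustment_ratio=spec.price_adjustment_ratio,
        managerial_daily_wage=spec.wage_rates["managerial_daily"],
        clerical_hourly_wage=spec.wage_rates["clerical_hourly"],
        caregiver_hourly_wage=spec.wage_rates["caregiver_hourly"],
        domestic_hourly_wage=spec.wage_rates["domestic_hourly"],
        home_production_hours=AgeTable(
            brackets=spec.age_brackets, F=[hours_f] * n, M=[hours_m] * n
        ),
        healthcare_unit_cost=dict(spec.healthcare_unit_cost),
        out_of_pocket_pct=spec.out_of_pocket_pct,
        healthcare_admin_pct=spec.healthcare_admin_pct,
        insurance_admin_pct=spec.insurance_admin_pct,
        replacement_rate=spec.replacement_rate,
        conditional_life_expectancy=AgeCurve(ages=ages, F=le_f, M=le_m),
        fatal_per_nonfatal_injury=spec.fatal_rate["injury"],
    )


def default_parameters() -> ModelParameters:
    """Model parameters with per-condition treatment episode lengths."""
    episodes = {g: 1.5 for g in LONG_EPISODE_GROUPS}
    episodes["injury"] = 1.0
    return ModelParameters(treatment_episode_years=episodes)


def generate_bundle(spec: SynthSpec) -> tuple[CountryProfile, list[CaseCohort]]:
    """Sample a loadable country bundle; deterministic given ``spec.seed``.

    Case counts are one multinomial draw per kind over the full
    (condition group x severity band x age bracket x sex) grid, so cohort
    counts sum to the requested totals exactly.
    """
    rng = np.random.default_rng(spec.seed)
    profile = build_profile(spec)
    cohorts: list[CaseCohort] = []
    for kind, n_cases in (
        ("injury", spec.n_injury_cases),
        ("disease", spec.n_disease_cases),
    ):
        cohorts.extend(_sample_kind(spec, rng, kind, n_cases))
    return profile, cohorts


def _sample_kind(
    spec: SynthSpec, rng: np.random.Generator, kind: str, n_cases: int
) -> list[CaseCohort]:
    if n_cases == 0:
        return []
    band_ids = list(NONFATAL_BAND_IDS[kind]) + ["fatal"]
    fatal = spec.fatal_rate[kind]
    band_p = np.array(spec.severity_probs[kind]) * (1.0 - fatal)
    band_p = np.append(band_p, fatal)
    if kind == "injury":
        groups, group_p = ["injury"], np.array([1.0])
    else:
        groups = list(spec.disease_group_probs)
        group_p = np.array([spec.disease_group_probs[g] for g in groups])
    age_p = np.array(spec.age_distribution)
    sex_p = np.array([spec.sex_split, 1.0 - spec.sex_split])
    # joint over (group, band, age, sex), flattened in C order
    joint = np.einsum("g,b,a,s->gbas", group_p, band_p, age_p, sex_p).ravel()
    joint = joint / joint.sum()
    counts = rng.multinomial(n_cases, joint).reshape(
        len(groups), len(band_ids), len(spec.age_brackets), 2
    )
    out = []
    for gi, group in enumerate(groups):
        for bi, band_id in enumerate(band_ids):
            for ai, (lo, hi) in enumerate(spec.age_brackets):
                for si, sex in enumerate(("F", "M")):
                    c = int(counts[gi, bi, ai, si])
                    if c > 0:
                        out.append(
                            CaseCohort(
                                kind=kind,
                                condition_group=group,
                                band_id=band_id,
                                age_low=lo,
                                age_high=hi,
                                sex=sex,
                                count=c,
                            )
                        )
    return out


def generate_known_answer_bundle(
    spec: SynthSpec, target_per_case_cost: float
) -> tuple[CountryProfile, list[CaseCohort], ModelParameters, BurdenSummary]:
    """Bundle whose burden has a closed form, for parameter-recovery tests.

    Requires a spec restricted to a single temporary injury severity band
    with no fatalities and no diseases.  All cost components other than the
    absence earnings loss are zeroed and discounting/growth switched off, so
    per-case cost is exactly ``daily_wage x lost_days x (1 + fringe)``; the
    daily wage is chosen to hit ``target_per_case_cost`` and the analytic
    :class:`BurdenSummary` is returned alongside the bundle.
    """
    if target_per_case_cost <= 0:
        raise ValueError("target per-case cost must be positive")
    probs = spec.severity_probs["injury"]
    hot = [i for i, p in enumerate(probs) if p > 0]
    if len(hot) != 1:
        raise ValueError(
            "known-answer bundle needs severity_probs degenerate on one band"
        )
    band = get_band("injury", NONFATAL_BAND_IDS["injury"][hot[0]])
    if band.permanent or band.expected_lost_days < 1:
        raise ValueError(
            "known-answer bundle needs a temporary band with >= 1 lost day"
        )
    if spec.fatal_rate["injury"] != 0 or spec.n_disease_cases != 0:
        raise ValueError("known-answer bundle must have no fatalities or diseases")

    params = default_parameters().model_copy(
        update={
            "discount_rate": 0.0,
            "productivity_growth": 0.0,
            "minor_injury_healthcare_cost": 0.0,
            "qaly_multiplier": {
                "temporary_minor": 0.0,
                "temporary_serious": 0.0,
                "permanent": 0.0,
            },
            "presenteeism_ratio_default": 0.0,
        }
    )
    days = band.expected_lost_days
    daily = target_per_case_cost / (days * (1.0 + spec.fringe_rate))
    annual = daily * params.working_days_per_year
    flat = spec.model_copy(
        update={
            "earnings_base": annual,
            "earnings_age_factors": [1.0] * len(spec.age_brackets),
            "earnings_sex_gap": 0.0,
            "wage_rates": {
                "managerial_daily": 0.0,
                "clerical_hourly": 0.0,
                "caregiver_hourly": 0.0,
                "domestic_hourly": 0.0,
            },
            "healthcare_unit_cost": {k: 0.0 for k in spec.healthcare_unit_cost},
            "out_of_pocket_pct": 0.0,
            "healthcare_admin_pct": 0.0,
            "insurance_admin_pct": 0.0,
            "home_production_hours": (0.0, 0.0),
        }
    )
    profile, cohorts = generate_bundle(flat)
    n = flat.n_injury_cases
    total = n * target_per_case_cost
    rr = profile.replacement_rate
    expected = BurdenSummary(
        total_cost=total,
        by_category={"direct": 0.0, "indirect": total, "intangible": 0.0},
        pct_gdp=total / profile.gdp * 100.0,
        per_case=target_per_case_cost,
        per_employed=total / profile.employed_persons,
        stakeholder_shares={
            "worker_family": 1.0 - rr,
            "employer": 0.0,
            "system_public": rr,
        },
        case_total=float(n),
    )
    return profile, cohorts, params, expected
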