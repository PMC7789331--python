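"""Readers and writers for country bundles and burden reports.

A country bundle is three text files: a country profile (JSON), an
incidence table (CSV with columns ``kind,condition_group,band_id,age_low,
age_high,sex,count``) and a model-parameter file (JSON).  Reports are three
CSV tables mirroring the layout national burden studies print: incidence,
category totals with shares, and stakeholder totals with shares, all in
reference-year euros.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .aggregate import allocate_stakeholders
from .types import (
    CATEGORIES,
    STAKEHOLDERS,
    BurdenSummary,
    CaseCohort,
    CostBreakdown,
    CountryProfile,
    ModelParameters,
    StratumError,
)

INCIDENCE_COLUMNS = [
    "kind",
    "condition_group",
    "band_id",
    "age_low",
    "age_high",
    "sex",
    "count",
]


def load_country_bundle(
    profile_path: str | Path,
    incidence_path: str | Path,
    params_path: str | Path,
) -> tuple[CountryProfile, list[CaseCohort], ModelParameters]:
    """Load and validate a country bundle.

    Every cohort stratum must be resolvable against the profile: a cohort
    whose age bracket or sex has no earnings entry is a hard error naming
    the stratum; unknown severity bands and negative counts are hard errors
    from cohort validation.
    """
    with open(profile_path, "r", encoding="utf-8") as fh:
        profile = CountryProfile.model_validate(json.load(fh))
    with open(params_path, "r", encoding="utf-8") as fh:
        params = ModelParameters.model_validate(json.load(fh))
    frame = pd.read_csv(incidence_path)
    missing = [c for c in INCIDENCE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"incidence file lacks required columns: {missing}")
    cohorts = [
        CaseCohort(**{c: row[c] for c in INCIDENCE_COLUMNS})
        for row in frame.to_dict("records")
    ]
    validate_bundle(profile, cohorts)
    return profile, cohorts, params


def validate_bundle(profile: CountryProfile, cohorts: list[CaseCohort]) -> None:
    """Check that every cohort's earnings stratum exists in the profile."""
    for cohort in cohorts:
        try:
            profile.annual_earnings.value(cohort.midpoint_age, cohort.sex)
        except StratumError as err:
            raise StratumError(
                f"cohort {cohort.kind}/{cohort.condition_group}/{cohort.band_id} "
                f"age {cohort.age_low:g}-{cohort.age_high:g} sex {cohort.sex}: {err}"
            ) from err


def write_country_bundle(
    profile: CountryProfile,
    cohorts: list[CaseCohort],
    params: ModelParameters,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a loadable bundle (profile.json, incidence.csv, parameters.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "profile": out / "profile.json",
        "incidence": out / "incidence.csv",
        "params": out / "parameters.json",
    }
    paths["profile"].write_text(
        json.dumps(profile.model_dump(), indent=2), encoding="utf-8"
    )
    paths["params"].write_text(
        json.dumps(params.model_dump(), indent=2), encoding="utf-8"
    )
    frame = pd.DataFrame(
        [{c: getattr(k, c) for c in INCIDENCE_COLUMNS} for k in cohorts],
        columns=INCIDENCE_COLUMNS,
    )
    frame.to_csv(paths["incidence"], index=False)
    return paths


def load_bundle_dir(
    bundle_dir: str | Path,
) -> tuple[CountryProfile, list[CaseCohort], ModelParameters]:
    """Load a bundle from a directory written by :func:`write_country_bundle`."""
    d = Path(bundle_dir)
    return load_country_bundle(
        d / "profile.json", d / "incidence.csv", d / "parameters.json"
    )


def _fmt_meur(amount_eur: float, share: float) -> str:
    return f"M€{round(amount_eur / 1e6):,.0f} ({round(share * 100):.0f}%)"


def write_burden_report(
    summary: BurdenSummary,
    breakdown: CostBreakdown,
    out_dir: str | Path,
    cohorts: list[CaseCohort] | None = None,
    profile: CountryProfile | None = None,
) -> dict[str, Path]:
    """Write the three report tables; raw euro columns allow exact re-reads.

    Totals are additionally formatted to printed-report precision: nearest
    M€ with whole-percent shares for categories and stakeholders.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    total = summary.total_cost

    rows = []
    for cat in CATEGORIES:
        amount = summary.by_category[cat]
        share = amount / total if total > 0 else 0.0
        rows.append(
            {
                "category": cat,
                "cost_eur": amount,
                "cost_meur": round(amount / 1e6),
                "share_pct": round(share * 100),
                "formatted": _fmt_meur(amount, share),
            }
        )
    rows.append(
        {
            "category": "total",
            "cost_eur": total,
            "cost_meur": round(total / 1e6),
            "share_pct": 100 if total > 0 else 0,
            "formatted": _fmt_meur(total, 1.0 if total > 0 else 0.0),
        }
    )
    table2 = pd.DataFrame(rows)
    table2["per_case_eur"] = round(summary.per_case)
    table2["per_employed_eur"] = round(summary.per_employed)
    table2["pct_gdp"] = round(summary.pct_gdp, 1)
    p2 = out / "table2_categories.csv"
    table2.to_csv(p2, index=False)

    stk_rows = []
    if profile is not None:
        totals, societal = allocate_stakeholders(breakdown, profile)
    else:
        totals = {s: breakdown.stakeholder_total(s) for s in STAKEHOLDERS}
        societal = breakdown.societal_total
    for stk in STAKEHOLDERS:
        share = totals[stk] / societal if societal > 0 else 0.0
        stk_rows.append(
            {
                "stakeholder": stk,
                "cost_eur": totals[stk],
                "cost_meur": round(totals[stk] / 1e6),
                "share_pct": round(share * 100),
                "formatted": _fmt_meur(totals[stk], share),
            }
        )
    p3 = out / "table3_stakeholders.csv"
    pd.DataFrame(stk_rows).to_csv(p3, index=False)

    p1 = out / "table1_incidence.csv"
    _incidence_table(cohorts or [], profile).to_csv(p1, index=False)
    return {"incidence": p1, "categories": p2, "stakeholders": p3}


def _incidence_table(
    cohorts: list[CaseCohort], profile: CountryProfile | None
) -> pd.DataFrame:
    rows = []
    employed = profile.employed_persons if profile is not None else None
    for kind in ("injury", "disease"):
        for fatal in (False, True):
            n = sum(
                c.count
                for c in cohorts
                if c.kind == kind and c.severity.fatal == fatal
            )
            rows.append(
                {
                    "kind": kind,
                    "outcome": "fatal" if fatal else "non_fatal",
                    "cases": n,
                    "per_100k_employed": (
                        round(n / employed * 100_000, 1) if employed else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)
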