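#!/usr/bin/env python
"""Estimate the national burden for the synthetic bundle.

Loads results/bundle/, costs every cohort across the ten subcategories,
aggregates to the national level and writes the three report tables
(incidence, category totals, stakeholder totals) to results/report/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import oshburden as ob
from oshburden.types import CATEGORY_OF

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=ROOT / "results" / "bundle")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "report")
    args = parser.parse_args()

    profile, cohorts, params = ob.load_bundle_dir(args.bundle)
    breakdown = ob.cost_bundle(profile, cohorts, params)
    summary = ob.aggregate_burden(breakdown, profile)
    paths = ob.write_burden_report(
        summary, breakdown, args.out, cohorts=cohorts, profile=profile
    )

    print(f"report written to {args.out}")
    print(
        f"  total burden M€{summary.total_cost / 1e6:,.0f}"
        f" = {summary.pct_gdp:.1f}% of GDP"
    )
    for cat in ("direct", "indirect", "intangible"):
        print(
            f"  {cat:>10}: M€{summary.by_category[cat] / 1e6:,.0f}"
            f" ({summary.category_share(cat):.0%})"
        )
    print(
        f"  €{summary.per_case:,.0f} per case,"
        f" €{summary.per_employed:,.0f} per employed person"
    )
    print("  subcategories (M€):")
    for sub in CATEGORY_OF:
        print(f"    {sub:>20}: {breakdown.subcategory_total(sub) / 1e6:>8,.0f}")
    for s, share in summary.stakeholder_shares.items():
        print(f"  {s:>15} bears {share:.0%}")
    print(f"tables: {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
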