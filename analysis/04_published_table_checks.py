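#!/usr/bin/env python
"""Consistency checks of the aggregation arithmetic against published tables.

Rebuilds each published country's burden summary from its component values
(category totals, stakeholder totals, incidence rates) through the package's
aggregation engine and compares derived metrics — total, per case, per
employed person, shares, and the QALY-revaluation changes — with the
published figures.  Writes results/published_checks.csv.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from oshburden import reference as ref

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--out", type=Path, default=ROOT / "results" / "published_checks.csv"
    )
    args = parser.parse_args()

    tables = ref.load_reference_tables()
    rows = []
    for code in sorted(tables["countries"]):
        country = tables["countries"][code]
        b = country["burden"]
        summary = ref.reference_summary(country)
        low, high = ref.qaly_scenario_changes(country, tables)
        rows.append(
            {
                "country": code,
                "total_meur_derived": round(summary.total_cost / 1e6),
                "total_meur_published": b["total_meur"],
                "per_case_derived": round(summary.per_case),
                "per_case_published": b["per_case_eur"],
                "per_employed_derived": round(summary.per_employed),
                "per_employed_published": b["per_employed_eur"],
                "worker_share_derived_pct": round(
                    summary.stakeholder_shares["worker_family"] * 100
                ),
                "worker_share_published_pct": country["stakeholder_shares_pct"][
                    "worker_family"
                ],
                "qaly_change_low_derived": low,
                "qaly_change_low_published": country["qaly_change_pct"]["low"],
                "qaly_change_high_derived": high,
                "qaly_change_high_published": country["qaly_change_pct"]["high"],
            }
        )
        print(
            f"{code}: total M€{rows[-1]['total_meur_derived']:,}"
            f" (published {b['total_meur']:,}),"
            f" per case €{rows[-1]['per_case_derived']:,}"
            f" (published {b['per_case_eur']:,}),"
            f" QALY change {low:+.2f}/{high:+.2f}"
            f" (published {country['qaly_change_pct']['low']:+.2f}"
            f"/{country['qaly_change_pct']['high']:+.2f})"
        )

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
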