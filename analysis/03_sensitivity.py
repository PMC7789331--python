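#!/usr/bin/env python
"""One-way sensitivity analysis over the synthetic bundle.

Runs the eight shipped scenario families (disease incidence, injury
underreporting, no-workday-lost add-on, QALY value, healthcare cost scale,
permanent earnings-loss fraction, caregiving caps) and writes the
lower/upper %GDP and %change table to results/sensitivity.csv.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

import oshburden as ob

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=ROOT / "results" / "bundle")
    parser.add_argument(
        "--out", type=Path, default=ROOT / "results" / "sensitivity.csv"
    )
    args = parser.parse_args()

    profile, cohorts, params = ob.load_bundle_dir(args.bundle)
    baseline = ob.aggregate_burden(ob.cost_bundle(profile, cohorts, params), profile)
    print(f"baseline: {baseline.pct_gdp:.2f}% of GDP")

    rows = []
    for spec in ob.load_scenario_library():
        res = ob.run_one_way(profile, cohorts, params, spec, baseline=baseline)
        rows.append(
            {
                "scenario": res.name,
                "pct_gdp_low": round(res.pct_gdp_low, 2),
                "pct_gdp_high": round(res.pct_gdp_high, 2),
                "gdp_change_low_pct": res.gdp_change_low,
                "gdp_change_high_pct": res.gdp_change_high,
            }
        )
        print(
            f"  {res.name:>26}: %GDP {res.pct_gdp_low:.2f};{res.pct_gdp_high:.2f}"
            f"  change {res.gdp_change_low:+.2f};{res.gdp_change_high:+.2f}"
        )

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
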