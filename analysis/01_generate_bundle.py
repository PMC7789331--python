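#!/usr/bin/env python
"""Generate the Finland-like synthetic country bundle used by the analysis.

Writes a loadable bundle (profile.json, incidence.csv, parameters.json) to
results/bundle/ and prints the sampled incidence structure: totals by kind,
fatal counts, and the severity-band distribution.
"""

from __future__ import annotations

import argparse
from collections import Counter
from pathlib import Path

import oshburden as ob

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2015)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "bundle")
    args = parser.parse_args()

    spec = ob.SynthSpec(seed=args.seed)
    profile, cohorts = ob.generate_bundle(spec)
    ob.write_country_bundle(profile, cohorts, ob.default_parameters(), args.out)

    print(f"bundle written to {args.out} (seed {args.seed})")
    for kind in ("injury", "disease"):
        total = sum(c.count for c in cohorts if c.kind == kind)
        fatal = sum(c.count for c in cohorts if c.kind == kind and c.severity.fatal)
        print(f"  {kind}: {total:,.0f} cases, of which {fatal:,.0f} fatal")
        bands = Counter()
        for c in cohorts:
            if c.kind == kind:
                bands[c.band_id] += c.count
        for band_id, n in sorted(bands.items(), key=lambda kv: -kv[1]):
            print(f"    {band_id:>12}: {n:>8,.0f} ({n / total:.1%})")


if __name__ == "__main__":
    main()
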