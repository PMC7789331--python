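"""Incidence adjustment: underreporting correction and severity allocation.

Registered non-fatal injury counts understate true incidence in countries
where reporting incentives are weak.  Fatal injuries, by contrast, are
reliably registered everywhere, so a benchmark country's fatal:non-fatal
ratio yields a floor for the true non-fatal count: ``fatal / ratio``.
Occupational disease incidence is built from compensated registers plus, for
selected condition groups, attributable fractions applied to population
incidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class UnderreportingBenchmark:
    """Fatal-to-non-fatal injury ratio of a well-reporting benchmark country."""

    benchmark_fatal_per_nonfatal: float
    source_country: str = ""

    def __post_init__(self) -> None:
        if self.benchmark_fatal_per_nonfatal <= 0:
            raise ValueError("benchmark fatal:non-fatal ratio must be positive")


def adjust_injury_underreporting(
    registered_nonfatal: float,
    fatal_count: float,
    benchmark: UnderreportingBenchmark,
) -> tuple[float, float]:
    """Adjust a registered non-fatal injury count for underreporting.

    Returns ``(adjusted_count, implied_ratio)`` where
    ``adjusted = max(registered, fatal / benchmark_ratio)`` and
    ``implied_ratio = adjusted / registered``.  The adjustment only ever
    inflates: a register that already exceeds the benchmark-implied floor is
    taken at face value (its fatal:non-fatal ratio is already comparable to
    the benchmark's).
    """
    if registered_nonfatal < 0 or fatal_count < 0:
        raise ValueError("case counts must be non-negative")
    implied = fatal_count / benchmark.benchmark_fatal_per_nonfatal
    adjusted = max(registered_nonfatal, implied)
    ratio = adjusted / registered_nonfatal if registered_nonfatal > 0 else math.inf
    return adjusted, ratio


def estimate_attributable_cases(
    population_cases: float, attributable_fraction: float
) -> float:
    """Work-related cases = population incidence x attributable fraction.

    The product is kept as a real number; rounding to whole cases happens
    only in final reports.
    """
    if not 0 <= attributable_fraction <= 1:
        raise ValueError("attributable fraction must lie in [0, 1]")
    if population_cases < 0:
        raise ValueError("population cases must be non-negative")
    return population_cases * attributable_fraction


def allocate_severity(total_cases: int, severity_probs: list[float]) -> list[int]:
    """Deterministically split ``total_cases`` over bands by probability.

    Uses largest-remainder rounding so the integer counts sum to
    ``total_cases`` exactly; ties in the fractional remainders are broken by
    band order.
    """
    if total_cases < 0:
        raise ValueError("total_cases must be non-negative")
    if any(p < 0 for p in severity_probs):
        raise ValueError("severity probabilities must be non-negative")
    s = sum(severity_probs)
    if s <= 0:
        raise ValueError("severity probabilities sum to zero")
    exact = [total_cases * p / s for p in severity_probs]
    counts = [int(math.floor(x)) for x in exact]
    shortfall = total_cases - sum(counts)
    remainders = sorted(
        range(len(exact)), key=lambda i: (exact[i] - counts[i], -i), reverse=True
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts
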