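"""Severity bands for work injuries and diseases.

Incident cases are stratified into lost-work-time bands that mirror the
reporting conventions of European accident-at-work statistics (ESAW) and the
EU Labour Force Survey: injuries in 0-3 / 4-14 / 15-90 / 91-180 / 181-365
days lost, never-return and fatal; diseases in <3 / 4-30 / 31-90 / >90 days
lost, never-return and fatal.  Every band carries the information the costing
model needs: the expected number of lost workdays (band midpoint), whether
the case is permanently impaired (more than six months of lost time) and
whether it is fatal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class SeverityBand:
    """A lost-work-time severity band.

    Parameters
    ----------
    kind
        ``"injury"`` or ``"disease"``.
    band_id
        Stable label used in incidence files (e.g. ``"4-14"``).
    lost_days_low, lost_days_high
        Band edges in lost workdays; ``lost_days_high=None`` marks an
        open-ended (never-return) band.
    permanent
        Case never recovers full work capacity (more than six months lost,
        including never-return).
    fatal
        Case is a fatality; mutually exclusive with ``permanent``.
    """

    kind: str
    band_id: str
    lost_days_low: float
    lost_days_high: float | None
    permanent: bool = False
    fatal: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("injury", "disease"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.fatal and self.permanent:
            raise ValueError("a band cannot be both fatal and permanent")
        if self.lost_days_high is not None and self.lost_days_low > self.lost_days_high:
            raise ValueError(
                f"band {self.band_id}: lost_days_low > lost_days_high"
            )

    @property
    def expected_lost_days(self) -> float:
        """Expected lost workdays: the arithmetic midpoint of the band.

        Open-ended (never-return) bands return ``inf``; downstream rules cap
        the value where a cap applies (e.g. informal caregiving).  Fatal
        cases return 0 (lost production is valued as a lifetime stream, not
        as lost days).
        """
        if self.fatal:
            return 0.0
        if self.lost_days_high is None:
            return math.inf
        return 0.5 * (self.lost_days_low + self.lost_days_high)

    @property
    def severity_class(self) -> str:
        """One of ``fatal``, ``permanent``, ``minor``, ``temporary``.

        ``minor`` covers bands with at most three days lost (nominal-cost
        healthcare rule, no quality-of-life loss); ``temporary`` covers the
        remaining non-permanent bands.
        """
        if self.fatal:
            return "fatal"
        if self.permanent:
            return "permanent"
        if self.lost_days_high is not None and self.lost_days_high <= 3:
            return "minor"
        return "temporary"

    @property
    def returns_to_work(self) -> bool:
        """Whether the case eventually resumes work (presenteeism window)."""
        return not self.fatal and self.lost_days_high is not None

    @property
    def qaly_class(self) -> str | None:
        """Severity class keying the quality-of-life multiplier table."""
        if self.fatal:
            return "fatal"
        if self.permanent:
            return "permanent"
        if self.severity_class == "minor":
            return None
        return (
            "temporary_minor" if self.expected_lost_days <= 30 else "temporary_serious"
        )


def _build(kind: str, defs) -> dict[str, SeverityBand]:
    return {
        band_id: SeverityBand(kind, band_id, lo, hi, permanent=perm)
        for band_id, lo, hi, perm in defs
    }


# (band_id, lost_days_low, lost_days_high, permanent).  "no_lost_days" is an
# auxiliary injury band (nominal healthcare cost only) used by the scenario
# that adds injuries without any workday lost; it is not part of the default
# incidence structure.
_INJURY_DEFS = [
    ("no_lost_days", 0.0, 0.0, False),
    ("0-3", 0.0, 3.0, False),
    ("4-14", 4.0, 14.0, False),
    ("15-90", 15.0, 90.0, False),
    ("91-180", 91.0, 180.0, False),
    ("181-365", 181.0, 365.0, True),
    ("never_return", 183.0, None, True),
]

_DISEASE_DEFS = [
    ("lt3", 0.0, 3.0, False),
    ("4-30", 4.0, 30.0, False),
    ("31-90", 31.0, 90.0, False),
    ("gt90", 91.0, 365.0, False),
    ("never_return", 183.0, None, True),
]

INJURY_BANDS: dict[str, SeverityBand] = _build("injury", _INJURY_DEFS)
INJURY_BANDS["fatal"] = SeverityBand("injury", "fatal", 0.0, 0.0, fatal=True)

DISEASE_BANDS: dict[str, SeverityBand] = _build("disease", _DISEASE_DEFS)
DISEASE_BANDS["fatal"] = SeverityBand("disease", "fatal", 0.0, 0.0, fatal=True)

BANDS: dict[str, dict[str, SeverityBand]] = {
    "injury": INJURY_BANDS,
    "disease": DISEASE_BANDS,
}

#: Default sampling/allocation order of the non-fatal bands, by kind.
NONFATAL_BAND_IDS: dict[str, list[str]] = {
    "injury": ["0-3", "4-14", "15-90", "91-180", "181-365", "never_return"],
    "disease": ["lt3", "4-30", "31-90", "gt90", "never_return"],
}


def get_band(kind: str, band_id: str) -> SeverityBand:
    """Look up a severity band, raising ``KeyError`` with context if unknown."""
    try:
        return BANDS[kind][band_id]
    except KeyError:
        raise KeyError(f"unknown severity band {band_id!r} for kind {kind!r}") from None
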