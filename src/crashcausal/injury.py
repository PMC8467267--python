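"""Injury severity coding and crash-geometry conventions.

Two small pieces of domain vocabulary live here:

* NASS-style 7-digit injury codes, whose final digit is the Abbreviated
  Injury Scale (AIS) severity: 1 minor, 2 moderate, 3 serious, 4 severe,
  5 critical, 6 maximum, 7 unknown severity.  The leading six digits
  locate the injury anatomically; this package carries them opaquely.
* Principal direction of force (PDOF), expressed either as degrees of a
  circle (0 deg = 12 o'clock = frontal, increasing clockwise) or as a
  clock-face position.  Cohort definitions are stated as clock arcs,
  e.g. "9 to 11 o'clock" for a left-frontal impact window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DomainError, InvalidSeverityError, MalformedCodeError

__all__ = [
    "InjuryRecord",
    "Pdof",
    "parse_injury_code",
    "max_ais",
    "clock_to_degrees",
    "degrees_to_clock",
    "pdof_in_window",
    "AIS_UNKNOWN",
]

#: AIS code meaning "injured, severity unknown"; never counts as a magnitude.
AIS_UNKNOWN = 7

_AIS_LABELS = {
    1: "minor",
    2: "moderate",
    3: "serious",
    4: "severe",
    5: "critical",
    6: "maximum",
    7: "unknown severity",
}


@dataclass(frozen=True)
class InjuryRecord:
    """One coded injury: opaque 6-digit locator plus AIS severity digit."""

    raw_code: str
    body_region_part: str
    ais_severity: int

    @property
    def severity_unknown(self) -> bool:
        return self.ais_severity == AIS_UNKNOWN

    @property
    def severity_label(self) -> str:
        return _AIS_LABELS[self.ais_severity]

    def serialize(self) -> str:
        """Re-emit the original 7-digit code byte-for-byte."""
        return self.body_region_part + str(self.ais_severity)


def parse_injury_code(code: str) -> InjuryRecord:
    """Parse a 7-digit injury code into its opaque locator and AIS digit.

    Raises
    ------
    MalformedCodeError
        If ``code`` is not exactly 7 digit characters.
    InvalidSeverityError
        If the final digit is 0, 8 or 9 (not a defined AIS level).
    """
    if not isinstance(code, str):
        raise MalformedCodeError(f"injury code must be a string, got {type(code).__name__}")
    if len(code) != 7 or not code.isdigit():
        raise MalformedCodeError(
            f"injury code must be exactly 7 digit characters, got {code!r}"
        )
    severity = int(code[-1])
    if severity not in _AIS_LABELS:
        raise InvalidSeverityError(
            f"final digit of {code!r} is {severity}; AIS severity must be 1-7"
        )
    return InjuryRecord(raw_code=code, body_region_part=code[:6], ais_severity=severity)


def max_ais(injuries: Iterable[InjuryRecord]) -> int:
    """Maximum AIS severity over coded injuries, ignoring unknown (7) codes.

    Returns 0 for an empty list or when every code has unknown severity
    (unknown is not a magnitude and never counts toward the maximum).
    """
    best = 0
    for inj in injuries:
        if inj.ais_severity != AIS_UNKNOWN and inj.ais_severity > best:
            best = inj.ais_severity
    return best


@dataclass(frozen=True)
class Pdof:
    """Principal direction of force in degrees [0, 360), clockwise from frontal."""

    degrees: float

    def __post_init__(self):
        if not (0.0 <= self.degrees < 360.0):
            raise DomainError(f"PDOF degrees must lie in [0, 360), got {self.degrees}")

    def to_clock(self) -> tuple[int, int]:
        """Nearest clock position (hours 1-12, minutes 0-59)."""
        total_minutes = round(self.degrees / 0.5)
        hours, minutes = divmod(total_minutes, 60)
        hours = hours % 12
        if hours == 0:
            hours = 12
        return hours, minutes


def clock_to_degrees(hours: int, minutes: int = 0) -> Pdof:
    """Convert a clock-face direction to PDOF degrees.

    12 o'clock is 0 deg (frontal); each hour is 30 deg, each minute 0.5 deg,
    increasing clockwise.  ``10:30`` therefore maps to 315 deg.
    """
    if not (1 <= hours <= 12):
        raise DomainError(f"clock hours must be in 1..12, got {hours}")
    if not (0 <= minutes <= 59):
        raise DomainError(f"clock minutes must be in 0..59, got {minutes}")
    return Pdof(degrees=(hours % 12) * 30.0 + minutes * 0.5)


def degrees_to_clock(degrees: float) -> tuple[int, int]:
    """Inverse of :func:`clock_to_degrees`, to the nearest half degree."""
    return Pdof(degrees=degrees).to_clock()


def _as_degrees(position) -> float:
    if isinstance(position, Pdof):
        return position.degrees
    if isinstance(position, (int, float)):
        return Pdof(float(position)).degrees
    if isinstance(position, Sequence) and len(position) == 2:
        return clock_to_degrees(int(position[0]), int(position[1])).degrees
    raise DomainError(f"cannot interpret {position!r} as a PDOF position")


def pdof_in_window(p, start_clock, end_clock) -> bool:
    """True iff ``p`` lies on the closed clockwise arc from start to end.

    Positions may be :class:`Pdof`, plain degrees, or ``(hours, minutes)``
    clock tuples.  The arc is traversed clockwise (increasing degrees) from
    start to end, so an arc like 11 o'clock to 1 o'clock wraps through 0 deg.
    Both endpoints are included.
    """
    deg = _as_degrees(p)
    start = _as_degrees(start_clock)
    end = _as_degrees(end_clock)
    if start <= end:
        return start <= deg <= end
    return deg >= start or deg <= end
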