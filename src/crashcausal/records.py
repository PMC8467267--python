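"""Occupant-level crash records, survey design labels, and the interchange format.

The working container for analysis is a :class:`pandas.DataFrame` in the
interchange schema below (one row per occupant-in-crash).  A validated
row-level view, :class:`CrashOccupantRecord`, is available through
:func:`frame_to_records` / :func:`records_to_frame` for callers who want
typed objects; the reader and writer round-trip both forms losslessly.

Interchange columns (CSV/TSV, header required, booleans as 0/1)::

    record_id, year, delta_v_mph, pdof_deg, belt_used, airbag_deployed,
    rollover, ejected, role, body_type, model_year, died_30day,
    injury_codes, weight, stratum, psu

``injury_codes`` is a semicolon-delimited list of 7-digit codes, possibly
empty.  Empty cells, ``NA`` and ``unknown`` (case-insensitive) denote
missing/unknown values; unknown belt or airbag status is retained as the
explicit category ``"unknown"`` because cohort definitions test knownness.

Records carry national inflation weights together with stratum and primary
sampling unit (PSU) labels, mirroring the design of stratified multistage
crash samples such as NASS-CDS, whose weighted totals estimate all
police-reported tow-away crashes nationally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DomainError, RejectRateError, SchemaError
from .injury import InjuryRecord, Pdof, parse_injury_code

__all__ = [
    "COLUMNS",
    "CrashOccupantRecord",
    "SurveyDesign",
    "CaseSpec",
    "RejectReport",
    "read_records",
    "write_records",
    "records_to_frame",
    "frame_to_records",
    "km_h",
    "mph",
    "KMH_PER_MPH",
]

COLUMNS = [
    "record_id",
    "year",
    "delta_v_mph",
    "pdof_deg",
    "belt_used",
    "airbag_deployed",
    "rollover",
    "ejected",
    "role",
    "body_type",
    "model_year",
    "died_30day",
    "injury_codes",
    "weight",
    "stratum",
    "psu",
]

BELT_LEVELS = ("used", "not_used", "unknown")
AIRBAG_LEVELS = ("deployed", "not_deployed", "unknown")
ROLE_LEVELS = ("driver", "front_passenger", "rear_passenger")

#: Exact statute-mile to kilometre factor.
KMH_PER_MPH = 1.609344

_MISSING_TOKENS = {"", "na", "nan", "unknown", "none", "."}


def km_h(mph_value: float) -> float:
    """Convert miles per hour to kilometres per hour (factor 1.609344)."""
    return mph_value * KMH_PER_MPH


def mph(km_h_value: float) -> float:
    """Convert kilometres per hour to miles per hour."""
    return km_h_value / KMH_PER_MPH


@dataclass(frozen=True)
class CrashOccupantRecord:
    """One occupant in one crash: exposure, covariates, outcome and design labels."""

    record_id: str
    year: int
    delta_v_mph: Optional[float]
    pdof: Optional[Pdof]
    belt_used: str
    airbag_deployed: str
    rollover: bool
    ejected: bool
    role: str
    body_type: str
    model_year: int
    died_30day: bool
    injuries: tuple[InjuryRecord, ...]
    weight: float
    stratum: str
    psu: str

    def __post_init__(self):
        if self.weight <= 0 or not math.isfinite(self.weight):
            raise DomainError(f"weight must be a positive finite real, got {self.weight}")
        if self.delta_v_mph is not None and self.delta_v_mph < 0:
            raise DomainError(f"delta V must be non-negative, got {self.delta_v_mph}")
        if self.belt_used not in BELT_LEVELS:
            raise DomainError(f"belt_used must be one of {BELT_LEVELS}, got {self.belt_used!r}")
        if self.airbag_deployed not in AIRBAG_LEVELS:
            raise DomainError(
                f"airbag_deployed must be one of {AIRBAG_LEVELS}, got {self.airbag_deployed!r}"
            )
        if self.role not in ROLE_LEVELS:
            raise DomainError(f"role must be one of {ROLE_LEVELS}, got {self.role!r}")


@dataclass(frozen=True)
class SurveyDesign:
    """Stratum/PSU structure of a complex sample, with-replacement approximation.

    No finite-population correction is applied: PSUs are treated as drawn
    with replacement within strata, the standard first-stage approximation
    for Taylor-linearized variance estimation.  Strata containing a single
    PSU cannot contribute a between-PSU variance term and are flagged.
    """

    strata: tuple[str, ...]
    psus_by_stratum: dict[str, tuple[str, ...]]

    def __post_init__(self):
        for stratum in self.strata:
            if len(self.psus_by_stratum.get(stratum, ())) < 1:
                raise DomainError(f"stratum {stratum!r} contains no PSUs")
        seen: dict[str, str] = {}
        for stratum, psus in self.psus_by_stratum.items():
            for psu in psus:
                if psu in seen:
                    raise DomainError(
                        f"PSU {psu!r} appears in strata {seen[psu]!r} and {stratum!r}"
                    )
                seen[psu] = stratum

    @property
    def single_psu_strata(self) -> tuple[str, ...]:
        """Strata with exactly one PSU (variance-degenerate)."""
        return tuple(s for s in self.strata if len(self.psus_by_stratum[s]) == 1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyDesign":
        """Recover the design labels present in a record table."""
        pairs = df[["stratum", "psu"]].astype(str).drop_duplicates()
        mapping: dict[str, list[str]] = {}
        for stratum, psu in pairs.itertuples(index=False):
            mapping.setdefault(stratum, []).append(psu)
        strata = tuple(sorted(mapping))
        return cls(strata=strata, psus_by_stratum={s: tuple(sorted(mapping[s])) for s in strata})


@dataclass(frozen=True)
class CaseSpec:
    """The litigated occupant's crash profile plus the cohort used to match it.

    ``outcome`` is either ``"death_30day"`` or ``("max_ais_ge_k", k)`` for an
    injury-at-threshold outcome.  ``cohort`` is a
    :class:`crashcausal.cohort.CohortSpec` describing the matched analysis
    population.  ``peak_acceleration_g`` is informational only (it supports
    the biomechanical narrative, not the risk model).
    """

    role: str
    belt_used_actual: str
    airbag_deployed: str
    delta_v_mph: float
    pdof: Pdof
    body_type: str
    model_year: int
    outcome: object
    cohort: object
    peak_acceleration_g: Optional[float] = None

    def __post_init__(self):
        if self.delta_v_mph <= 0:
            raise DomainError(f"case delta V must be positive, got {self.delta_v_mph}")
        if self.belt_used_actual not in ("used", "not_used"):
            raise DomainError(
                f"belt_used_actual must be 'used' or 'not_used', got {self.belt_used_actual!r}"
            )
        if self.airbag_deployed not in AIRBAG_LEVELS:
            raise DomainError(
                f"airbag_deployed must be one of {AIRBAG_LEVELS}, got {self.airbag_deployed!r}"
            )

    def profile(self, belt_used: str) -> dict:
        """Covariate profile at the case crash under a hypothetical belt state."""
        return {
            "delta_v_mph": self.delta_v_mph,
            "belt_used": belt_used,
            "airbag_deployed": self.airbag_deployed,
            "body_type": self.body_type,
            "model_year": self.model_year,
        }


@dataclass
class RejectReport:
    """Rows that failed to parse, with reasons; never silently dropped."""

    n_input_rows: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    @property
    def reject_fraction(self) -> float:
        return self.n_rejected / self.n_input_rows if self.n_input_rows else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input_rows": self.n_input_rows,
            "n_rejected": self.n_rejected,
            "rejected": [{"row": r, "reason": m} for r, m in self.rejected],
        }


def _is_missing(token: str) -> bool:
    return token.strip().lower() in _MISSING_TOKENS


def _parse_float(token: str, column: str, allow_missing: bool) -> Optional[float]:
    if _is_missing(token):
        if allow_missing:
            return None
        raise ValueError(f"missing value in mandatory numeric column {column!r}")
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"unparsable numeric {token!r} in column {column!r}") from None


def _parse_int(token: str, column: str) -> int:
    try:
        return int(float(token))
    except ValueError:
        raise ValueError(f"unparsable integer {token!r} in column {column!r}") from None


def _parse_bool(token: str, column: str) -> bool:
    t = token.strip().lower()
    if t in ("1", "true", "yes"):
        return True
    if t in ("0", "false", "no"):
        return False
    raise ValueError(f"unparsable boolean {token!r} in column {column!r}")


def _parse_trivalent(token: str, levels: tuple[str, ...], column: str) -> str:
    t = token.strip().lower()
    if _is_missing(t):
        return "unknown"
    if t in levels:
        return t
    raise ValueError(f"unrecognised value {token!r} in column {column!r}")


def _parse_row(row: dict[str, str]) -> CrashOccupantRecord:
    delta_v = _parse_float(row["delta_v_mph"], "delta_v_mph", allow_missing=True)
    if delta_v is not None and delta_v < 0:
        raise ValueError(f"negative delta V {delta_v}")
    pdof_deg = _parse_float(row["pdof_deg"], "pdof_deg", allow_missing=True)
    pdof = Pdof(pdof_deg) if pdof_deg is not None else None
    codes_cell = row["injury_codes"].strip()
    injuries = tuple(
        parse_injury_code(c.strip()) for c in codes_cell.split(";") if c.strip()
    )
    weight = _parse_float(row["weight"], "weight", allow_missing=False)
    role_token = row["role"].strip().lower()
    if role_token not in ROLE_LEVELS:
        raise ValueError(f"unrecognised role {row['role']!r}")
    return CrashOccupantRecord(
        record_id=row["record_id"].strip(),
        year=_parse_int(row["year"], "year"),
        delta_v_mph=delta_v,
        pdof=pdof,
        belt_used=_parse_trivalent(row["belt_used"], BELT_LEVELS, "belt_used"),
        airbag_deployed=_parse_trivalent(row["airbag_deployed"], AIRBAG_LEVELS, "airbag_deployed"),
        rollover=_parse_bool(row["rollover"], "rollover"),
        ejected=_parse_bool(row["ejected"], "ejected"),
        role=role_token,
        body_type=row["body_type"].strip().lower(),
        model_year=_parse_int(row["model_year"], "model_year"),
        died_30day=_parse_bool(row["died_30day"], "died_30day"),
        injuries=injuries,
        weight=weight,
        stratum=row["stratum"].strip(),
        psu=row["psu"].strip(),
    )


def read_records(
    path,
    sep: Optional[str] = None,
    column_map: Optional[dict[str, str]] = None,
    speed_unit: str = "mph",
    max_reject_fraction: float = 0.10,
) -> tuple[pd.DataFrame, RejectReport]:
    """Read an interchange CSV/TSV into the analysis table.

    Parameters
    ----------
    path
        File with a header row in the interchange schema.
    sep
        Field delimiter; inferred from the extension when omitted
        (``.tsv`` -> tab, otherwise comma).
    column_map
        Optional mapping ``{source column -> interchange column}`` for
        renamed inputs.
    speed_unit
        ``"mph"`` (default) or ``"kmh"``; km/h inputs are converted to the
        canonical internal mph.
    max_reject_fraction
        Refuse to proceed when more than this fraction of rows fail to
        parse; malformed rows below the threshold are collected in the
        returned :class:`RejectReport`, never silently dropped.

    Returns
    -------
    (DataFrame, RejectReport)
        The table of successfully parsed rows (interchange schema) and the
        ledger of rejected rows with reasons.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=column_map)
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"input file lacks mandatory column(s): {', '.join(missing_cols)}")
    if speed_unit not in ("mph", "kmh"):
        raise DomainError(f"speed_unit must be 'mph' or 'kmh', got {speed_unit!r}")

    report = RejectReport(n_input_rows=len(raw))
    records: list[CrashOccupantRecord] = []
    for i, row in enumerate(raw[COLUMNS].to_dict(orient="records")):
        try:
            rec = _parse_row(row)
        except (ValueError, DomainError) as exc:
            report.rejected.append((i, str(exc)))
            continue
        if speed_unit == "kmh" and rec.delta_v_mph is not None:
            rec = replace(rec, delta_v_mph=mph(rec.delta_v_mph))
        records.append(rec)
    if report.reject_fraction > max_reject_fraction:
        raise RejectRateError(
            f"{report.n_rejected} of {report.n_input_rows} rows rejected "
            f"({report.reject_fraction:.1%} > {max_reject_fraction:.0%} limit); "
            "refusing to analyse a substantially corrupted input"
        )
    return records_to_frame(records), report


def records_to_frame(records: Iterable[CrashOccupantRecord]) -> pd.DataFrame:
    """Assemble typed records into the interchange DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "year": r.year,
                "delta_v_mph": np.nan if r.delta_v_mph is None else float(r.delta_v_mph),
                "pdof_deg": np.nan if r.pdof is None else float(r.pdof.degrees),
                "belt_used": r.belt_used,
                "airbag_deployed": r.airbag_deployed,
                "rollover": bool(r.rollover),
                "ejected": bool(r.ejected),
                "role": r.role,
                "body_type": r.body_type,
                "model_year": r.model_year,
                "died_30day": bool(r.died_30day),
                "injury_codes": ";".join(inj.serialize() for inj in r.injuries),
                "weight": float(r.weight),
                "stratum": r.stratum,
                "psu": r.psu,
            }
        )
    df = pd.DataFrame(rows, columns=COLUMNS)
    if df.empty:
        df = df.astype(
            {
                "delta_v_mph": float,
                "pdof_deg": float,
                "rollover": bool,
                "ejected": bool,
                "died_30day": bool,
                "weight": float,
            },
            errors="ignore",
        )
    return df


def frame_to_records(df: pd.DataFrame) -> list[CrashOccupantRecord]:
    """Materialise typed records from the interchange DataFrame."""
    out = []
    for row in df.itertuples(index=False):
        dv = None if pd.isna(row.delta_v_mph) else float(row.delta_v_mph)
        pdof = None if pd.isna(row.pdof_deg) else Pdof(float(row.pdof_deg))
        codes = str(row.injury_codes) if not pd.isna(row.injury_codes) else ""
        injuries = tuple(parse_injury_code(c) for c in codes.split(";") if c)
        out.append(
            CrashOccupantRecord(
                record_id=str(row.record_id),
                year=int(row.year),
                delta_v_mph=dv,
                pdof=pdof,
                belt_used=str(row.belt_used),
                airbag_deployed=str(row.airbag_deployed),
                rollover=bool(row.rollover),
                ejected=bool(row.ejected),
                role=str(row.role),
                body_type=str(row.body_type),
                model_year=int(row.model_year),
                died_30day=bool(row.died_30day),
                injuries=injuries,
                weight=float(row.weight),
                stratum=str(row.stratum),
                psu=str(row.psu),
            )
        )
    return out


def write_records(records_or_frame, path, sep: Optional[str] = None) -> None:
    """Write records (list or interchange DataFrame) to CSV/TSV.

    Booleans are written as 0/1 and missing numerics as empty cells so that
    :func:`read_records` round-trips the table field-for-field.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if isinstance(records_or_frame, pd.DataFrame):
        df = records_or_frame.copy()
    else:
        df = records_to_frame(records_or_frame)
    for col in ("rollover", "ejected", "died_30day"):
        df[col] = df[col].astype(int)
    df = df[COLUMNS]
    df.to_csv(path, sep=sep, index=False, na_rep="")
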