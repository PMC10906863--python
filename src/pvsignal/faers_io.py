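"""Readers and writers for FAERS-style quarterly ASCII tables.

The public FAERS quarterly extracts ship as dollar-delimited text files with
a header row and no quoting: one file per table kind (DEMO, DRUG, REAC,
OUTC, THER) per quarter.  This module parses that dialect into typed
records, validating each row against the FAERS code sets and rejecting —
never silently dropping — rows that cannot be validated.  Dates in FAERS
are stored as 4, 6 or 8 digit strings (year, year+month, full date), so the
central date type is a :class:`PartialDate` that records only the
components actually present.

Parsing is header-driven: column order in the file is irrelevant, and
columns beyond the required set are optional.  Files are read as UTF-8 with
a latin-1 fallback per file, so the result is deterministic regardless of
platform locale.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._utils import fmt_number

log = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER")

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
AGE_UNITS = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})

#: FAERS occupation codes for the reporter, collapsed to the categories a
#: demographic table distinguishes.
_REPORTER_MAP = {"CN": "consumer", "MD": "physician", "PH": "pharmacist"}
_REPORTER_WRITE = {
    "consumer": "CN",
    "physician": "MD",
    "pharmacist": "PH",
    "other": "OT",
    "missing": "",
}

_REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid", "fda_dt"),
    "DRUG": ("primaryid", "drug_seq", "drugname", "role_cod"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "THER": ("primaryid", "dsg_drug_seq"),
}


class FaersFormatError(Exception):
    """Fatal structural problem in an input file (missing column, unreadable)."""


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartialDate:
    """A date known to year, year+month, or full-day precision.

    ``day`` may only be present when ``month`` is; out-of-range components
    are rejected at construction rather than clamped.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not 1000 <= self.year <= 9999:
            raise ValueError(f"year out of range: {self.year}")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValueError("day present without month")
            if not 1 <= self.day <= 31:
                raise ValueError(f"day out of range: {self.day}")

    @property
    def is_full(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> date:
        """Calendar date; only valid for full dates."""
        if not self.is_full:
            raise ValueError("not a full date")
        return date(self.year, self.month, self.day)  # type: ignore[arg-type]

    def sort_key(self) -> tuple[int, int, int]:
        """Orderable key; absent components sort before any present value."""
        return (self.year, self.month or 0, self.day or 0)

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_partial_date(raw: str) -> PartialDate | None:
    """Parse a FAERS date string (``YYYY``, ``YYYYMM`` or ``YYYYMMDD``).

    Total: any malformed or out-of-range input yields ``None`` (missing),
    never an exception.  Full dates are additionally checked against the
    calendar, so e.g. February 30th is missing, not a date.
    """
    raw = raw.strip()
    if not raw:
        return None
    if not raw.isdigit():
        return None
    try:
        if len(raw) == 4:
            return PartialDate(int(raw))
        if len(raw) == 6:
            return PartialDate(int(raw[:4]), int(raw[4:6]))
        if len(raw) == 8:
            pd = PartialDate(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
            pd.to_date()  # calendar validity
            return pd
    except ValueError:
        return None
    return None


def format_partial_date(d: PartialDate | None) -> str:
    return "" if d is None else str(d)


# ---------------------------------------------------------------------------
# Typed records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: PartialDate
    event_dt: PartialDate | None = None
    sex: str = "UNK"  # F, M or UNK
    age_value: float | None = None
    age_unit: str | None = None  # DEC, YR, MON, WK, DY, HR
    reporter_type: str = "missing"  # consumer/physician/pharmacist/other/missing
    country: str | None = None


@dataclass(frozen=True)
class DrugRecord:
    primaryid: str
    drug_seq: int
    drugname: str
    prod_ai: str | None
    role: str  # PS, SS, C, I


@dataclass(frozen=True)
class ReacRecord:
    primaryid: str
    pt: str


@dataclass(frozen=True)
class OutcRecord:
    primaryid: str
    outcome: str


@dataclass(frozen=True)
class TherRecord:
    primaryid: str
    drug_seq: int
    start_dt: PartialDate | None


RECORD_TYPES = {
    "DEMO": DemoRecord,
    "DRUG": DrugRecord,
    "REAC": ReacRecord,
    "OUTC": OutcRecord,
    "THER": TherRecord,
}


@dataclass
class ParseReport:
    """Per-file accounting: every rejected row is listed with its reason."""

    path: str
    table_kind: str
    rows_read: int = 0
    rows_ok: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejects)


# ---------------------------------------------------------------------------
# Row parsers
# ---------------------------------------------------------------------------


def _parse_demo(row: Mapping[str, str], country_column: str, warns: list[str]):
    primaryid = row.get("primaryid", "").strip()
    caseid = row.get("caseid", "").strip()
    if not primaryid:
        return None, "missing primaryid"
    if not caseid:
        return None, "missing caseid"
    fda_dt = parse_partial_date(row.get("fda_dt", ""))
    if fda_dt is None:
        return None, "invalid or missing fda_dt"

    raw_event = row.get("event_dt", "")
    event_dt = parse_partial_date(raw_event)
    if event_dt is None and raw_event.strip():
        warns.append(f"unparseable event_dt {raw_event!r} for {primaryid}")

    sex = row.get("sex", "").strip().upper()
    if sex not in ("F", "M"):
        if sex and sex not in ("UNK", "NS", "U"):
            warns.append(f"unknown sex code {sex!r} for {primaryid}")
        sex = "UNK"

    age_value: float | None = None
    raw_age = row.get("age", "").strip()
    if raw_age:
        try:
            age_value = float(raw_age)
        except ValueError:
            warns.append(f"unparseable age {raw_age!r} for {primaryid}")
    age_unit = row.get("age_cod", "").strip().upper() or None
    if age_unit is not None and age_unit not in AGE_UNITS:
        warns.append(f"unknown age unit {age_unit!r} for {primaryid}")
        age_unit = None

    occp = row.get("occp_cod", "").strip().upper()
    reporter = _REPORTER_MAP.get(occp, "other" if occp else "missing")

    if country_column == "auto":
        country = row.get("occr_country", "").strip() or row.get(
            "reporter_country", ""
        ).strip() or None
    else:
        country = row.get(country_column, "").strip() or None

    return (
        DemoRecord(
            primaryid=primaryid,
            caseid=caseid,
            fda_dt=fda_dt,
            event_dt=event_dt,
            sex=sex,
            age_value=age_value,
            age_unit=age_unit,
            reporter_type=reporter,
            country=country,
        ),
        None,
    )


def _parse_drug(row: Mapping[str, str], warns: list[str]):
    primaryid = row.get("primaryid", "").strip()
    if not primaryid:
        return None, "missing primaryid"
    try:
        drug_seq = int(row.get("drug_seq", "").strip())
    except ValueError:
        return None, "invalid drug_seq"
    drugname = row.get("drugname", "").strip()
    if not drugname:
        return None, "missing drugname"
    role = row.get("role_cod", "").strip().upper()
    if role not in ROLE_CODES:
        return None, "invalid role"
    prod_ai = row.get("prod_ai", "").strip() or None
    return DrugRecord(primaryid, drug_seq, drugname, prod_ai, role), None


def _parse_reac(row: Mapping[str, str], warns: list[str]):
    primaryid = row.get("primaryid", "").strip()
    if not primaryid:
        return None, "missing primaryid"
    pt = " ".join(row.get("pt", "").split())
    if not pt:
        return None, "missing pt"
    return ReacRecord(primaryid, pt), None


def _parse_outc(row: Mapping[str, str], warns: list[str]):
    primaryid = row.get("primaryid", "").strip()
    if not primaryid:
        return None, "missing primaryid"
    outcome = row.get("outc_cod", "").strip().upper()
    if outcome not in OUTCOME_CODES:
        return None, "invalid outcome code"
    return OutcRecord(primaryid, outcome), None


def _parse_ther(row: Mapping[str, str], warns: list[str]):
    primaryid = row.get("primaryid", "").strip()
    if not primaryid:
        return None, "missing primaryid"
    try:
        drug_seq = int(row.get("dsg_drug_seq", "").strip())
    except ValueError:
        return None, "invalid dsg_drug_seq"
    raw_start = row.get("start_dt", "")
    start_dt = parse_partial_date(raw_start)
    if start_dt is None and raw_start.strip():
        warns.append(f"unparseable start_dt {raw_start!r} for {primaryid}")
    return TherRecord(primaryid, drug_seq, start_dt), None


# ---------------------------------------------------------------------------
# File-level read / write
# ---------------------------------------------------------------------------


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_faers_table(
    path: str | Path,
    table_kind: str,
    country_column: str = "auto",
) -> tuple[list, ParseReport]:
    """Read one dollar-delimited table into typed records.

    Returns the valid records plus a :class:`ParseReport` in which every
    rejected row appears with its line number and reason.  A row with more
    fields than the header (an embedded delimiter in free text) is rejected
    rather than repaired; a row with fewer fields is padded with empties,
    matching files whose trailing empty fields were trimmed.

    Raises :class:`FaersFormatError` if the file is unreadable or the
    header lacks a required column for ``table_kind``.
    """
    if table_kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind: {table_kind}")
    path = Path(path)
    try:
        text = _read_text(path)
    except OSError as exc:
        raise FaersFormatError(f"cannot read {path}: {exc}") from exc

    lines = text.splitlines()
    if not lines:
        raise FaersFormatError(f"{path}: empty file, no header")
    header = [h.strip().lower() for h in lines[0].split("$")]
    for col in _REQUIRED_COLUMNS[table_kind]:
        if col not in header:
            raise FaersFormatError(f"{path}: missing required column {col!r}")

    report = ParseReport(path=str(path), table_kind=table_kind)
    records: list = []
    ncol = len(header)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        report.rows_read += 1
        fields = line.split("$")
        if len(fields) > ncol:
            report.rejects.append((lineno, "field count exceeds header"))
            continue
        fields += [""] * (ncol - len(fields))
        row = dict(zip(header, fields))
        if table_kind == "DEMO":
            rec, reason = _parse_demo(row, country_column, report.warnings)
        elif table_kind == "DRUG":
            rec, reason = _parse_drug(row, report.warnings)
        elif table_kind == "REAC":
            rec, reason = _parse_reac(row, report.warnings)
        elif table_kind == "OUTC":
            rec, reason = _parse_outc(row, report.warnings)
        else:
            rec, reason = _parse_ther(row, report.warnings)
        if rec is None:
            report.rejects.append((lineno, reason or "malformed row"))
        else:
            records.append(rec)
            report.rows_ok += 1
    return records, report


_WRITE_COLUMNS = {
    "DEMO": (
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "sex",
        "age",
        "age_cod",
        "occp_cod",
        "occr_country",
    ),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
}


def _record_row(rec, table_kind: str) -> list[str]:
    if table_kind == "DEMO":
        return [
            rec.primaryid,
            rec.caseid,
            format_partial_date(rec.fda_dt),
            format_partial_date(rec.event_dt),
            "" if rec.sex == "UNK" else rec.sex,
            fmt_number(rec.age_value),
            rec.age_unit or "",
            _REPORTER_WRITE.get(rec.reporter_type, "OT"),
            rec.country or "",
        ]
    if table_kind == "DRUG":
        return [
            rec.primaryid,
            str(rec.drug_seq),
            rec.role,
            rec.drugname,
            rec.prod_ai or "",
        ]
    if table_kind == "REAC":
        return [rec.primaryid, rec.pt]
    if table_kind == "OUTC":
        return [rec.primaryid, rec.outcome]
    return [rec.primaryid, str(rec.drug_seq), format_partial_date(rec.start_dt)]


def write_faers_table(records: Sequence, path: str | Path, table_kind: str) -> None:
    """Write records back in the dollar-delimited dialect (round-trip safe)."""
    if table_kind not in _WRITE_COLUMNS:
        raise ValueError(f"unknown table kind: {table_kind}")
    path = Path(path)
    lines = ["$".join(_WRITE_COLUMNS[table_kind])]
    for rec in records:
        row = _record_row(rec, table_kind)
        for value in row:
            if "$" in value:
                raise ValueError(f"field contains delimiter: {value!r}")
        lines.append("$".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Multi-quarter store
# ---------------------------------------------------------------------------


@dataclass
class RecordStore:
    """All records of a multi-quarter load, with per-quarter provenance."""

    demo: list[DemoRecord] = field(default_factory=list)
    drug: list[DrugRecord] = field(default_factory=list)
    reac: list[ReacRecord] = field(default_factory=list)
    outc: list[OutcRecord] = field(default_factory=list)
    ther: list[TherRecord] = field(default_factory=list)
    reports: list[ParseReport] = field(default_factory=list)
    #: quarter label -> {table kind -> source path}
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)
    #: quarter label -> {table kind -> accepted row count}
    quarter_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def table(self, kind: str) -> list:
        return getattr(self, kind.lower())

    def counts(self) -> dict[str, int]:
        return {k: len(self.table(k)) for k in TABLE_KINDS}


_QUARTER_FILE_RE = re.compile(
    r"^(DEMO|DRUG|REAC|OUTC|THER)(\d{4}Q[1-4])\.(?:txt|TXT)$"
)


def discover_quarters(input_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Map quarter labels to table files named like ``DEMO2021Q1.txt``."""
    quarters: dict[str, dict[str, Path]] = {}
    for p in sorted(Path(input_dir).iterdir()):
        m = _QUARTER_FILE_RE.match(p.name)
        if m:
            kind, quarter = m.group(1), m.group(2)
            quarters.setdefault(quarter, {})[kind] = p
    return quarters


def load_quarters(
    quarters: Mapping[str, Mapping[str, str | Path]],
    country_column: str = "auto",
) -> RecordStore:
    """Load and concatenate several quarters of tables.

    Every quarter must contribute at least DEMO, DRUG and REAC (case
    deduplication is impossible without DEMO); OUTC and THER are optional
    per quarter.
    """
    store = RecordStore()
    for quarter in sorted(quarters):
        tables = quarters[quarter]
        for required in ("DEMO", "DRUG", "REAC"):
            if required not in tables:
                raise FaersFormatError(
                    f"quarter {quarter}: missing required table {required}"
                )
        store.provenance[quarter] = {}
        store.quarter_counts[quarter] = {}
        for kind in TABLE_KINDS:
            if kind not in tables:
                continue
            records, report = read_faers_table(
                tables[kind], kind, country_column=country_column
            )
            store.table(kind).extend(records)
            store.reports.append(report)
            store.provenance[quarter][kind] = str(tables[kind])
            store.quarter_counts[quarter][kind] = len(records)
            log.info(
                "%s %s: %d rows ok, %d rejected",
                quarter,
                kind,
                report.rows_ok,
                report.rows_rejected,
            )
    return store
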