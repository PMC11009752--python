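"""Spontaneous adverse-event report data model and I/O.

A :class:`Report` is one *version* of a spontaneous case: demographics, the
drugs mentioned on the report, and the set of adverse-event preferred terms
(PTs) coded on it.  The same case may be resubmitted several times as new
versions; :func:`deduplicate` keeps exactly one version per case.

Two on-disk dialects are supported:

* ``native`` — a flat CSV with one row per (report, drug, event) triple,
  merged into one :class:`Report` per ``report_id`` at load time.
* ``faers_ascii`` — the "$"-delimited DEMO/DRUG/REAC quarterly extract
  layout, keyed by ``primaryid``/``caseid``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterator

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "AgeBand",
    "DrugRole",
    "DrugMention",
    "Report",
    "ReportSet",
    "ReportFormatError",
    "load_reports",
    "write_native",
    "deduplicate",
    "filter_window",
    "bin_age",
    "parse_partial_date",
]


class ReportFormatError(ValueError):
    """Raised when a report file does not conform to its declared dialect."""


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    NS = "NS"


class AgeBand(str, enum.Enum):
    UNDER18 = "under18"
    A18TO64 = "18to64"
    A65TO85 = "65to85"
    OVER85 = "over85"
    NS = "NS"


class DrugRole(str, enum.Enum):
    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"
    INTERACTING = "I"
    UNKNOWN = "NS"


#: Roles treated as "exposed" by default in disproportionality contrasts.
SUSPECT_ROLES = frozenset(
    {DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT, DrugRole.UNKNOWN}
)


@dataclass(frozen=True)
class DrugMention:
    """One drug line on a report: the verbatim name and its reported role."""

    verbatim_name: str
    role: DrugRole = DrugRole.UNKNOWN

    def __post_init__(self) -> None:
        if not self.verbatim_name.strip():
            raise ValueError("verbatim_name must be non-empty")


@dataclass(frozen=True)
class Report:
    """One version of a spontaneous adverse-event case.

    ``report_id`` is unique per version; ``case_id`` is stable across
    versions of the same case.  ``events`` holds upper-cased, trimmed
    preferred terms and is never empty (event-less records are dropped at
    load).
    """

    report_id: str
    case_id: str
    version: int
    receipt_date: date
    sex: Sex
    age_band: AgeBand
    drugs: tuple[DrugMention, ...]
    events: frozenset[str]

    def __post_init__(self) -> None:
        if self.version < 0:
            raise ValueError("version must be >= 0")
        if not self.events:
            raise ValueError("events must be non-empty")
        if not self.drugs:
            raise ValueError("drugs must be non-empty")


@dataclass
class ReportSet:
    """An ordered collection of reports with a provenance label."""

    reports: list[Report] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)


# ---------------------------------------------------------------------------
# parsing helpers

def parse_partial_date(value: str | int) -> date:
    """Parse an ISO-8601 or compact (YYYYMMDD / YYYYMM / YYYY) date.

    Missing month/day components are coerced to the first of the period so
    that window filtering is total over partially dated reports.
    """
    s = str(value).strip().replace("-", "")
    if not s.isdigit() or len(s) not in (4, 6, 8):
        raise ReportFormatError(f"unparseable date: {value!r}")
    year = int(s[:4])
    month = int(s[4:6]) if len(s) >= 6 else 1
    day = int(s[6:8]) if len(s) == 8 else 1
    return date(year, month, day)


def bin_age(age_years: float) -> AgeBand:
    """Bin an age in years into the reporting bands.

    Boundaries: <18, 18–64, 65–85 (85 inclusive), >85.
    """
    if age_years < 18:
        return AgeBand.UNDER18
    if age_years < 65:
        return AgeBand.A18TO64
    if age_years <= 85:
        return AgeBand.A65TO85
    return AgeBand.OVER85


def _parse_sex(value: object) -> Sex:
    s = str(value).strip().upper()
    if s in ("F", "FEMALE"):
        return Sex.F
    if s in ("M", "MALE"):
        return Sex.M
    return Sex.NS


def _parse_role(value: object) -> DrugRole:
    s = str(value).strip().upper()
    try:
        return DrugRole(s)
    except ValueError:
        return DrugRole.UNKNOWN


_BAND_ALIASES = {b.value.lower(): b for b in AgeBand}
_BAND_ALIASES.update({"<18": AgeBand.UNDER18, "18-64": AgeBand.A18TO64,
                      "65-85": AgeBand.A65TO85, ">85": AgeBand.OVER85})


def _parse_age_band(band: object, age: object) -> AgeBand:
    """age_band column wins over the age-in-years column when both present."""
    if band is not None and not pd.isna(band) and str(band).strip():
        return _BAND_ALIASES.get(str(band).strip().lower(), AgeBand.NS)
    if age is not None and not pd.isna(age) and str(age).strip():
        try:
            return bin_age(float(age))
        except ValueError:
            return AgeBand.NS
    return AgeBand.NS


# ---------------------------------------------------------------------------
# native dialect

NATIVE_COLUMNS = [
    "report_id", "case_id", "version", "receipt_date", "sex",
    "age", "age_band", "drug_verbatim", "drug_role", "event_pt",
]
_MANDATORY = [c for c in NATIVE_COLUMNS if c not in ("age", "age_band")]


def load_reports(path: str | Path, format: str = "native") -> ReportSet:
    """Load a report file into a :class:`ReportSet`.

    One :class:`Report` is formed per input report version; records with no
    event term cannot satisfy the report invariant and are dropped with a
    logged warning.  Unparseable sex/age map to NS.
    """
    if format == "native":
        return _load_native(Path(path))
    if format == "faers_ascii":
        return _load_faers_ascii(Path(path))
    raise ValueError(f"unknown format: {format!r}")


def _load_native(path: Path) -> ReportSet:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return ReportSet([], provenance=str(path))
    for col in _MANDATORY:
        if col not in df.columns:
            raise ReportFormatError(f"missing mandatory column: {col}")
    if "age" not in df.columns:
        df["age"] = ""
    if "age_band" not in df.columns:
        df["age_band"] = ""

    reports: list[Report] = []
    dropped = 0
    for report_id, grp in df.groupby("report_id", sort=True):
        first = grp.iloc[0]
        events = frozenset(
            pt.strip().upper() for pt in grp["event_pt"] if pt.strip()
        )
        drugs = tuple(dict.fromkeys(
            DrugMention(v.strip(), _parse_role(r))
            for v, r in zip(grp["drug_verbatim"], grp["drug_role"])
            if v.strip()
        ))
        if not events or not drugs:
            dropped += 1
            logger.warning("dropping report %s: no %s", report_id,
                           "events" if not events else "drugs")
            continue
        reports.append(Report(
            report_id=str(report_id),
            case_id=first["case_id"],
            version=int(first["version"]),
            receipt_date=parse_partial_date(first["receipt_date"]),
            sex=_parse_sex(first["sex"]),
            age_band=_parse_age_band(first["age_band"], first["age"]),
            drugs=drugs,
            events=events,
        ))
    logger.info("loaded %s: %d rows -> %d reports (%d dropped)",
                path, len(df), len(reports), dropped)
    return ReportSet(reports, provenance=str(path))


def write_native(rs: ReportSet, path: str | Path) -> None:
    """Write a :class:`ReportSet` to the native CSV dialect."""
    rows = []
    for rep in rs:
        for drug in rep.drugs:
            for pt in sorted(rep.events):
                rows.append({
                    "report_id": rep.report_id,
                    "case_id": rep.case_id,
                    "version": rep.version,
                    "receipt_date": rep.receipt_date.isoformat(),
                    "sex": rep.sex.value,
                    "age": "",
                    "age_band": rep.age_band.value,
                    "drug_verbatim": drug.verbatim_name,
                    "drug_role": drug.role.value,
                    "event_pt": pt,
                })
    pd.DataFrame(rows, columns=NATIVE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FAERS ASCII dialect ("$"-delimited DEMO/DRUG/REAC triplet)

def _read_dollar(path: Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                     engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("primaryid", "caseid"):
        if col not in df.columns:
            raise ReportFormatError(f"missing mandatory column: {col} ({kind})")
    return df


def _find_file(root: Path, stem: str) -> Path:
    hits = sorted(p for p in root.iterdir()
                  if p.name.lower().startswith(stem)
                  and p.name.lower().endswith(".txt"))
    if not hits:
        raise ReportFormatError(f"no {stem.upper()} file under {root}")
    return hits[0]


def _load_faers_ascii(root: Path) -> ReportSet:
    """Load a DEMO/DRUG/REAC triplet from a directory.

    DEMO supplies demographics and the case version, DRUG the verbatim
    names and role codes, REAC the reaction PTs.  Cases with no REAC row
    are dropped (they cannot satisfy the report invariant).
    """
    demo = _read_dollar(_find_file(root, "demo"), "DEMO")
    drug = _read_dollar(_find_file(root, "drug"), "DRUG")
    reac = _read_dollar(_find_file(root, "reac"), "REAC")
    if "pt" not in reac.columns:
        raise ReportFormatError("missing mandatory column: pt (REAC)")
    if "drugname" not in drug.columns:
        raise ReportFormatError("missing mandatory column: drugname (DRUG)")

    drugs_by_id: dict[str, list[DrugMention]] = {}
    for _, row in drug.iterrows():
        name = row["drugname"].strip()
        if name:
            drugs_by_id.setdefault(row["primaryid"], []).append(
                DrugMention(name, _parse_role(row.get("role_cod", "")))
            )
    events_by_id: dict[str, set[str]] = {}
    for _, row in reac.iterrows():
        pt = row["pt"].strip().upper()
        if pt:
            events_by_id.setdefault(row["primaryid"], set()).add(pt)

    reports: list[Report] = []
    dropped = 0
    for _, row in demo.iterrows():
        pid = row["primaryid"]
        events = frozenset(events_by_id.get(pid, ()))
        drugs = tuple(dict.fromkeys(drugs_by_id.get(pid, ())))
        if not events or not drugs:
            dropped += 1
            logger.warning("dropping case %s: no %s", pid,
                           "events" if not events else "drugs")
            continue
        age_cod = str(row.get("age_cod", "YR")).strip().upper() or "YR"
        age = row.get("age", "")
        age_years = None
        if str(age).strip():
            try:
                age_years = float(age) / 12.0 if age_cod == "MON" else float(age)
            except ValueError:
                age_years = None
        reports.append(Report(
            report_id=pid,
            case_id=row["caseid"],
            version=int(row.get("caseversion", 0) or 0),
            receipt_date=parse_partial_date(row.get("fda_dt", "")),
            sex=_parse_sex(row.get("sex", "")),
            age_band=bin_age(age_years) if age_years is not None else AgeBand.NS,
            drugs=drugs,
            events=events,
        ))
    logger.info("loaded %s: %d DEMO rows -> %d reports (%d dropped)",
                root, len(demo), len(reports), dropped)
    return ReportSet(reports, provenance=str(root))


# ---------------------------------------------------------------------------
# dedup & window

def deduplicate(rs: ReportSet) -> ReportSet:
    """Keep one report per case: highest version, then latest receipt date,
    then lexicographically largest report_id.  Output is sorted by case_id."""
    best: dict[str, Report] = {}
    for rep in rs:
        key = (rep.version, rep.receipt_date, rep.report_id)
        cur = best.get(rep.case_id)
        if cur is None or key > (cur.version, cur.receipt_date, cur.report_id):
            best[rep.case_id] = rep
    out = [best[cid] for cid in sorted(best)]
    return ReportSet(out, provenance=rs.provenance)


def filter_window(rs: ReportSet, start: date, end: date) -> ReportSet:
    """Retain reports received within [start, end], inclusive on both ends."""
    if start > end:
        raise ValueError(f"start {start} is after end {end}")
    kept = [r for r in rs if start <= r.receipt_date <= end]
    return ReportSet(kept, provenance=rs.provenance)
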