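from __future__ import annotations

from datetime import date
from pathlib import Path

import pytest

from pvsignal import (
    AgeBand, DrugMention, DrugRole, Report, Sex, demo_vocabulary,
)


@pytest.fixture(scope="session")
def vocab():
    return demo_vocabulary()


def make_report(
    report_id: str = "R1",
    case_id: str | None = None,
    version: int = 1,
    receipt: date = date(2021, 6, 15),
    sex: Sex = Sex.NS,
    age_band: AgeBand = AgeBand.NS,
    drug: str = "tiotropium",
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
    events: tuple[str, ...] = ("HEADACHE",),
) -> Report:
    return Report(
        report_id=report_id,
        case_id=case_id if case_id is not None else f"C{report_id}",
        version=version,
        receipt_date=receipt,
        sex=sex,
        age_band=age_band,
        drugs=(DrugMention(drug, role),),
        events=frozenset(events),
    )


@pytest.fixture
def write_native_csv(tmp_path: Path):
    """Write native-dialect rows (list of dicts) to a temp CSV."""

    def _write(rows: list[dict], name: str = "reports.csv") -> Path:
        cols = ["report_id", "case_id", "version", "receipt_date", "sex",
                "age", "age_band", "drug_verbatim", "drug_role", "event_pt"]
        path = tmp_path / name
        lines = [",".join(cols)]
        for row in rows:
            lines.append(",".join(str(row.get(c, "")) for c in cols))
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def native_row(report_id="R1", case_id=None, version=1,
               receipt_date="2021-06-15", sex="F", age="", age_band="",
               drug_verbatim="tiotropium", drug_role="PS",
               event_pt="Atrial fibrillation") -> dict:
    return {
        "report_id": report_id,
        "case_id": case_id if case_id is not None else f"C{report_id}",
        "version": version, "receipt_date": receipt_date, "sex": sex,
        "age": age, "age_band": age_band, "drug_verbatim": drug_verbatim,
        "drug_role": drug_role, "event_pt": event_pt,
    }
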