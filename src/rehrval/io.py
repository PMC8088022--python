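"""Delimited-text interchange for claims cohorts.

Two flat UTF-8 tables mirror the shape of a claims extract:

* an **events** table, one row per encounter, columns
  ``patient_id, event_date, category, code, code_system, quantity,
  duration_days, provider_specialty, location`` (ISO-8601 dates, header
  required, comma default / tab accepted);
* an optional **patients** table with demographics and the index date,
  columns ``patient_id, birth_year, sex, index_date, location``.

``read_events(write_events(x))`` is an exact round trip, including the
relative order of same-day events.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import ClaimsEvent, EventCategory, PatientRecord, Sex

EVENT_COLUMNS = [
    "patient_id",
    "event_date",
    "category",
    "code",
    "code_system",
    "quantity",
    "duration_days",
    "provider_specialty",
    "location",
]
PATIENT_COLUMNS = ["patient_id", "birth_year", "sex", "index_date", "location"]


class ParseError(ValueError):
    """Malformed interchange file; the message names the offending row."""


def _parse_date(value: str, row: int, path: Path) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        raise ParseError(f"{path}: row {row}: malformed date {value!r}") from None


def read_events(
    path: str | Path,
    patients_path: str | Path | None = None,
    delimiter: str | None = None,
) -> list[PatientRecord]:
    """Read an events table (and optionally a patients table) into records.

    Records are grouped by patient and internally sorted by event date,
    preserving file order among same-day events.  Without a patients
    table, demographics default (birth_year 0, sex F) and the index date
    is each patient's first event date.  Duplicate rows are kept: claims
    may legitimately repeat.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = ""

    events_by_patient: dict[str, list[ClaimsEvent]] = {}
    valid_categories = {c.value for c in EventCategory}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        cat = getattr(row, "category")
        if cat not in valid_categories:
            raise ParseError(f"{path}: row {i}: unknown category {cat!r}")
        quantity = getattr(row, "quantity")
        duration = getattr(row, "duration_days")
        ev = ClaimsEvent(
            patient_id=str(getattr(row, "patient_id")),
            event_date=_parse_date(getattr(row, "event_date"), i, path),
            category=EventCategory(cat),
            code=str(getattr(row, "code")),
            code_system=str(getattr(row, "code_system")),
            quantity=float(quantity) if quantity != "" else None,
            duration_days=int(duration) if duration != "" else None,
            provider_specialty=str(getattr(row, "provider_specialty")),
            location=str(getattr(row, "location")),
        )
        events_by_patient.setdefault(ev.patient_id, []).append(ev)

    demographics: dict[str, dict] = {}
    patient_order: list[str] = list(events_by_patient)
    if patients_path is not None:
        pdf = pd.read_csv(Path(patients_path), sep=delimiter, engine="python", dtype=str, keep_default_na=False)
        missing = [c for c in PATIENT_COLUMNS[:4] if c not in pdf.columns]
        if missing:
            raise ParseError(f"{patients_path}: missing required columns {missing}")
        for i, row in enumerate(pdf.itertuples(index=False), start=2):
            pid = str(getattr(row, "patient_id"))
            demographics[pid] = dict(
                birth_year=int(getattr(row, "birth_year")),
                sex=Sex(getattr(row, "sex")),
                index_date=_parse_date(getattr(row, "index_date"), i, Path(patients_path)),
                location=str(getattr(row, "location", "")),
            )
        patient_order = list(pdf["patient_id"].astype(str))
        for pid in events_by_patient:
            if pid not in demographics:
                raise ParseError(f"{path}: patient {pid!r} has events but no patients-table row")

    records = []
    for pid in patient_order:
        events = sorted(events_by_patient.get(pid, []), key=lambda e: e.event_date)
        demo = demographics.get(pid)
        if demo is None:
            demo = dict(
                birth_year=0,
                sex=Sex.FEMALE,
                index_date=events[0].event_date,
                location="",
            )
        records.append(PatientRecord(patient_id=pid, events=events, **demo))
    return records


def events_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records into the events-table layout."""
    rows = [
        {
            "patient_id": ev.patient_id,
            "event_date": ev.event_date.isoformat(),
            "category": ev.category.value,
            "code": ev.code,
            "code_system": ev.code_system,
            "quantity": "" if ev.quantity is None else ev.quantity,
            "duration_days": "" if ev.duration_days is None else ev.duration_days,
            "provider_specialty": ev.provider_specialty,
            "location": ev.location,
        }
        for rec in records
        for ev in rec.events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def patients_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": rec.patient_id,
            "birth_year": rec.birth_year,
            "sex": rec.sex.value,
            "index_date": rec.index_date.isoformat(),
            "location": rec.location,
        }
        for rec in records
    ]
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def write_events(
    records: Sequence[PatientRecord],
    path: str | Path,
    patients_path: str | Path | None = None,
    delimiter: str = ",",
) -> None:
    """Write records as an events table (plus optional patients table)."""
    events_frame(records).to_csv(path, sep=delimiter, index=False)
    if patients_path is not None:
        patients_frame(records).to_csv(patients_path, sep=delimiter, index=False)
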