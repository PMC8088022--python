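"""Anonymized reconstituted EHRs (rEHRs) for expert review.

A claims record becomes a reviewable chronological document through four
irreversible transformations: a fresh review identifier (keyed one-way
digest, unlinkable without the salt), calendar dates replaced by the
signed delay in days since inclusion, location details dropped, and age
shown only as a class (5-year bins by default).  The unblinding map
(review_id -> patient_id) is kept in a separate ledger that is never
passed to the adjudication step, so blinding holds by construction.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import ClaimsEvent, EventCategory, PatientRecord, Sex
from .vocab import CODE_LABELS


class AnonymizationError(ValueError):
    pass


@dataclass(frozen=True)
class REHREntry:
    delay_days: int
    category: EventCategory
    code: str
    label: str
    details: str = ""


@dataclass(frozen=True)
class REHR:
    """The anonymized, delay-indexed rendition of a patient record.

    Carries no calendar date, no original identifier, no location, and
    no field derived from any algorithm output.  Delays may be negative
    (history before inclusion).
    """

    review_id: str
    age_class: str
    sex: Sex
    entries: tuple[REHREntry, ...]


def review_id_for(patient_id: str, salt: str, digest_size: int = 6) -> str:
    """Truncated keyed digest; different salts give unlinkable ids."""
    h = hashlib.blake2b(patient_id.encode(), key=salt.encode()[:64], digest_size=digest_size)
    return "R" + h.hexdigest()


def age_class(age: int, width: int = 5) -> str:
    lo = (age // width) * width
    return f"{lo}–{lo + width - 1}"  # en dash, e.g. "40–44"


def _entry_details(ev: ClaimsEvent) -> str:
    parts = []
    if ev.quantity is not None:
        parts.append(f"quantity {ev.quantity:g}")
    if ev.duration_days is not None:
        parts.append(f"{ev.duration_days} day stay")
    if ev.provider_specialty:
        parts.append(ev.provider_specialty)
    return ", ".join(parts)


def build_rehr(
    record: PatientRecord,
    inclusion_date: dt.date | None = None,
    id_salt: str = "",
    code_labels: Mapping[str, str] | None = None,
    age_class_width: int = 5,
) -> REHR:
    """Anonymize one record relative to its inclusion date.

    ``inclusion_date`` defaults to the record's index date and must lie
    within the observation span.  Labels fall back to the shared code
    dictionary; an unlabelled code is shown raw with a flag.
    """
    if inclusion_date is None:
        inclusion_date = record.index_date
    lo, hi = record.observation_span
    if not (lo <= inclusion_date <= hi):
        raise AnonymizationError(
            f"inclusion date {inclusion_date} outside observation span [{lo}, {hi}]"
        )
    labels = CODE_LABELS if code_labels is None else code_labels
    entries = tuple(
        REHREntry(
            delay_days=(ev.event_date - inclusion_date).days,
            category=ev.category,
            code=ev.code,
            label=_label_for(ev.code, labels),
            details=_entry_details(ev),
        )
        for ev in record.events
    )
    entries = tuple(sorted(entries, key=lambda e: (e.delay_days, e.category.value, e.code)))
    age = inclusion_date.year - record.birth_year
    return REHR(
        review_id=review_id_for(record.patient_id, id_salt),
        age_class=age_class(age, age_class_width),
        sex=record.sex,
        entries=entries,
    )


def _label_for(code: str, labels: Mapping[str, str]) -> str:
    if code in labels:
        return labels[code]
    # ICD-10 children inherit the parent label
    root = code.split(".")[0]
    if root in labels:
        return labels[root]
    return "unlabelled code"


def build_rehr_batch(
    records: Sequence[PatientRecord],
    id_salt: str,
    **kwargs,
) -> tuple[list[REHR], dict[str, str]]:
    """Anonymize a batch; returns (rEHRs, unblinding ledger).

    The ledger maps review_id -> patient_id and is the only link back;
    write it to a separate file and keep it away from reviewers.
    """
    rehrs, ledger = [], {}
    for rec in records:
        r = build_rehr(rec, id_salt=id_salt, **kwargs)
        if r.review_id in ledger:
            raise AnonymizationError(f"review_id collision for {r.review_id}")
        ledger[r.review_id] = rec.patient_id
        rehrs.append(r)
    return rehrs, ledger


# --- rendering ----------------------------------------------------------

_ENTRY_RE = re.compile(r"^D(?P<delay>[+-]\d+)\s+—\s+(?P<category>\S+)\s+—\s+")


def render_rehr(rehr: REHR) -> str:
    """Deterministic plain-text review document.

    Header (review id, age class, sex), then one line per entry:
    ``D+<delay> — <category> — <label> (<code>)[ — details]``.
    Same-delay entries order by (category, code).
    """
    lines = [
        f"rEHR {rehr.review_id}",
        f"age class {rehr.age_class} | sex {rehr.sex.value}",
        "",
    ]
    for e in rehr.entries:
        line = f"D{e.delay_days:+d} — {e.category.value} — {e.label} ({e.code})"
        if e.details:
            line += f" — {e.details}"
        lines.append(line)
    return "\n".join(lines) + "\n"


def parse_rendered_delays(document: str) -> list[int]:
    """Recover entry delays from a rendered document (round-trip check)."""
    out = []
    for line in document.splitlines():
        m = _ENTRY_RE.match(line)
        if m:
            out.append(int(m.group("delay")))
    return out


# --- leak scanning ------------------------------------------------------

#: Date shapes that must never survive anonymization.
DATE_PATTERNS = (
    re.compile(r"\b\d{4}-\d{2}-\d{2}\b"),          # ISO-8601
    re.compile(r"\b\d{1,2}/\d{1,2}/\d{2,4}\b"),    # d/m/y
    re.compile(r"\b(19|20)\d{2}\b"),               # bare year
    re.compile(
        r"\b(Jan|Feb|Mar|Apr|May|Jun|Jul|Aug|Sep|Oct|Nov|Dec)[a-z]*\.? \d{1,2}",
        re.IGNORECASE,
    ),
)


def scan_for_leaks(
    document: str,
    patient_ids: Sequence[str] = (),
    locations: Sequence[str] = (),
) -> list[str]:
    """Findings (empty = clean): date substrings, raw ids, location tokens."""
    findings = []
    for pat in DATE_PATTERNS:
        for m in pat.finditer(document):
            findings.append(f"date-like substring {m.group(0)!r}")
    for pid in patient_ids:
        if pid and pid in document:
            findings.append(f"raw patient id {pid!r}")
    for loc in locations:
        if loc and loc in document:
            findings.append(f"location token {loc!r}")
    return findings
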