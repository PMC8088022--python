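"""Core domain types for longitudinal claims data.

A claims extract is modelled as a stream of dated, coded healthcare
encounters per pseudonymized patient: drug dispensings (ATC-coded at
product granularity), hospital stays with ICD-10 discharge diagnoses,
procedures (no results), medical visits, long-term-disease (LTD)
registrations and death records.  Time is day-resolved — claims carry no
time of day.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence


class EventCategory(str, Enum):
    DISPENSING = "dispensing"
    HOSPITAL_STAY = "hospital_stay"
    PROCEDURE = "procedure"
    VISIT = "visit"
    LTD_REGISTRATION = "ltd_registration"
    DEATH = "death"


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"


#: ICD-10 shape: one letter, two digits, optional subcode (dot optional).
ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.?[A-Z0-9]{0,4})?$")

#: Categories whose codes are ICD-10 by convention in this data model.
_ICD10_CATEGORIES = frozenset(
    {EventCategory.HOSPITAL_STAY, EventCategory.LTD_REGISTRATION, EventCategory.DEATH}
)


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


@dataclass(frozen=True)
class ClaimsEvent:
    """One dated, coded healthcare encounter.

    ``quantity`` is meaningful only for dispensings, ``duration_days``
    only for hospital stays; both must be ``None`` elsewhere.
    """

    patient_id: str
    event_date: dt.date
    category: EventCategory
    code: str
    code_system: str = ""
    quantity: float | None = None
    duration_days: int | None = None
    provider_specialty: str = ""
    location: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.event_date, dt.date) or isinstance(self.event_date, dt.datetime):
            raise InvariantError(f"event_date must be a calendar day, got {self.event_date!r}")
        object.__setattr__(self, "category", EventCategory(self.category))
        if self.quantity is not None:
            if self.category is not EventCategory.DISPENSING:
                raise InvariantError("quantity is only valid for dispensing events")
            if self.quantity < 0:
                raise InvariantError("quantity must be non-negative")
        if self.duration_days is not None:
            if self.category is not EventCategory.HOSPITAL_STAY:
                raise InvariantError("duration_days is only valid for hospital_stay events")
            if self.duration_days < 0:
                raise InvariantError("duration_days must be non-negative")
        if self.category in _ICD10_CATEGORIES and self.code_system.upper() in ("", "ICD-10", "ICD10"):
            if not ICD10_RE.match(self.code):
                raise InvariantError(
                    f"code {self.code!r} does not look like ICD-10 "
                    "(letter + 2 digits + optional subcode)"
                )


@dataclass
class PatientRecord:
    """A patient's full ordered event stream plus demographics.

    ``index_date`` is the cohort-entry (inclusion) date from which rEHR
    delays are later counted.  Events are kept sorted non-decreasing by
    date; same-day events preserve their insertion order and downstream
    algorithms must not depend on that order.
    """

    patient_id: str
    birth_year: int
    sex: Sex
    index_date: dt.date
    events: list[ClaimsEvent] = field(default_factory=list)
    location: str = ""

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        for ev in self.events:
            if ev.patient_id != self.patient_id:
                raise InvariantError(
                    f"event patient_id {ev.patient_id!r} != record {self.patient_id!r}"
                )
        if any(
            a.event_date > b.event_date for a, b in zip(self.events, self.events[1:])
        ):
            # stable: same-day order is preserved, only date order enforced
            self.events = sorted(self.events, key=lambda e: e.event_date)
        if self.events:
            lo, hi = self.observation_span
            if not (lo <= self.index_date <= hi):
                raise InvariantError(
                    f"index_date {self.index_date} outside observation span [{lo}, {hi}]"
                )

    @property
    def observation_span(self) -> tuple[dt.date, dt.date]:
        """(first, last) event date; (index_date, index_date) if no events."""
        if not self.events:
            return (self.index_date, self.index_date)
        return (self.events[0].event_date, self.events[-1].event_date)

    def events_in(
        self,
        category: EventCategory | None = None,
        on_or_after: dt.date | None = None,
    ) -> list[ClaimsEvent]:
        out: Iterable[ClaimsEvent] = self.events
        if category is not None:
            out = (e for e in out if e.category is category)
        if on_or_after is not None:
            out = (e for e in out if e.event_date >= on_or_after)
        return list(out)

    def with_events(self, events: Sequence[ClaimsEvent]) -> "PatientRecord":
        return replace(self, events=list(events))
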