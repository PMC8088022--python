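"""Synthetic SNDS-like cohorts with planted ground truth.

The generator emulates the French claims database at the granularity the
validation method needs: per-patient streams of drug dispensings
(ATC-coded at product level), hospital stays with ICD-10 discharge
diagnoses, procedures, medical visits and long-term-disease
registrations, driven by a planted true disease status plus background
noise.  Two disease models are shipped:

* **MS relapses** — true relapse times follow a homogeneous Poisson
  process over each patient's follow-up; each relapse emits a high-dose
  corticosteroid dispensing and/or an MS-coded hospital stay (0–3 day
  jitter after onset, dispensing follows onset), on top of disease-
  modifying-therapy refills, visits and unrelated care.
* **prostate cancer** — each patient gets a state trajectory
  (diagnosis → optional metastasis → optional castration resistance,
  resistance may precede metastasis); each state emits its own Poisson
  stream of indicator events (bone-targeted agents, metastatic-site
  stays, imaging; mCRPC-specific therapies) from the transition date on.

All randomness flows from one integer seed through
``numpy.random.SeedSequence.spawn``, so each patient's stream is
reproducible independently of cohort size.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import vocab
from .model import ClaimsEvent, EventCategory, PatientRecord, Sex

DAYS_PER_YEAR = 365.25


class ParameterError(ValueError):
    pass


# --- ground truth -------------------------------------------------------

PCA_STATES = ("non_met_HSPC", "met_HSPC", "non_met_CRPC", "mCRPC")


@dataclass
class GroundTruth:
    """Planted truth for one simulated patient.

    MS mode fills ``true_relapse_dates``; prostate-cancer mode fills
    ``true_state`` and the transition dates (mCRPC implies both a
    metastasis date and a resistance date).
    """

    patient_id: str
    is_case: bool
    true_relapse_dates: list[dt.date] = field(default_factory=list)
    true_state: str | None = None
    diagnosis_date: dt.date | None = None
    metastasis_date: dt.date | None = None
    resistance_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.true_state is not None and self.true_state not in PCA_STATES:
            raise ParameterError(f"unknown state {self.true_state!r}")
        if self.true_state == "mCRPC" and (
            self.metastasis_date is None or self.resistance_date is None
        ):
            raise ParameterError("mCRPC requires both a metastasis and a resistance date")


# --- parameters ---------------------------------------------------------

def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {p}")


def _check_rate(name: str, r: float) -> None:
    if r < 0:
        raise ParameterError(f"{name} must be >= 0, got {r}")


@dataclass(frozen=True)
class MSCohortParams:
    """Study conditions for the simulated MS cohort.

    Defaults mirror the validation-study setting: cohort entry at a
    first dimethyl-fumarate dispensing between mid-2015 and end-2017,
    4.5 years of history, 1–3.5 years of follow-up, and an annualized
    relapse rate of 0.45 (typical for treated relapsing-remitting MS).
    """

    n_patients: int
    history_years: float = 4.5
    followup_years: tuple[float, float] = (1.0, 3.5)
    relapse_rate_per_year: float = 0.45
    p_steroid_given_relapse: float = 0.9
    p_hospital_given_relapse: float = 0.85
    noise_steroid_rate_per_year: float = 0.05
    noise_hospital_rate_per_year: float = 0.10
    jitter_days_max: int = 3
    background_visit_rate_per_year: float = 3.0
    dmt_refill_interval_days: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ParameterError("n_patients must be positive")
        fu = self.followup_years
        if isinstance(fu, (int, float)):
            object.__setattr__(self, "followup_years", (float(fu), float(fu)))
        _check_prob("p_steroid_given_relapse", self.p_steroid_given_relapse)
        _check_prob("p_hospital_given_relapse", self.p_hospital_given_relapse)
        for name in (
            "relapse_rate_per_year",
            "noise_steroid_rate_per_year",
            "noise_hospital_rate_per_year",
            "background_visit_rate_per_year",
        ):
            _check_rate(name, getattr(self, name))


@dataclass(frozen=True)
class PCaCohortParams:
    """Study conditions for the simulated prostate-cancer cohort.

    Follow-up is 3 years from a prostate-cancer diagnosis (hospital or
    LTD code, with androgen-deprivation therapy ongoing).  Transition
    probabilities are illustrative: no care-pathway frequencies are
    published for this setting.
    """

    n_patients: int
    history_years: float = 5.0
    followup_years: float = 3.0
    p_metastasis: float = 0.30
    p_resistance_given_met: float = 0.50
    p_resistance_given_non_met: float = 0.08
    met_event_rate_per_year: float = 2.0
    res_event_rate_per_year: float = 2.0
    adt_rate_per_year: float = 4.0
    noise_imaging_rate_per_year: float = 0.05
    background_visit_rate_per_year: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ParameterError("n_patients must be positive")
        for name in (
            "p_metastasis",
            "p_resistance_given_met",
            "p_resistance_given_non_met",
        ):
            _check_prob(name, getattr(self, name))
        for name in (
            "met_event_rate_per_year",
            "res_event_rate_per_year",
            "adt_rate_per_year",
            "noise_imaging_rate_per_year",
            "background_visit_rate_per_year",
        ):
            _check_rate(name, getattr(self, name))


# --- helpers ------------------------------------------------------------

def _poisson_days(rng: np.random.Generator, rate_per_year: float, span_days: int) -> list[int]:
    """Event day offsets of a homogeneous Poisson process over a span."""
    if rate_per_year <= 0 or span_days <= 0:
        return []
    k = rng.poisson(rate_per_year * span_days / DAYS_PER_YEAR)
    return sorted(int(d) for d in rng.integers(0, span_days, size=k))


def _random_date(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    return lo + dt.timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


_FR_LOCATIONS = ("Bordeaux", "Toulouse", "Nancy", "Paris", "Lyon", "Lille")


# --- MS cohort ----------------------------------------------------------

def simulate_ms_cohort(
    params: MSCohortParams,
) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Simulate an MS treatment cohort with planted relapse dates."""
    records, truths = [], []
    children = np.random.SeedSequence(params.seed).spawn(params.n_patients)
    fu_lo, fu_hi = params.followup_years
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"MS{i:06d}"
        birth_year = int(rng.integers(1955, 1996))
        sex = Sex.FEMALE if rng.random() < 0.72 else Sex.MALE
        index = _random_date(rng, dt.date(2015, 7, 1), dt.date(2017, 12, 31))
        followup_days = int(round(rng.uniform(fu_lo, fu_hi) * DAYS_PER_YEAR))
        history_days = int(round(params.history_years * DAYS_PER_YEAR))
        location = _FR_LOCATIONS[int(rng.integers(len(_FR_LOCATIONS)))]

        events: list[ClaimsEvent] = []

        def add(day_offset: int, **kw) -> None:
            events.append(
                ClaimsEvent(
                    patient_id=pid,
                    event_date=index + dt.timedelta(days=day_offset),
                    location=location,
                    **kw,
                )
            )

        # cohort entry: first MS-drug dispensing, then refills over follow-up
        for day in range(0, followup_days, params.dmt_refill_interval_days):
            add(day, category=EventCategory.DISPENSING, code=vocab.MS_DRUG_CODE,
                code_system="ATC", quantity=1.0)

        # true relapses: homogeneous Poisson over follow-up
        relapse_offsets = _poisson_days(rng, params.relapse_rate_per_year, followup_days)
        relapse_dates = [index + dt.timedelta(days=d) for d in relapse_offsets]
        for day in relapse_offsets:
            jitter = lambda: int(rng.integers(0, params.jitter_days_max + 1))
            if rng.random() < params.p_steroid_given_relapse:
                add(day + jitter(), category=EventCategory.DISPENSING,
                    code=str(rng.choice(vocab.STEROID_CODES)), code_system="ATC",
                    quantity=float(rng.integers(1, 4)))
            if rng.random() < params.p_hospital_given_relapse:
                code = "G35" if rng.random() < 0.8 else str(rng.choice(("G36.9", "G04.9", "H46")))
                add(day + jitter(), category=EventCategory.HOSPITAL_STAY, code=code,
                    code_system="ICD-10", duration_days=int(rng.integers(1, 6)))

        # unrelated care: visits over the whole span, noise signal events
        for day in _poisson_days(rng, params.background_visit_rate_per_year,
                                 history_days + followup_days):
            add(day - history_days, category=EventCategory.VISIT, code=vocab.VISIT_CODE_GP,
                code_system="NGAP", provider_specialty="general practice")
        for day in _poisson_days(rng, params.noise_steroid_rate_per_year,
                                 history_days + followup_days):
            add(day - history_days, category=EventCategory.DISPENSING,
                code=str(rng.choice(vocab.STEROID_CODES)), code_system="ATC", quantity=1.0)
        for day in _poisson_days(rng, params.noise_hospital_rate_per_year, followup_days):
            # scheduled MS monitoring stays carry the disease code too
            add(day, category=EventCategory.HOSPITAL_STAY, code="G35",
                code_system="ICD-10", duration_days=1)

        events.sort(key=lambda e: e.event_date)
        records.append(
            PatientRecord(patient_id=pid, birth_year=birth_year, sex=sex,
                          index_date=index, events=events, location=location)
        )
        truths.append(
            GroundTruth(patient_id=pid, is_case=bool(relapse_dates),
                        true_relapse_dates=relapse_dates)
        )
    return records, truths


# --- prostate-cancer cohort ---------------------------------------------

def simulate_pca_cohort(
    params: PCaCohortParams,
) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Simulate a prostate-cancer cohort with planted state trajectories."""
    records, truths = [], []
    children = np.random.SeedSequence(params.seed).spawn(params.n_patients)
    followup_days = int(round(params.followup_years * DAYS_PER_YEAR))
    history_days = int(round(params.history_years * DAYS_PER_YEAR))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"PC{i:06d}"
        birth_year = int(rng.integers(1935, 1966))
        index = _random_date(rng, dt.date(2009, 1, 1), dt.date(2014, 12, 31))
        location = _FR_LOCATIONS[int(rng.integers(len(_FR_LOCATIONS)))]

        # trajectory: transitions dated uniformly over follow-up; resistance
        # may precede metastasis, both follow diagnosis (= index)
        has_met = rng.random() < params.p_metastasis
        p_res = params.p_resistance_given_met if has_met else params.p_resistance_given_non_met
        has_res = rng.random() < p_res
        met_day = int(rng.integers(0, followup_days)) if has_met else None
        res_day = int(rng.integers(0, followup_days)) if has_res else None
        if has_met and has_res:
            state = "mCRPC"
        elif has_met:
            state = "met_HSPC"
        elif has_res:
            state = "non_met_CRPC"
        else:
            state = "non_met_HSPC"

        events: list[ClaimsEvent] = []

        def add(day_offset: int, **kw) -> None:
            events.append(
                ClaimsEvent(
                    patient_id=pid,
                    event_date=index + dt.timedelta(days=day_offset),
                    location=location,
                    **kw,
                )
            )

        add(0, category=EventCategory.HOSPITAL_STAY, code=vocab.PCA_DIAGNOSIS_CODE,
            code_system="ICD-10", duration_days=int(rng.integers(1, 8)))
        add(0, category=EventCategory.LTD_REGISTRATION, code=vocab.PCA_DIAGNOSIS_CODE,
            code_system="ICD-10")
        for day in _poisson_days(rng, params.adt_rate_per_year, followup_days):
            add(day, category=EventCategory.DISPENSING,
                code=str(rng.choice(vocab.ADT_CODES)), code_system="ATC", quantity=1.0)
        if met_day is not None:
            for day in _poisson_days(rng, params.met_event_rate_per_year,
                                     followup_days - met_day):
                kind = rng.integers(3)
                if kind == 0:
                    add(met_day + day, category=EventCategory.DISPENSING,
                        code=str(rng.choice(vocab.MET_DISPENSING_CODES)),
                        code_system="ATC", quantity=1.0)
                elif kind == 1:
                    add(met_day + day, category=EventCategory.HOSPITAL_STAY,
                        code="C79.5", code_system="ICD-10",
                        duration_days=int(rng.integers(1, 6)))
                else:
                    add(met_day + day, category=EventCategory.PROCEDURE,
                        code=str(rng.choice(vocab.MET_PROCEDURE_CODES)),
                        code_system="CCAM")
        if res_day is not None:
            for day in _poisson_days(rng, params.res_event_rate_per_year,
                                     followup_days - res_day):
                add(res_day + day, category=EventCategory.DISPENSING,
                    code=str(rng.choice(vocab.CRPC_DISPENSING_CODES)),
                    code_system="ATC", quantity=1.0)
        for day in _poisson_days(rng, params.noise_imaging_rate_per_year, followup_days):
            # staging work-up imaging also occurs outside metastatic disease
            add(day, category=EventCategory.PROCEDURE, code="PAQK007", code_system="CCAM")
        for day in _poisson_days(rng, params.background_visit_rate_per_year,
                                 history_days + followup_days):
            add(day - history_days, category=EventCategory.VISIT, code=vocab.VISIT_CODE_GP,
                code_system="NGAP", provider_specialty="general practice")

        events.sort(key=lambda e: e.event_date)
        records.append(
            PatientRecord(patient_id=pid, birth_year=birth_year, sex=Sex.MALE,
                          index_date=index, events=events, location=location)
        )
        truths.append(
            GroundTruth(
                patient_id=pid, is_case=(state == "mCRPC"), true_state=state,
                diagnosis_date=index,
                metastasis_date=None if met_day is None else index + dt.timedelta(days=met_day),
                resistance_date=None if res_day is None else index + dt.timedelta(days=res_day),
            )
        )
    return records, truths


# --- noise injection ----------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Misclassification stressor: spurious additions and deletions.

    ``additions`` maps (category, code, code_system) to a yearly rate of
    spurious events over each record's observation span; ``delete_probs``
    maps a code prefix to the probability that each matching event is
    dropped.  Planted ground truth is never touched.
    """

    additions: tuple[tuple[EventCategory, str, str, float], ...] = ()
    delete_probs: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        for *_, rate in self.additions:
            _check_rate("addition rate", rate)
        for prefix, p in self.delete_probs:
            _check_prob(f"delete_probs[{prefix}]", p)


def inject_noise(
    records: Sequence[PatientRecord], noise: NoiseSpec, seed: int
) -> list[PatientRecord]:
    """Return noisy copies of the records; the inputs are not modified."""
    out = []
    children = np.random.SeedSequence(seed).spawn(len(records))
    for rec, child in zip(records, children):
        rng = np.random.default_rng(child)
        events = []
        for ev in rec.events:
            if any(ev.code.upper().startswith(pfx.upper()) and rng.random() < p
                   for pfx, p in noise.delete_probs):
                continue
            events.append(ev)
        lo, hi = rec.observation_span
        span = max((hi - lo).days, 1)
        for category, code, system, rate in noise.additions:
            category = EventCategory(category)
            for day in _poisson_days(rng, rate, span):
                events.append(
                    ClaimsEvent(
                        patient_id=rec.patient_id,
                        event_date=lo + dt.timedelta(days=day),
                        category=category,
                        code=code,
                        code_system=system,
                        quantity=1.0 if category is EventCategory.DISPENSING else None,
                        duration_days=1 if category is EventCategory.HOSPITAL_STAY else None,
                        location=rec.location,
                    )
                )
        events.sort(key=lambda e: e.event_date)
        out.append(rec.with_events(events))
    return out


# --- ground-truth interchange -------------------------------------------

TRUTH_COLUMNS = [
    "patient_id", "is_case", "relapse_dates", "true_state",
    "diagnosis_date", "metastasis_date", "resistance_date",
]


def write_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    rows = [
        {
            "patient_id": t.patient_id,
            "is_case": int(t.is_case),
            "relapse_dates": ";".join(d.isoformat() for d in t.true_relapse_dates),
            "true_state": t.true_state or "",
            "diagnosis_date": t.diagnosis_date.isoformat() if t.diagnosis_date else "",
            "metastasis_date": t.metastasis_date.isoformat() if t.metastasis_date else "",
            "resistance_date": t.resistance_date.isoformat() if t.resistance_date else "",
        }
        for t in truths
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_truth(path: str | Path) -> list[GroundTruth]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GroundTruth(
                patient_id=str(row.patient_id),
                is_case=bool(int(row.is_case)),
                true_relapse_dates=[
                    dt.date.fromisoformat(s) for s in str(row.relapse_dates).split(";") if s
                ],
                true_state=str(row.true_state) or None,
                diagnosis_date=dt.date.fromisoformat(row.diagnosis_date) if row.diagnosis_date else None,
                metastasis_date=dt.date.fromisoformat(row.metastasis_date) if row.metastasis_date else None,
                resistance_date=dt.date.fromisoformat(row.resistance_date) if row.resistance_date else None,
            )
        )
    return out
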