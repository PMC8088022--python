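"""Declarative temporal rule engine for case-identifying algorithms.

Two algorithm families are supported:

* **MS relapse** — a relapse signal is a high-dose corticosteroid
  dispensing combined (configurably) with an MS-related hospital
  discharge diagnosis; signals closer than a minimum independence lag
  are merged into one relapse episode (the shipped default lag is
  31 days: two signals exactly 31 days apart count as independent
  relapses).
* **mCRPC-style two-indicator classifier** — a patient is labelled
  metastatic castration-resistant prostate cancer when both a
  metastasis-management indicator and a castration-resistance indicator
  fire; the classification date is the later of the two earliest
  indicator dates.

Algorithm definitions are declarative (code sets + rule + windows) and
can be loaded from YAML; ``ms_relapse.yaml`` and ``mcrpc.yaml`` ship
with the package.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import yaml

from .model import EventCategory, PatientRecord


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CodeSet:
    """A named set of codes or code prefixes.

    Matching is by prefix, the ICD-10 convention: ``G35`` matches
    ``G35`` and any child such as ``G35.0``.  Prefixes are uppercase.
    """

    name: str
    system: str
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.codes:
            raise ConfigError(f"code set {self.name!r} is empty")
        object.__setattr__(self, "codes", frozenset(c.upper() for c in self.codes))

    def matches(self, code: str) -> bool:
        code = code.upper()
        return any(code.startswith(prefix) for prefix in self.codes)


SignalRule = Literal["either", "steroid_only", "require_both_within_window"]


@dataclass(frozen=True)
class RelapseAlgoConfig:
    steroid_codes: CodeSet
    ms_diagnosis_codes: CodeSet
    signal_rule: SignalRule = "require_both_within_window"
    co_occurrence_window_days: int = 30
    min_independence_lag_days: int = 31

    def __post_init__(self) -> None:
        if self.min_independence_lag_days < 1:
            raise ConfigError("min_independence_lag_days must be >= 1")
        if self.co_occurrence_window_days < 0:
            raise ConfigError("co_occurrence_window_days must be >= 0")
        if self.signal_rule not in ("either", "steroid_only", "require_both_within_window"):
            raise ConfigError(f"unknown signal_rule {self.signal_rule!r}")


@dataclass(frozen=True)
class IndicatorTrigger:
    """A code set restricted to one event category (e.g. ATC dispensings)."""

    category: EventCategory
    codes: CodeSet


@dataclass(frozen=True)
class MCRPCAlgoConfig:
    metastasis_indicator: tuple[IndicatorTrigger, ...]
    resistance_indicator: tuple[IndicatorTrigger, ...]
    classification_date_rule: Literal["max_of_indicators"] = "max_of_indicators"

    def __post_init__(self) -> None:
        if not self.metastasis_indicator or not self.resistance_indicator:
            raise ConfigError("both indicator lists must be non-empty")


@dataclass(frozen=True)
class EpisodeCall:
    """One algorithm finding: a relapse episode or a patient classification."""

    patient_id: str
    episode_start: dt.date
    label: str
    contributing_event_ids: tuple[int, ...] = ()
    indicator_dates: dict[str, dt.date] = field(default_factory=dict)


# --- MS relapse ---------------------------------------------------------

def detect_relapse_signals(
    record: PatientRecord, config: RelapseAlgoConfig
) -> list[dt.date]:
    """Dated relapse signals in follow-up (on/after the index date).

    ``either``: any steroid dispensing or MS-coded stay is a signal.
    ``steroid_only``: steroid dispensings only.
    ``require_both_within_window``: a steroid dispensing paired with an
    MS-coded stay within ± window days signals at the earlier of the
    pair.  Output is sorted ascending, deduplicated.
    """
    start = record.index_date
    steroid_days = [
        e.event_date
        for e in record.events_in(EventCategory.DISPENSING, on_or_after=start)
        if config.steroid_codes.matches(e.code)
    ]
    stay_days = [
        e.event_date
        for e in record.events_in(EventCategory.HOSPITAL_STAY, on_or_after=start)
        if config.ms_diagnosis_codes.matches(e.code)
    ]
    if config.signal_rule == "either":
        signals = set(steroid_days) | set(stay_days)
    elif config.signal_rule == "steroid_only":
        signals = set(steroid_days)
    else:  # require_both_within_window
        window = dt.timedelta(days=config.co_occurrence_window_days)
        signals = {
            min(s, h)
            for s in steroid_days
            for h in stay_days
            if abs(s - h) <= window
        }
    return sorted(signals)


def merge_episodes(signals: Sequence[dt.date], min_lag_days: int) -> list[dt.date]:
    """Greedy left-to-right merge of signals into independent episodes.

    The first signal opens an episode; each later signal opens a new one
    iff it falls >= ``min_lag_days`` after the start of the *current*
    episode (anchoring on the start prevents unbounded chaining of
    closely spaced treatments), else it is absorbed.  The boundary is
    inclusive: signals exactly ``min_lag_days`` apart are independent.
    """
    if any(a > b for a, b in zip(signals, signals[1:])):
        raise ValueError("signals must be sorted ascending")
    lag = dt.timedelta(days=min_lag_days)
    starts: list[dt.date] = []
    for s in signals:
        if not starts or s - starts[-1] >= lag:
            starts.append(s)
    return starts


# --- mCRPC two-indicator classifier ------------------------------------

def _earliest_indicator_date(
    record: PatientRecord, triggers: Sequence[IndicatorTrigger]
) -> dt.date | None:
    dates = [
        e.event_date
        for trig in triggers
        for e in record.events_in(trig.category, on_or_after=record.index_date)
        if trig.codes.matches(e.code)
    ]
    return min(dates) if dates else None


def classify_mcrpc(record: PatientRecord, config: MCRPCAlgoConfig) -> EpisodeCall:
    """Classify a prostate-cancer patient from the two time indicators.

    mCRPC requires both indicators; the classification date is the later
    of the two earliest indicator dates.  A single indicator yields the
    corresponding intermediate state, none yields non_met_HSPC.
    """
    met = _earliest_indicator_date(record, config.metastasis_indicator)
    res = _earliest_indicator_date(record, config.resistance_indicator)
    indicator_dates = {}
    if met is not None:
        indicator_dates["metastasis"] = met
    if res is not None:
        indicator_dates["resistance"] = res
    if met is not None and res is not None:
        label, start = "mCRPC", max(met, res)
    elif met is not None:
        label, start = "met_HSPC", met
    elif res is not None:
        label, start = "non_met_CRPC", res
    else:
        label, start = "non_met_HSPC", record.index_date
    return EpisodeCall(
        patient_id=record.patient_id,
        episode_start=start,
        label=label,
        indicator_dates=indicator_dates,
    )


# --- driver -------------------------------------------------------------

def run_algorithm(
    records: Sequence[PatientRecord],
    config: RelapseAlgoConfig | MCRPCAlgoConfig,
    mode: Literal["ms", "mcrpc"],
) -> tuple[list[EpisodeCall], dict[str, bool]]:
    """Apply an algorithm to a cohort.

    Returns (episode calls, per-patient case flag).  MS mode: a case has
    at least one relapse episode in follow-up.  mCRPC mode: a case is
    labelled mCRPC.
    """
    calls: list[EpisodeCall] = []
    flags: dict[str, bool] = {}
    if mode == "ms":
        if not isinstance(config, RelapseAlgoConfig):
            raise ConfigError("mode 'ms' requires a RelapseAlgoConfig")
        for rec in records:
            signals = detect_relapse_signals(rec, config)
            starts = merge_episodes(signals, config.min_independence_lag_days)
            calls.extend(
                EpisodeCall(patient_id=rec.patient_id, episode_start=s, label="relapse")
                for s in starts
            )
            flags[rec.patient_id] = bool(starts)
    elif mode == "mcrpc":
        if not isinstance(config, MCRPCAlgoConfig):
            raise ConfigError("mode 'mcrpc' requires a MCRPCAlgoConfig")
        for rec in records:
            call = classify_mcrpc(rec, config)
            calls.append(call)
            flags[rec.patient_id] = call.label == "mCRPC"
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    return calls, flags


# --- YAML configs -------------------------------------------------------

def _codeset_from_dict(name: str, d: dict) -> CodeSet:
    return CodeSet(name=name, system=str(d.get("system", "")), codes=frozenset(d["codes"]))


def load_config(path: str | Path) -> RelapseAlgoConfig | MCRPCAlgoConfig:
    """Load a declarative algorithm definition from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> RelapseAlgoConfig | MCRPCAlgoConfig:
    kind = doc.get("algorithm")
    if kind == "ms_relapse":
        return RelapseAlgoConfig(
            steroid_codes=_codeset_from_dict("steroids", doc["steroid_codes"]),
            ms_diagnosis_codes=_codeset_from_dict("ms_diagnoses", doc["ms_diagnosis_codes"]),
            signal_rule=doc.get("signal_rule", "require_both_within_window"),
            co_occurrence_window_days=int(doc.get("co_occurrence_window_days", 30)),
            min_independence_lag_days=int(doc.get("min_independence_lag_days", 31)),
        )
    if kind == "mcrpc":
        def triggers(key: str) -> tuple[IndicatorTrigger, ...]:
            return tuple(
                IndicatorTrigger(
                    category=EventCategory(t["category"]),
                    codes=_codeset_from_dict(f"{key}:{t['category']}", t),
                )
                for t in doc[key]
            )

        return MCRPCAlgoConfig(
            metastasis_indicator=triggers("metastasis_indicator"),
            resistance_indicator=triggers("resistance_indicator"),
            classification_date_rule=doc.get("classification_date_rule", "max_of_indicators"),
        )
    raise ConfigError(f"unknown algorithm kind {kind!r}")


def shipped_config(name: Literal["ms_relapse", "mcrpc"]) -> RelapseAlgoConfig | MCRPCAlgoConfig:
    """Load one of the algorithm definitions bundled with the package."""
    ref = resources.files("rehrval.configs").joinpath(f"{name}.yaml")
    return config_from_dict(yaml.safe_load(ref.read_text()))
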