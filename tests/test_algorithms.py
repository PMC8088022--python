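"""Temporal rule engine vs independent brute-force oracles."""

import datetime as dt
import random

import numpy as np
import pytest

from rehrval.algorithms import (
    CodeSet,
    ConfigError,
    MCRPCAlgoConfig,
    IndicatorTrigger,
    RelapseAlgoConfig,
    classify_mcrpc,
    detect_relapse_signals,
    merge_episodes,
    run_algorithm,
    shipped_config,
)
from rehrval.model import ClaimsEvent, EventCategory, PatientRecord, Sex

D0 = dt.date(2016, 1, 1)


def _d(day):
    return D0 + dt.timedelta(days=day)


def _record(steroid_days=(), stay_days=(), index_day=0, extra=()):
    pid = "T1"
    events = [
        ClaimsEvent(pid, _d(d), EventCategory.DISPENSING, "H02AB04", "ATC", quantity=1.0)
        for d in steroid_days
    ]
    events += [
        ClaimsEvent(pid, _d(d), EventCategory.HOSPITAL_STAY, "G35", "ICD-10", duration_days=2)
        for d in stay_days
    ]
    events += list(extra)
    events.append(ClaimsEvent(pid, _d(index_day), EventCategory.VISIT, "CS", "NGAP"))
    events.sort(key=lambda e: e.event_date)
    return PatientRecord(pid, 1975, Sex.FEMALE, _d(index_day), events)


MS_CFG = RelapseAlgoConfig(
    steroid_codes=CodeSet("steroids", "ATC", frozenset({"H02AB04", "H02AB01"})),
    ms_diagnosis_codes=CodeSet("ms", "ICD-10", frozenset({"G35", "G36", "G04", "H46"})),
)


def oracle_signals(steroid_days, stay_days, rule, window):
    """All-pairs brute force over the signal definition."""
    if rule == "either":
        return sorted(set(steroid_days) | set(stay_days))
    if rule == "steroid_only":
        return sorted(set(steroid_days))
    out = set()
    for s in steroid_days:
        for h in stay_days:
            if abs(s - h) <= window:
                out.add(min(s, h))
    return sorted(out)


class TestDetectSignals:
    def test_no_matching_codes(self):
        assert detect_relapse_signals(_record(), MS_CFG) == []

    def test_pair_within_window_signals_at_earlier_date(self):
        rec = _record(steroid_days=[10], stay_days=[12])
        cfg = RelapseAlgoConfig(MS_CFG.steroid_codes, MS_CFG.ms_diagnosis_codes,
                                co_occurrence_window_days=7)
        assert detect_relapse_signals(rec, cfg) == [_d(10)]

    def test_far_pair_rejected_by_both_rule_but_kept_by_either(self):
        rec = _record(steroid_days=[10], stay_days=[40])
        strict = RelapseAlgoConfig(MS_CFG.steroid_codes, MS_CFG.ms_diagnosis_codes,
                                   co_occurrence_window_days=7)
        assert detect_relapse_signals(rec, strict) == []
        loose = RelapseAlgoConfig(MS_CFG.steroid_codes, MS_CFG.ms_diagnosis_codes,
                                  signal_rule="either")
        assert detect_relapse_signals(rec, loose) == [_d(10), _d(40)]

    @pytest.mark.parametrize("rule", ["either", "steroid_only", "require_both_within_window"])
    def test_random_records_match_all_pairs_oracle(self, rule):
        rng = random.Random(314)
        for _ in range(200):
            steroids = sorted(rng.sample(range(0, 150), rng.randint(0, 6)))
            stays = sorted(rng.sample(range(0, 150), rng.randint(0, 6)))
            window = rng.choice([0, 7, 30])
            cfg = RelapseAlgoConfig(MS_CFG.steroid_codes, MS_CFG.ms_diagnosis_codes,
                                    signal_rule=rule, co_occurrence_window_days=window)
            got = detect_relapse_signals(_record(steroids, stays), cfg)
            want = [_d(d) for d in oracle_signals(steroids, stays, rule, window)]
            assert got == want

    def test_events_before_index_ignored(self):
        rec = _record(steroid_days=[-40, 10], stay_days=[-42, 12], index_day=0)
        cfg = RelapseAlgoConfig(MS_CFG.steroid_codes, MS_CFG.ms_diagnosis_codes,
                                co_occurrence_window_days=7)
        assert detect_relapse_signals(rec, cfg) == [_d(10)]

    def test_same_day_order_invariance(self):
        base = [
            ClaimsEvent("T1", _d(5), EventCategory.DISPENSING, "H02AB04", "ATC", quantity=1.0),
            ClaimsEvent("T1", _d(5), EventCategory.HOSPITAL_STAY, "G35", "ICD-10", duration_days=1),
            ClaimsEvent("T1", _d(5), EventCategory.VISIT, "CS", "NGAP"),
        ]
        results = set()
        for perm in ([0, 1, 2], [2, 1, 0], [1, 0, 2]):
            rec = PatientRecord("T1", 1975, Sex.FEMALE, _d(0), [
                ClaimsEvent("T1", _d(0), EventCategory.VISIT, "CS", "NGAP"),
                *[base[i] for i in perm],
            ])
            results.add(tuple(detect_relapse_signals(rec, MS_CFG)))
        assert len(results) == 1


def oracle_merge(days, lag):
    """Recursive formulation: next episode = first signal >= lag after start."""
    if not days:
        return []
    head, rest = days[0], [d for d in days if d - days[0] >= lag]
    return [head] + oracle_merge(rest, lag)


class TestMergeEpisodes:
    def test_empty(self):
        assert merge_episodes([], 31) == []

    @pytest.mark.parametrize(
        "days,expected",
        [
            ([0, 10, 45], [0, 45]),
            ([0, 20, 40], [0, 40]),   # day 20 absorbed; 40 >= 31 after 0
            ([0, 31], [0, 31]),       # boundary inclusive: exactly 31 days apart
            ([0, 30], [0]),
        ],
    )
    def test_worked_examples(self, days, expected):
        got = merge_episodes([_d(d) for d in days], 31)
        assert got == [_d(d) for d in expected]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            merge_episodes([_d(5), _d(1)], 31)

    def test_agrees_with_recursive_oracle_on_random_sets(self):
        rng = random.Random(99)
        for _ in range(2000):
            days = sorted(rng.sample(range(0, 400), rng.randint(0, 12)))
            lag = rng.randint(1, 60)
            got = merge_episodes([_d(d) for d in days], lag)
            assert got == [_d(d) for d in oracle_merge(days, lag)]

    def test_episode_spacing_and_coverage_invariants(self):
        rng = random.Random(7)
        for _ in range(300):
            days = sorted(rng.sample(range(0, 300), rng.randint(1, 10)))
            lag = rng.randint(1, 45)
            starts = merge_episodes([_d(d) for d in days], lag)
            gaps = [(b - a).days for a, b in zip(starts, starts[1:])]
            assert all(g >= lag for g in gaps)
            for d in days:
                assert any(0 <= (_d(d) - s).days < lag for s in starts)


MCRPC_CFG = shipped_config("mcrpc")


def _pca_record(met_days=(), res_days=(), index_day=0):
    pid = "T2"
    events = [ClaimsEvent(pid, _d(index_day), EventCategory.HOSPITAL_STAY, "C61",
                          "ICD-10", duration_days=2)]
    events += [
        ClaimsEvent(pid, _d(d), EventCategory.DISPENSING, "M05BA08", "ATC", quantity=1.0)
        for d in met_days
    ]
    events += [
        ClaimsEvent(pid, _d(d), EventCategory.DISPENSING, "L02BX03", "ATC", quantity=1.0)
        for d in res_days
    ]
    events.sort(key=lambda e: e.event_date)
    return PatientRecord(pid, 1945, Sex.MALE, _d(index_day), events)


class TestClassifyMCRPC:
    def test_no_indicators_is_non_met_hspc(self):
        assert classify_mcrpc(_pca_record(), MCRPC_CFG).label == "non_met_HSPC"

    def test_both_indicators_classify_at_later_date(self):
        call = classify_mcrpc(_pca_record(met_days=[100], res_days=[300]), MCRPC_CFG)
        assert call.label == "mCRPC"
        assert call.episode_start == _d(300)
        assert call.indicator_dates == {"metastasis": _d(100), "resistance": _d(300)}

    def test_resistance_only(self):
        assert classify_mcrpc(_pca_record(res_days=[50]), MCRPC_CFG).label == "non_met_CRPC"

    def test_metastasis_only(self):
        assert classify_mcrpc(_pca_record(met_days=[50]), MCRPC_CFG).label == "met_HSPC"

    def test_random_records_match_earliest_date_oracle(self):
        rng = random.Random(5)
        for _ in range(300):
            met = sorted(rng.sample(range(0, 400), rng.randint(0, 4)))
            res = sorted(rng.sample(range(0, 400), rng.randint(0, 4)))
            call = classify_mcrpc(_pca_record(met, res), MCRPC_CFG)
            if met and res:
                assert call.label == "mCRPC"
                assert call.episode_start == _d(max(min(met), min(res)))
            elif met:
                assert (call.label, call.episode_start) == ("met_HSPC", _d(min(met)))
            elif res:
                assert (call.label, call.episode_start) == ("non_met_CRPC", _d(min(res)))
            else:
                assert call.label == "non_met_HSPC"


class TestRunAlgorithm:
    def test_signal_free_cohort_is_all_noncases(self):
        from rehrval.simulate import MSCohortParams, simulate_ms_cohort
        params = MSCohortParams(n_patients=30, relapse_rate_per_year=0.0,
                                noise_steroid_rate_per_year=0.0,
                                noise_hospital_rate_per_year=0.0, seed=8)
        records, _ = simulate_ms_cohort(params)
        _, flags = run_algorithm(records, shipped_config("ms_relapse"), "ms")
        assert not any(flags.values())

    def test_noiseless_cohort_flags_equal_truth(self, ms_cohort_noiseless):
        records, truths = ms_cohort_noiseless
        _, flags = run_algorithm(records, shipped_config("ms_relapse"), "ms")
        truth = {t.patient_id: t.is_case for t in truths}
        assert flags == truth

    def test_jitter_free_cohort_recovers_true_episodes_exactly(self):
        from rehrval.simulate import MSCohortParams, simulate_ms_cohort
        params = MSCohortParams(
            n_patients=120, p_steroid_given_relapse=1.0, p_hospital_given_relapse=1.0,
            noise_steroid_rate_per_year=0.0, noise_hospital_rate_per_year=0.0,
            jitter_days_max=0, seed=23,
        )
        records, truths = simulate_ms_cohort(params)
        cfg = shipped_config("ms_relapse")
        calls, _ = run_algorithm(records, cfg, "ms")
        starts = {}
        for c in calls:
            starts.setdefault(c.patient_id, []).append(c.episode_start)
        for t in truths:
            expected = merge_episodes(sorted(t.true_relapse_dates),
                                      cfg.min_independence_lag_days)
            assert starts.get(t.patient_id, []) == expected

    def test_lag_boundary_gives_two_episodes(self):
        rec = _record(steroid_days=[0, 31], stay_days=[0, 31])
        calls, flags = run_algorithm([rec], shipped_config("ms_relapse"), "ms")
        assert len(calls) == 2
        assert flags["T1"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            run_algorithm([], shipped_config("ms_relapse"), "nope")

    def test_mode_config_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            run_algorithm([], shipped_config("mcrpc"), "ms")


class TestConfigs:
    def test_codeset_prefix_semantics(self):
        cs = CodeSet("ms", "ICD-10", frozenset({"G35", "H46"}))
        assert cs.matches("G35") and cs.matches("G35.0") and cs.matches("g35")
        assert not cs.matches("G36")

    def test_empty_codeset_rejected(self):
        with pytest.raises(ConfigError):
            CodeSet("x", "ATC", frozenset())

    def test_shipped_ms_config_matches_published_rule(self):
        cfg = shipped_config("ms_relapse")
        assert cfg.min_independence_lag_days == 31
        assert cfg.steroid_codes.matches("H02AB04")
        assert cfg.ms_diagnosis_codes.matches("G35")

    def test_bad_lag_rejected(self):
        with pytest.raises(ConfigError):
            RelapseAlgoConfig(MS_CFG.steroid_codes, MS_CFG.ms_diagnosis_codes,
                              min_independence_lag_days=0)

    def test_mcrpc_requires_both_indicator_lists(self):
        trig = IndicatorTrigger(EventCategory.DISPENSING,
                                CodeSet("x", "ATC", frozenset({"M05BA08"})))
        with pytest.raises(ConfigError):
            MCRPCAlgoConfig(metastasis_indicator=(trig,), resistance_indicator=())
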