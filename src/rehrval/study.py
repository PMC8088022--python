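"""Validation-sample assembly, blinded double review, and scoring.

The study design mirrors intra-database validation of a case-identifying
algorithm: draw a random sample of algorithm-identified cases and
non-cases (optionally stratifying the non-cases), have two independent
reviewers adjudicate each anonymized record as true case / true
non-case, resolve disagreements by committee consensus, and only then
unblind to cross the verdicts with the algorithm flags in a 2x2 table.

The adjudication simulator stands in for the expert committee: each
reviewer confirms a true case with probability ``sensitivity`` and
rejects a true non-case with probability ``specificity``.  Its inputs
are review ids and ground truth only — algorithm flags live in a
separate unblinded ledger, so blinding is structural, not procedural.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .stats import ConfusionTable


class SamplingError(ValueError):
    pass


@dataclass(frozen=True)
class SamplingPlan:
    """How many algorithm-positives and -negatives to review.

    ``noncase_strata`` optionally splits the non-case quota over labelled
    strata (e.g. 34/33/33 over the three non-mCRPC states).
    """

    n_cases: int = 100
    n_noncases: int = 100
    noncase_strata: tuple[tuple[str, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_noncases <= 0:
            raise SamplingError("sample sizes must be positive")
        if self.noncase_strata is not None:
            total = sum(n for _, n in self.noncase_strata)
            if total != self.n_noncases:
                raise SamplingError(
                    f"stratum sizes sum to {total}, expected n_noncases={self.n_noncases}"
                )


@dataclass(frozen=True)
class ReviewerProfile:
    """An imperfect reviewer: P(confirm | case) and P(reject | non-case)."""

    sensitivity: float = 1.0
    specificity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SamplingError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class AdjudicationResult:
    review_id: str
    verdict: Literal["true_case", "true_noncase"]
    reviewer_verdicts: tuple[bool, bool]
    consensus_used: bool


def sample_validation_set(
    flags: Mapping[str, bool],
    plan: SamplingPlan,
    strata: Mapping[str, str] | None = None,
) -> list[str]:
    """Draw the validation sample of patient ids from the algorithm flags.

    Simple random sampling without replacement, independently within the
    case group and each non-case stratum; deterministic given the plan
    seed.  Raises naming the short group/stratum if eligibility falls
    below quota.
    """
    rng = np.random.default_rng(plan.seed)
    cases = sorted(pid for pid, f in flags.items() if f)
    noncases = sorted(pid for pid, f in flags.items() if not f)
    if len(cases) < plan.n_cases:
        raise SamplingError(
            f"need {plan.n_cases} algorithm cases, only {len(cases)} eligible"
        )
    chosen = list(rng.choice(cases, size=plan.n_cases, replace=False))
    if plan.noncase_strata is None:
        if len(noncases) < plan.n_noncases:
            raise SamplingError(
                f"need {plan.n_noncases} algorithm non-cases, only {len(noncases)} eligible"
            )
        chosen += list(rng.choice(noncases, size=plan.n_noncases, replace=False))
    else:
        if strata is None:
            raise SamplingError("plan has noncase_strata but no stratum labels given")
        for label, n in plan.noncase_strata:
            pool = [pid for pid in noncases if strata.get(pid) == label]
            if len(pool) < n:
                raise SamplingError(
                    f"stratum {label!r}: need {n} non-cases, only {len(pool)} eligible"
                )
            chosen += list(rng.choice(pool, size=n, replace=False))
    return [str(p) for p in chosen]


ConsensusRule = Literal["truth", "first_reviewer", "random"]


def simulate_adjudication(
    sample: Sequence[str],
    ground_truth: Mapping[str, bool],
    reviewers: tuple[ReviewerProfile, ReviewerProfile] = (ReviewerProfile(), ReviewerProfile()),
    consensus_rule: ConsensusRule = "truth",
    seed: int = 0,
) -> list[AdjudicationResult]:
    """Simulate the blinded double review with committee consensus.

    ``sample`` holds review ids (or any ids); ``ground_truth`` maps each
    to true case status.  Reviewer verdicts are independent Bernoulli
    draws given truth and profile; on disagreement the consensus rule
    applies (default ``truth``: the committee discussion reaches the
    correct status).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rid in sample:
        if rid not in ground_truth:
            raise KeyError(f"no ground truth for {rid!r}")
        truth = bool(ground_truth[rid])
        verdicts = []
        for rev in reviewers:
            p_correct = rev.sensitivity if truth else rev.specificity
            correct = rng.random() < p_correct
            verdicts.append(truth if correct else not truth)
        v1, v2 = verdicts
        if v1 == v2:
            final, consensus = v1, False
        else:
            consensus = True
            if consensus_rule == "truth":
                final = truth
            elif consensus_rule == "first_reviewer":
                final = v1
            elif consensus_rule == "random":
                final = bool(rng.integers(2))
            else:
                raise ValueError(f"unknown consensus rule {consensus_rule!r}")
        out.append(
            AdjudicationResult(
                review_id=rid,
                verdict="true_case" if final else "true_noncase",
                reviewer_verdicts=(v1, v2),
                consensus_used=consensus,
            )
        )
    return out


def score_against_algorithm(
    adjudications: Sequence[AdjudicationResult],
    algorithm_flags: Mapping[str, bool],
    strata: Mapping[str, str] | None = None,
) -> ConfusionTable | dict[str, ConfusionTable]:
    """Cross expert verdicts with the unblinded algorithm flags.

    TP: algorithm case confirmed; FP: algorithm case rejected; FN:
    algorithm non-case adjudicated a true case; TN: algorithm non-case
    confirmed.  With ``strata`` (labels for algorithm non-cases), also
    returns one table per stratum under their labels plus ``"overall"``.
    """
    tp = fp = tn = fn = 0
    per_stratum: dict[str, list[int]] = {}
    for adj in adjudications:
        if adj.review_id not in algorithm_flags:
            raise KeyError(f"{adj.review_id!r} missing from the unblinded ledger")
        algo = bool(algorithm_flags[adj.review_id])
        true_case = adj.verdict == "true_case"
        if algo and true_case:
            tp += 1
        elif algo:
            fp += 1
        elif true_case:
            fn += 1
        else:
            tn += 1
        if strata is not None and not algo:
            label = strata.get(adj.review_id, "?")
            cell = per_stratum.setdefault(label, [0, 0])  # [fn, tn]
            cell[0 if true_case else 1] += 1
    overall = ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)
    if strata is None:
        return overall
    tables = {
        label: ConfusionTable(tp=0, fp=0, fn=c[0], tn=c[1])
        for label, c in sorted(per_stratum.items())
    }
    tables["overall"] = overall
    return tables
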