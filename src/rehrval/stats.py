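"""Diagnostic-performance estimators for validation studies.

Implements the standard machinery for scoring a case-identifying
algorithm against expert adjudication:

* PPV = TP/(TP+FP) and NPV = TN/(TN+FN) from a 2x2 table;
* Wald (normal-approximation) confidence intervals
  ``p ± z_{1-alpha/2} * sqrt(p(1-p)/n)`` with n the number of
  algorithm-positive (resp. -negative) reviewed patients, clamped to
  [0, 1];
* a single stratum-weighted NPV: the per-stratum false-negative rates
  are reweighted by each stratum's share of the non-case source
  population before forming the table margin;
* derivation of sensitivity and specificity from PPV, NPV, prevalence
  and (optionally) the algorithm positivity rate;
* precision planning: the Wald half-width at a given n, and the
  smallest n achieving a target half-width.

Reported percentages are rounded to the nearest integer (half away from
zero) and CI bounds are rounded then clamped to [0, 100]; a degenerate
estimate of exactly 0 or 1 is reported without an interval.  Statistics
with a zero denominator are returned as an explicit ``None``, never
silently as 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm


class EstimationError(ValueError):
    pass


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round_pct(p: float) -> int:
    """Proportion -> integer percent, half away from zero, clamped."""
    return min(100, max(0, _round_half_up(p * 100.0)))


@dataclass(frozen=True)
class ConfusionTable:
    """Adjudication-vs-algorithm counts.

    Counts may be fractional: stratum weighting produces non-integer
    false negatives (e.g. FN = 1.23).
    """

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EstimationError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> float:
        return self.tp + self.fp

    @property
    def n_negative(self) -> float:
        return self.tn + self.fn

    @property
    def total(self) -> float:
        return self.n_positive + self.n_negative


def predictive_values(table: ConfusionTable) -> tuple[float | None, float | None]:
    """(PPV, NPV); either is None when its denominator is zero."""
    ppv = table.tp / table.n_positive if table.n_positive > 0 else None
    npv = table.tn / table.n_negative if table.n_negative > 0 else None
    return ppv, npv


def z_value(alpha: float) -> float:
    """Standard-normal quantile z_{1-alpha/2} (1.96 at alpha = 0.05)."""
    if not 0.0 < alpha < 1.0:
        raise EstimationError("alpha must be in (0, 1)")
    return float(norm.ppf(1.0 - alpha / 2.0))


def precision_halfwidth(p: float, n: float, alpha: float = 0.05) -> float:
    """Wald half-width z * sqrt(p(1-p)/n)."""
    if n <= 0:
        raise EstimationError("n must be positive")
    if not 0.0 <= p <= 1.0:
        raise EstimationError("p must be in [0, 1]")
    return z_value(alpha) * math.sqrt(p * (1.0 - p) / n)


def wald_ci(p: float, n: float, alpha: float = 0.05) -> tuple[float, float]:
    """Wald interval for a proportion, clamped to [0, 1]."""
    half = precision_halfwidth(p, n, alpha)
    return (max(0.0, p - half), min(1.0, p + half))


def required_n(p: float, target_halfwidth: float, alpha: float = 0.05) -> int:
    """Smallest integer n with Wald half-width <= target at proportion p."""
    if target_halfwidth <= 0:
        raise EstimationError("target half-width must be positive")
    if p in (0.0, 1.0) or target_halfwidth >= 1.0:
        return 1
    z = z_value(alpha)
    n = max(1, math.ceil(z * z * p * (1.0 - p) / target_halfwidth**2))
    while n > 1 and precision_halfwidth(p, n - 1, alpha) <= target_halfwidth:
        n -= 1
    while precision_halfwidth(p, n, alpha) > target_halfwidth:
        n += 1
    return n


# --- stratum-weighted NPV ----------------------------------------------

@dataclass(frozen=True)
class StratumWeight:
    """One non-case stratum's sample result and population share."""

    label: str
    sampled_n: float
    observed_fn: float
    population_share: float

    def __post_init__(self) -> None:
        if self.sampled_n <= 0:
            raise EstimationError(f"stratum {self.label!r}: sampled_n must be positive")
        if not 0 <= self.observed_fn <= self.sampled_n:
            raise EstimationError(f"stratum {self.label!r}: observed_fn must be in [0, n]")
        if not 0.0 <= self.population_share <= 1.0:
            raise EstimationError(f"stratum {self.label!r}: share must be in [0, 1]")


@dataclass(frozen=True)
class WeightedNPVResult:
    weighted_fn: float
    weighted_tn: float
    npv: float
    ci: tuple[float, float]


def weighted_npv(
    strata: Sequence[StratumWeight],
    reporting_n: float,
    alpha: float = 0.05,
) -> WeightedNPVResult:
    """Single NPV over a stratified non-case sample.

    The false-negative rate is the share-weighted mean of per-stratum
    rates; weighted FN = rate x reporting_n, weighted TN the complement,
    and the CI uses the ordinary Wald formula with n = reporting_n.
    """
    if not strata:
        raise EstimationError("at least one stratum required")
    if reporting_n <= 0:
        raise EstimationError("reporting_n must be positive")
    total_share = sum(s.population_share for s in strata)
    if abs(total_share - 1.0) > 1e-9:
        raise EstimationError(f"population shares sum to {total_share}, expected 1")
    fn_rate = sum(s.population_share * s.observed_fn / s.sampled_n for s in strata)
    weighted_fn = fn_rate * reporting_n
    weighted_tn = reporting_n - weighted_fn
    npv = weighted_tn / reporting_n
    return WeightedNPVResult(
        weighted_fn=weighted_fn,
        weighted_tn=weighted_tn,
        npv=npv,
        ci=wald_ci(npv, reporting_n, alpha),
    )


# --- sensitivity / specificity from predictive values -------------------

@dataclass(frozen=True)
class DerivedAccuracy:
    sensitivity: float
    specificity: float
    prevalence: float
    positivity_rate: float


def derive_se_sp(
    ppv: float,
    npv: float,
    prevalence: float,
    positivity_rate: float | None = None,
) -> DerivedAccuracy:
    """Sensitivity and specificity from PPV, NPV and prevalence.

    With q the algorithm positivity rate (supplied, or solved from
    ``q = (p - (1-NPV)) / (PPV - (1-NPV))``, which requires
    PPV + NPV > 1):  Se = PPV*q/p and Sp = NPV*(1-q)/(1-p), clamped to
    [0, 1].  These are the standard identities obtained by reading the
    population 2x2 table in the other direction.
    """
    for name, v in (("ppv", ppv), ("npv", npv), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise EstimationError(f"{name} must be in [0, 1]")
    p = prevalence
    if p in (0.0, 1.0):
        raise EstimationError("prevalence must be strictly between 0 and 1")
    q = positivity_rate
    if q is None:
        denom = ppv - (1.0 - npv)
        if denom <= 0:
            raise EstimationError("PPV + NPV must exceed 1 to solve for the positivity rate")
        q = (p - (1.0 - npv)) / denom
    if not 0.0 <= q <= 1.0:
        raise EstimationError(f"positivity rate {q} outside [0, 1]")
    se = min(1.0, max(0.0, ppv * q / p))
    sp = min(1.0, max(0.0, npv * (1.0 - q) / (1.0 - p)))
    return DerivedAccuracy(sensitivity=se, specificity=sp, prevalence=p, positivity_rate=q)


# --- reporting ----------------------------------------------------------

@dataclass(frozen=True)
class PerformanceEstimate:
    """Point estimates, intervals, and their printed (rounded) forms."""

    table: ConfusionTable
    ppv: float | None
    npv: float | None
    ci_ppv: tuple[float, float] | None
    ci_npv: tuple[float, float] | None
    alpha: float = 0.05
    weighted: bool = False

    def _pct(self, v: float | None) -> int | None:
        return None if v is None else round_pct(v)

    @property
    def reported_ppv_pct(self) -> int | None:
        return self._pct(self.ppv)

    @property
    def reported_npv_pct(self) -> int | None:
        return self._pct(self.npv)

    @property
    def reported_ci_ppv_pct(self) -> tuple[int, int] | None:
        return None if self.ci_ppv is None else (round_pct(self.ci_ppv[0]), round_pct(self.ci_ppv[1]))

    @property
    def reported_ci_npv_pct(self) -> tuple[int, int] | None:
        return None if self.ci_npv is None else (round_pct(self.ci_npv[0]), round_pct(self.ci_npv[1]))


def estimate_performance(
    table: ConfusionTable, alpha: float = 0.05, weighted: bool = False
) -> PerformanceEstimate:
    """PPV/NPV with Wald CIs from a (possibly weighted) 2x2 table.

    A degenerate proportion (exactly 0 or 1) carries no interval,
    matching how a 100% predictive value is conventionally reported.
    """
    ppv, npv = predictive_values(table)

    def ci(p: float | None, n: float) -> tuple[float, float] | None:
        if p is None or p in (0.0, 1.0):
            return None
        return wald_ci(p, n, alpha)

    return PerformanceEstimate(
        table=table,
        ppv=ppv,
        npv=npv,
        ci_ppv=ci(ppv, table.n_positive),
        ci_npv=ci(npv, table.n_negative),
        alpha=alpha,
        weighted=weighted,
    )


def _fmt_count(x: float) -> str:
    return f"{x:g}"


def _fmt_stat(name: str, pct: int | None, ci: tuple[int, int] | None, level: int) -> str:
    if pct is None:
        return f"{name} undefined"
    if ci is None:
        return f"{name} = {pct}%"
    return f"{name} = {pct}% ({level}%CI = [{ci[0]}; {ci[1]}])"


def report(estimate: PerformanceEstimate, case_label: str = "Case") -> str:
    """Render the 2x2 table and estimates in the conventional layout."""
    t = estimate.table
    level = round(100 * (1 - estimate.alpha))
    ppv_line = _fmt_stat("PPV", estimate.reported_ppv_pct, estimate.reported_ci_ppv_pct, level)
    npv_line = _fmt_stat("NPV", estimate.reported_npv_pct, estimate.reported_ci_npv_pct, level)
    rows = [
        ["", "Validation committee", "", ""],
        ["Algorithm", f"{case_label} +", f"{case_label} -", "Total"],
        [f"{case_label} +", _fmt_count(t.tp), _fmt_count(t.fp), _fmt_count(t.n_positive)],
        [f"{case_label} -", _fmt_count(t.fn), _fmt_count(t.tn), _fmt_count(t.n_negative)],
        ["Total", _fmt_count(t.tp + t.fn), _fmt_count(t.fp + t.tn), _fmt_count(t.total)],
    ]
    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)) for r in rows]
    lines[2] += "  " + ppv_line
    lines[3] += "  " + npv_line
    return "\n".join(line.rstrip() for line in lines) + "\n"
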