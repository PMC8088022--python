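# Methods

## The problem

Case-identifying algorithms — deterministic rules over coded claims
events (drug dispensings, hospital discharge diagnoses, procedures,
long-term-disease registrations) — are the workhorse of
pharmacoepidemiology in nationwide claims databases such as the French
SNDS. Their diagnostic performance is normally assessed against an
external gold standard (medical charts, registries); when no external
source is accessible, an *intra-database* validation is possible: the
complete longitudinal claims stream of each sampled patient is rendered
as an anonymized **reconstituted electronic health record (rEHR)** and
adjudicated by clinical experts blinded to the algorithm's output, and
the algorithm is scored against the expert consensus. This package
implements that entire workflow — cohort simulation with planted truth,
the temporal rule engine, rEHR generation, the blinded review, and the
performance estimators — as composable, individually testable stages.

## Estimators

Let TP/FP (resp. TN/FN) be the algorithm-positive (resp. -negative)
reviewed patients confirmed/overturned by the committee:

    PPV = TP / (TP + FP)        NPV = TN / (TN + FN)

with Wald (normal-approximation) confidence intervals

    p ± z_{1−α/2} · sqrt( p(1−p) / n ),

n being the number of algorithm-positive (for PPV) or -negative (for
NPV) reviewed patients and z_{1−α/2} = 1.96 at α = 0.05. Intervals are
clamped to [0, 1]. Reported percentages round to the nearest integer,
half away from zero, CI bounds rounding before clamping to [0, 100];
this rounding convention is what reproduces conventionally printed
bounds such as [93; 100] from a raw upper limit of 1.0036. A degenerate
estimate of exactly 0 or 1 is reported without an interval — the Wald
interval is a point there and printing it would suggest spurious
certainty. Zero-denominator statistics are returned as an explicit
`None`, never silently as 0 or 1.

**Stratum-weighted NPV.** When the non-case sample is drawn from
strata (e.g. the three non-mCRPC prostate-cancer states sampled
34/33/33), a single NPV for the whole non-case population weights each
stratum's observed false-negative *rate* by that stratum's share of the
non-case source population:

    FN_w = reporting_n · Σ_s share_s · (fn_s / n_s),    TN_w = reporting_n − FN_w.

The CI uses the plain Wald formula with n = `reporting_n` (the
algorithm-negative margin of the reporting table), not an
effective-sample-size correction; population shares and `reporting_n`
are explicit inputs because they come from the source cohort, not from
the validation sample itself.

**Sensitivity and specificity from predictive values.** Given
prevalence p and positivity rate q (the population fraction flagged by
the algorithm), reading the population 2×2 table backwards gives

    q = (p − (1−NPV)) / (PPV − (1−NPV))   (if q is not supplied; needs PPV+NPV > 1)
    Se = PPV·q/p,     Sp = NPV·(1−q)/(1−p),

clamped to [0, 1]. q can be supplied directly because, in practice, the
externally observed positivity rate of the full source cohort can
differ from the one implied by the validation sample's PPV/NPV — the
derivation is exact only when all four inputs describe the same
population, which the tests verify on forward-constructed 2×2 tables.

**Precision planning.** `precision_halfwidth(p, n, α)` is the Wald
half-width; `required_n` inverts it to the smallest integer n meeting a
target half-width (closed-form start, then exact integer search).
Reviewing 100 patients per group bounds the margin of error below 10
points for any proportion, at ≤ 7 points for proportions ≥ 0.8 and
≤ 6 points at ≥ 0.9; 200 per group improves these to ≤ 6 and ≤ 4.

Wald intervals under-cover for extreme proportions at moderate n; the
test suite measures empirical coverage ≈ 0.93–0.95 at p = 0.9, n = 100
and the package exposes α rather than promising exact coverage. The
Wald form is kept because it is the estimator this validation design
actually uses; a Clopper–Pearson alternative was considered and not
shipped (fidelity of the reported numbers first).

## The rule engine

Algorithms are declarative: named code sets (prefix matching, the ICD-10
convention — `G35` matches `G35.0`), a signal rule, and windows,
loadable from YAML.

**MS relapse.** A relapse signal combines a high-dose corticosteroid
dispensing (methylprednisolone ATC H02AB04, betamethasone H02AB01) with
an MS-related discharge diagnosis (ICD-10 G35, G36, G04, H46). Because
the exact published combination logic and the dose threshold defining
"high dose" are not fully specified in public sources, the rule is a
config knob: `either`, `steroid_only`, or the shipped default
`require_both_within_window` (± 30 days; the signal dates at the
earlier of the pair). Signals are merged into independent relapse
episodes with a minimum lag of 31 days: a greedy left-to-right scan in
which a signal opens a new episode iff it falls ≥ 31 days after the
start of the current episode. Anchoring on the episode *start* (not the
last absorbed signal) prevents unbounded chaining of closely spaced
treatments; the boundary is inclusive — signals exactly 31 days apart
are independent relapses. Only events on/after the index (inclusion)
date count; history is retained for configs that need lookback.

**mCRPC.** A two-indicator classifier: the earliest
metastasis-management event (bone-targeted agents, secondary-malignancy
stays, bone imaging / radiotherapy procedures) and the earliest
castration-resistance event (mCRPC-specific therapy dispensings). Both
present ⇒ mCRPC, classified at the *later* of the two dates (both
conditions must hold); one present ⇒ the corresponding intermediate
state (met_HSPC / non_met_CRPC); neither ⇒ non_met_HSPC. This is a
deliberately simplified, configurable analogue of the full published
prostate-cancer algorithm, which is out of scope.

## rEHR anonymization

Four irreversible transformations (each checked by tests):
review identifiers are truncated keyed BLAKE2b digests of the patient id
(unlinkable without the salt; the unblinding map is written to a
separate file that the adjudication step cannot receive — blinding by
construction); calendar dates become signed day delays from the
inclusion date (negative = history); locations are dropped; age appears
only as a class (5-year bins by default — the conventional claims-data
disclosure bucket; the width is configurable since no standard is
mandated). A leak scanner rejects any rendered document containing
ISO/slash dates, bare years, month-name dates, raw patient ids or
location tokens; the pipeline runs it on every document it writes.

## The synthetic-data generator

The generator emulates what the validation method needs from SNDS-like
data — per-patient dated, coded event streams whose *pattern* encodes a
planted disease status — not the SNDS's marginal frequencies, costs or
coding-audit behaviour.

*MS mode.* Cohort entry at a first disease-modifying-therapy dispensing
(mid-2015 – end-2017), 4.5 years of history, per-patient follow-up
uniform on 1–3.5 years. True relapse times are a homogeneous Poisson
process (default 0.45/year, a typical on-treatment annualized relapse
rate). Each relapse emits a steroid dispensing with probability 0.9
and an MS-coded stay with probability 0.85, each 0–3 days after onset
(dispensing follows onset; the jitter stays inside any ≥ 7-day
co-occurrence window). Noise: unrelated steroid dispensings
(0.05/year) and MS-coded monitoring stays (0.10/year), background GP
visits and monthly DMT refills for document realism. The emission
probabilities and noise rates are illustrative — no quantitative
care-pathway frequencies are published for this setting — and are the
dials for misclassification experiments.

*Prostate-cancer mode.* Diagnosis at entry (ICD-10 C61 stay + LTD
registration, androgen deprivation ongoing), then an optional metastasis
transition (p = 0.30) and an optional castration-resistance transition
(p = 0.50 given metastatic, 0.08 otherwise), each dated uniformly over
the 3-year follow-up; resistance may precede metastasis. Each state
emits its own Poisson stream of indicator events from its transition
date (2/year), so late transitions can emit nothing — the realistic
false-negative mechanism — while work-up bone imaging in non-metastatic
patients (0.05/year) is the false-positive mechanism.

All randomness flows from one seed through `SeedSequence.spawn`, one
child per patient, so cohorts are reproducible and per-patient streams
do not shift when the cohort grows.

What passing tests on these cohorts show is that the pipeline machinery
is correct *given* the generative assumptions; they cannot show that
the shipped code sets capture real French coding practice, that real
relapse care follows onset within days, or that experts behave like the
Bernoulli reviewer model.

## The simulated validation study

Sampling is simple random sampling without replacement, independently
within the case group and each non-case stratum. Each of two reviewers
confirms a true case with probability `sensitivity` and rejects a true
non-case with probability `specificity`, independently; on disagreement
the consensus rule applies — default `truth` (the committee discussion
reaches the correct status, the assumption implicit in treating
consensus adjudication as a gold standard), with `first_reviewer` and
`random` available to probe sensitivity of the estimates to imperfect
consensus. Review is at patient level (case / non-case status), not per
episode. With perfect reviewers the estimated PPV/NPV equal the
algorithm's sample predictive values exactly, and across repeated
studies their mean converges to the cohort-level predictive values
(unbiasedness of SRS proportions), which the test suite checks to
within 3 Monte-Carlo standard errors.

## Numerical and design choices

- Dates are ISO calendar days; claims carry no time of day. Same-day
  event order is preserved from the source file and algorithms are
  tested to be invariant to it.
- Duplicate claim rows are kept — claims legitimately repeat.
- Stage seeds in the pipeline are fixed offsets of the one top-level
  seed; the manifest (seeds, parameters, output digests) reproduces a
  run byte-for-byte.
- Problem sizes in the shipped tests and the reproduction script —
  cohorts of 300–900 patients, 200–500 replicate studies, 1,000
  leak-scanned documents, 10,000 randomized oracle comparisons — were
  chosen to hold Monte-Carlo error well below the tolerances being
  asserted while keeping a full run in the tens of seconds.

## Known limitations

- The reviewer model is Bernoulli-independent given truth; real experts
  correlate (shared training, shared ambiguous documents).
- The generator plants no deaths, no censoring beyond end of follow-up,
  and no coding drift over calendar time.
- The weighted-NPV interval ignores the variance contribution of
  weighting (by design, to match the reporting convention it
  implements).
- ICD-10 validation is a shape check (letter + 2 digits + optional
  subcode), not a terminology lookup.
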