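# rehrval

Intra-database validation of case-identifying algorithms in healthcare
claims data, using anonymized reconstituted electronic health records
(rEHRs).

Pharmacoepidemiology studies in claims databases (the French SNDS and
its peers) identify diseases and outcomes with *case-identifying
algorithms*: deterministic temporal rules over coded events — drug
dispensings, hospital discharge diagnoses, procedures, long-term-disease
registrations. When no external gold standard (charts, registries) is
accessible, the algorithm can be validated *inside* the database: render
each sampled patient's complete claims stream as an anonymized,
delay-indexed rEHR, have a committee of experts adjudicate true case /
true non-case status blinded to the algorithm's output, and score the
algorithm against the consensus. `rehrval` implements that workflow
end to end for methodologists who want to design, simulate, and analyze
such studies:

- **claims model & I/O** — typed event/patient records with a flat
  delimited interchange format;
- **synthetic cohorts** — SNDS-like event streams with planted ground
  truth (MS relapses; prostate-cancer state trajectories), so every
  stage is testable without any real data;
- **rule engine** — declarative algorithm configs: an MS-relapse
  detector (high-dose corticosteroid + MS discharge diagnosis, episodes
  merged under a 31-day independence lag) and a two-indicator
  metastatic castration-resistant prostate cancer (mCRPC) classifier;
- **rEHR builder** — keyed one-way review ids, dates → day delays,
  locations dropped, 5-year age classes, with a leak scanner;
- **validation study** — (stratified) random sampling, a simulated
  blinded double review with committee consensus, unblinded scoring;
- **performance statistics** — PPV/NPV with Wald 95% CIs,
  stratum-weighted NPV, sensitivity/specificity derived from predictive
  values and prevalence, and precision/sample-size planning.

The core estimators, for a reviewed 2×2 table (TP, FP, FN, TN):

    PPV = TP/(TP+FP),   NPV = TN/(TN+FN),
    CI:  p ± z_{1−α/2}·√(p(1−p)/n),  z = 1.96 at α = 0.05,

with n the algorithm-positive (PPV) or -negative (NPV) review count,
and a single stratum-weighted NPV obtained by reweighting per-stratum
false-negative rates by their population shares. See
[docs/methods.md](docs/methods.md) for the full model.

## Worked example

Score a validation study in which experts confirmed 99 of 104
algorithm-identified relapse cases and all 96 non-cases:

```python
from rehrval import ConfusionTable, estimate_performance, report

est = estimate_performance(ConfusionTable(tp=99, fp=5, tn=96, fn=0))
print(report(est, case_label="Relapse"))
```

prints

```
           Validation committee
Algorithm  Relapse +             Relapse -  Total
Relapse +  99                    5          104    PPV = 95% (95%CI = [91; 99])
Relapse -  0                     96         96     NPV = 100%
Total      99                    101        200
```

i.e. a positive predictive value of 95% — 95% of algorithm-flagged
patients are true cases, with Wald interval [91; 99] — and a negative
predictive value of 100%, reported without an interval because the
estimate is degenerate. The same layout covers weighted tables: feeding
`ConfusionTable(tp=90, fp=3, tn=105.77, fn=1.23)` (fractional counts
from stratum weighting over 107 algorithm-negatives) reports
`PPV = 97% (95%CI = [93; 100])` and `NPV = 99% (95%CI = [97; 100])`.

The same works from the shell, and the whole pipeline
(simulate → run-algo → build-rehr → validate → estimate) runs from one
config:

```sh
rehrval simulate ms --n 500 --seed 7 --out cohort/
rehrval run-algo --events cohort/events.csv --patients cohort/patients.csv \
        --mode ms --out calls.csv
rehrval pipeline --config study.yaml --seed 7 --out out/
```

Each stage writes plain CSV/JSON, and the pipeline manifest (seeds,
parameters, output digests) makes a run byte-for-byte reproducible.

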