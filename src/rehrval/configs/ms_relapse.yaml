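# Relapse identification in multiple sclerosis: high-dose corticosteroid
# dispensing combined with an MS-related hospital discharge diagnosis;
# signals < 31 days after the current episode start are the same relapse.
algorithm: ms_relapse
steroid_codes:
  system: ATC
  codes: [H02AB04, H02AB01]   # methylprednisolone, betamethasone
ms_diagnosis_codes:
  system: ICD-10
  codes: [G35, G36, G04, H46] # MS, demyelination, encephalitis/myelitis, optic neuritis
signal_rule: require_both_within_window
co_occurrence_window_days: 30
min_independence_lag_days: 31
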