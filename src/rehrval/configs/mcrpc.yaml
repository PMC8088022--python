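# Two-indicator mCRPC classifier: metastasis-management indicator AND
# castration-resistance indicator; classification date = later of the two.
algorithm: mcrpc
metastasis_indicator:
  - category: dispensing
    system: ATC
    codes: [M05BA08, M05BX04]        # zoledronic acid, denosumab
  - category: hospital_stay
    system: ICD-10
    codes: [C79]                     # secondary malignant neoplasm
  - category: procedure
    system: CCAM
    codes: [PAQK007, ZZNL065]        # bone scintigraphy, radiotherapy
resistance_indicator:
  - category: dispensing
    system: ATC
    codes: [L02BX03, L02BB04, L01CD04, L01CD02]  # abiraterone, enzalutamide, cabazitaxel, docetaxel
classification_date_rule: max_of_indicators
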