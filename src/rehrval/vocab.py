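"""Shared code vocabulary for the shipped algorithms and the simulator.

One fixed dictionary is the single source of truth: the synthetic-cohort
generator emits only these codes (plus declared noise codes), and the
shipped algorithm configs consume the same sets.  Labels feed the rEHR
renderer.
"""

from __future__ import annotations

# --- multiple sclerosis -------------------------------------------------
# High-dose corticosteroids used for relapse treatment (ATC).
STEROID_CODES = ("H02AB04", "H02AB01")  # methylprednisolone, betamethasone
# MS-related hospital discharge diagnoses (ICD-10 prefixes): multiple
# sclerosis, other acute demyelination, encephalitis/myelitis/
# encephalomyelitis, optic neuritis.
MS_DIAGNOSIS_PREFIXES = ("G35", "G36", "G04", "H46")
MS_DRUG_CODE = "N07XX09"  # dimethyl fumarate (cohort-entry dispensing)

# --- prostate cancer ----------------------------------------------------
PCA_DIAGNOSIS_CODE = "C61"  # prostate cancer (hospital/LTD)
ADT_CODES = ("L02AE02", "L02AE03")  # leuprorelin, goserelin (androgen deprivation)
# Metastasis-management indicator: bone-targeted agents, metastatic-site
# diagnoses, bone imaging / radiotherapy procedures.
MET_DISPENSING_CODES = ("M05BA08", "M05BX04")  # zoledronic acid, denosumab
MET_DIAGNOSIS_PREFIXES = ("C79",)  # secondary malignant neoplasm
MET_PROCEDURE_CODES = ("PAQK007", "ZZNL065")  # bone scintigraphy, radiotherapy session
# Castration-resistance indicator: mCRPC-specific life-extending therapies.
CRPC_DISPENSING_CODES = ("L02BX03", "L02BB04", "L01CD04", "L01CD02")
# abiraterone, enzalutamide, cabazitaxel, docetaxel

# --- background / noise -------------------------------------------------
NOISE_DISPENSING_CODES = ("N02BE01", "J01CA04", "C10AA05")  # paracetamol, amoxicillin, atorvastatin
NOISE_DIAGNOSIS_CODES = ("S72.0", "K35.8", "J18.9")  # fracture, appendicitis, pneumonia
VISIT_CODE_GP = "CS"  # consultation
VISIT_CODE_NEURO = "CNP"  # specialist consultation

CODE_LABELS: dict[str, str] = {
    "H02AB04": "methylprednisolone, high dose",
    "H02AB01": "betamethasone, high dose",
    "N07XX09": "dimethyl fumarate",
    "G35": "multiple sclerosis",
    "G36.9": "acute demyelination of CNS",
    "G04.9": "encephalitis / myelitis / encephalomyelitis",
    "H46": "optic neuritis",
    "C61": "malignant neoplasm of prostate",
    "L02AE02": "leuprorelin",
    "L02AE03": "goserelin",
    "M05BA08": "zoledronic acid",
    "M05BX04": "denosumab",
    "C79.5": "secondary malignant neoplasm of bone",
    "PAQK007": "bone scintigraphy",
    "ZZNL065": "external-beam radiotherapy session",
    "L02BX03": "abiraterone",
    "L02BB04": "enzalutamide",
    "L01CD04": "cabazitaxel",
    "L01CD02": "docetaxel",
    "N02BE01": "paracetamol",
    "J01CA04": "amoxicillin",
    "C10AA05": "atorvastatin",
    "S72.0": "fracture of neck of femur",
    "K35.8": "acute appendicitis",
    "J18.9": "pneumonia, unspecified",
    "CS": "medical visit",
    "CNP": "specialist visit",
}
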