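"""Bundled toy code vocabularies.

A deliberately small ICD -> phecode map (~30 ICD-9/10 codes, 12 phecodes
across the disease groups the scans exercise) and a sleep-relevant code
classification (insomnia / breathing / other sleep disorder diagnoses plus
sleep-affecting medications).  Real analyses should pass their own map in
the same column layout; these fixtures exist so the synthetic cohort and the
test suite are self-contained.
"""

from __future__ import annotations

import pandas as pd

MENTAL = "mental disorders"
METABOLIC = "endocrine/metabolic"
CIRCULATORY = "circulatory system"
SLEEP = "sleep disorders"

# (icd_version, icd_code, phecode_id, phecode_label, disease_group)
_PHECODE_ROWS = [
    (10, "F32.9",  "296.2",  "Depression", MENTAL),
    (10, "F33.1",  "296.2",  "Depression", MENTAL),
    (9,  "311",    "296.2",  "Depression", MENTAL),
    (10, "F33.1",  "296.22", "Major depressive disorder", MENTAL),
    (10, "F33.2",  "296.22", "Major depressive disorder", MENTAL),
    (9,  "296.30", "296.22", "Major depressive disorder", MENTAL),
    (10, "F41.1",  "300.1",  "Anxiety disorder", MENTAL),
    (10, "F41.9",  "300.1",  "Anxiety disorder", MENTAL),
    (9,  "300.00", "300.1",  "Anxiety disorder", MENTAL),
    (10, "F39",    "296",    "Mood disorders", MENTAL),
    (9,  "296.90", "296",    "Mood disorders", MENTAL),
    (10, "F43.20", "309",    "Adjustment reaction", MENTAL),
    (9,  "309.9",  "309",    "Adjustment reaction", MENTAL),
    (10, "F17.210", "318",   "Tobacco use disorder", MENTAL),
    (9,  "305.1",  "318",    "Tobacco use disorder", MENTAL),
    (10, "E66.9",  "278.1",  "Obesity", METABOLIC),
    (10, "E66.01", "278.1",  "Obesity", METABOLIC),
    (9,  "278.00", "278.1",  "Obesity", METABOLIC),
    (10, "E11.9",  "250.2",  "Type 2 diabetes", METABOLIC),
    (9,  "250.00", "250.2",  "Type 2 diabetes", METABOLIC),
    (10, "I10",    "401.1",  "Essential hypertension", CIRCULATORY),
    (9,  "401.9",  "401.1",  "Essential hypertension", CIRCULATORY),
    (10, "G47.33", "327.3",  "Sleep apnea", SLEEP),
    (9,  "327.23", "327.3",  "Sleep apnea", SLEEP),
    (9,  "780.57", "327.3",  "Sleep apnea", SLEEP),
    (10, "G47.00", "327.4",  "Insomnia", SLEEP),
    (10, "F51.01", "327.4",  "Insomnia", SLEEP),
    (9,  "780.52", "327.4",  "Insomnia", SLEEP),
    (10, "G25.81", "327.7",  "Restless legs syndrome", SLEEP),
    (10, "G47.20", "327.6",  "Circadian rhythm sleep disorder", SLEEP),
    (9,  "307.45", "327.6",  "Circadian rhythm sleep disorder", SLEEP),
]

# (code_type, code, category) -- the Sleep Lifestyle Index's EHR inputs
_CLASSIFICATION_ROWS = [
    ("icd10", "G47.00",  "insomnia_disorder"),
    ("icd10", "F51.01",  "insomnia_disorder"),
    ("icd9",  "780.52",  "insomnia_disorder"),
    ("icd9",  "307.42",  "insomnia_disorder"),
    ("icd10", "G47.33",  "breathing_disorder"),
    ("icd9",  "327.23",  "breathing_disorder"),
    ("icd9",  "780.57",  "breathing_disorder"),
    ("icd10", "G25.81",  "other_sleep_disorder"),
    ("icd10", "G47.20",  "other_sleep_disorder"),
    ("icd9",  "307.45",  "other_sleep_disorder"),
    ("med",   "ZOLPIDEM",   "sleep_medication"),
    ("med",   "TEMAZEPAM",  "sleep_medication"),
    ("med",   "TRAZODONE",  "sleep_medication"),
    ("med",   "LORAZEPAM",  "sleep_medication"),
    ("med",   "MELATONIN",  "sleep_medication"),
]


def toy_phecode_map() -> pd.DataFrame:
    """The bundled ICD -> phecode map as a DataFrame."""
    return pd.DataFrame(_PHECODE_ROWS, columns=[
        "icd_version", "icd_code", "phecode_id", "phecode_label", "disease_group"])


def toy_sleep_classification() -> pd.DataFrame:
    """The bundled sleep-relevant code classification as a DataFrame."""
    return pd.DataFrame(_CLASSIFICATION_ROWS, columns=["code_type", "code", "category"])


def phecode_groups(phecode_map: pd.DataFrame) -> pd.DataFrame:
    """Unique (phecode_id, phecode_label, disease_group) lookup from a map."""
    return (phecode_map[["phecode_id", "phecode_label", "disease_group"]]
            .drop_duplicates("phecode_id").reset_index(drop=True))
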