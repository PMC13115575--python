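"""Reference cohort metadata for the 30-case vitreous-humor PMI study.

Published case-level metadata of the cohort this methodology was developed
on: 20 hospital deaths with documented PMI (24.8-97.6 h) and 10 cases with
only estimated PMI (9 scene deaths plus one refrigerated hospital death whose
chronological PMI, 179.28 h, is decoupled from its biochemical state).  The
spectra themselves are not redistributable; these records support cohort
bookkeeping, variant definitions and worked examples.
"""

from __future__ import annotations

from .spectra import SampleRecord

__all__ = ["reference_cohort"]

_KNOWN = [
    # sample, case, pmi_h, age, sex, cause of death, confounder flag
    ("172", "172/2025", 24.8, 73, "F", "thermal burns", ""),
    ("490", "490/2024", 26.67, 67, "M", "thermal burns", "clinical"),
    ("371", "371/2024", 29.25, 72, "M", "poisoning", ""),
    ("152", "152/2025", 31.83, 78, "M", "traumatic brain injury, chronic subdural hematoma", ""),
    ("484", "484/2025", 40.5, 79, "M", "traumatic brain injury", ""),
    ("1148", "1148/2024", 43.58, 46, "M", "traumatic brain injury", ""),
    ("1400", "1400/2024", 43.83, 51, "M", "traumatic brain injury", ""),
    ("718", "718/2024", 46.25, 50, "M", "head trauma, subdural hematoma surgery", "clinical"),
    ("1242", "1242/2024", 48.73, 57, "M", "epilepsy seizure", ""),
    ("455", "455/2025", 48.97, 49, "M", "tonsil carcinoma", ""),
    ("645", "645/2024", 53.42, 65, "M", "traumatic brain injury", ""),
    ("1139", "1139/2024", 55.98, 71, "M", "cervical spine injury", ""),
    ("1285", "1285/2024", 64.87, 90, "F", "septic shock, infected leg hematoma", ""),
    ("317", "317/2024", 73.33, 75, "M", "subdural hematoma, septic shock", ""),
    ("482", "482/2025", 76.08, 71, "M", "septic shock", ""),
    ("1478", "1478/2024", 82.83, 64, "M", "traumatic brain injury", ""),
    ("597", "597/2024", 87.25, 88, "M", "traumatic brain injury", ""),
    ("332", "332/2024", 90.5, 48, "M", "meningeal hemorrhage", ""),
    ("16", "16/2025", 94.33, 57, "M", "pancreatic cancer, acute cerebral stroke", "clinical"),
    ("1104", "1104/2024", 97.58, 54, "F", "drug intoxication", ""),
]

_UNKNOWN = [
    # sample, case, estimated pmi_h, age, sex, cause of death, storage flag
    ("641", "641/2024", 179.28, 69, "M", "septic shock", "refrigerated_prolonged"),
    ("647", "647/2024", 12.0, 35, "M", "drug intoxication", "normal"),
    ("205", "205/2025", 15.0, 55, "M", "hypothermia", "normal"),
    ("634", "634/2024", 17.0, 64, "M", "fall from height", "normal"),
    ("723", "723/2024", 19.0, 19, "M", "hypothermia", "normal"),
    ("643", "643/2024", 20.0, 55, "M", "fall from height", "normal"),
    ("637", "637/2024", 21.0, 71, "F", "thermal burns", "normal"),
    ("467", "467/2025", 33.0, 49, "M", "choking", "normal"),
    ("1247", "1247/2024", 33.0, 55, "M", "septic shock", "normal"),
    ("598", "598/2024", 35.5, 25, "M", "hanging", "normal"),
]


def reference_cohort() -> list[SampleRecord]:
    """All 30 case records (20 known-PMI, 10 estimated-PMI)."""
    records = [
        SampleRecord(
            sample_id=sid, case_id=case, cohort="known", pmi_hours=pmi,
            pmi_provenance="documented", age=age, sex=sex,
            cause_of_death=cause, confounder_flag=flag,
        )
        for sid, case, pmi, age, sex, cause, flag in _KNOWN
    ]
    records += [
        SampleRecord(
            sample_id=sid, case_id=case, cohort="unknown", pmi_hours=pmi,
            # 641 is a hospital death with a documented (but biochemically
            # decoupled) PMI; the scene deaths carry recovery-based estimates
            pmi_provenance="documented" if sid == "641" else "scene_estimate",
            age=age, sex=sex, cause_of_death=cause, storage_flag=storage,
        )
        for sid, case, pmi, age, sex, cause, storage in _UNKNOWN
    ]
    return records
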