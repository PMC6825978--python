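"""Shared builders for patient-record fixtures.

``benign_record`` sits strictly inside every non-deficit range (all 23
deficits = 0); ``frail_record`` sits strictly inside every deficit range
(all 23 deficits = 1). Tests perturb individual fields via the factory.
"""

import pytest

from dasikit.cohort import Cohort, LabPanel, PatientRecord


def _make_record(**overrides) -> PatientRecord:
    lab_fields = {
        "wbc", "hemoglobin", "platelets", "neutrophils", "lymphocytes",
        "sodium", "creatinine", "corrected_calcium", "albumin",
    }
    labs = {
        "wbc": 8.0, "hemoglobin": 13.0, "platelets": 250.0, "neutrophils": 4.0,
        "lymphocytes": 12.0, "sodium": 140.0, "creatinine": 1.0,
        "corrected_calcium": 9.5, "albumin": 4.0,
    }
    base = {
        "patient_id": "P001",
        "readmitted_30d": False,
        "survival_time": 100.0,
        "event": True,
        "sex": "male",
        "age": 60.0,
        "marital_status": "married",
        "language": "english",
        "race": "white",
        "fall_risk": "moderate",
        "ecog_ps": 1,
        "karnofsky": 80,
        "healthcare_visits_6mo": 0,
        "length_of_index_admission": 3.0,
        "chief_complaint": "back pain",
        "cancer_type_raw": "lung",
        "metastasis": False,
        "weight_kg": 70.0,
        "height_cm": 175.0,
        "n_medications": 4,
    }
    for k, v in overrides.items():
        if k in lab_fields:
            labs[k] = v
        else:
            base[k] = v
    return PatientRecord(labs=LabPanel(**labs), **base)


@pytest.fixture
def record_factory():
    return _make_record


@pytest.fixture
def benign_record():
    # lymphocytes 12 with albumin 4 keeps PNI (= albumin x lymphocytes) at 48,
    # above the 45 cutoff, while NLR/PLR/SII stay far below theirs
    return _make_record()


@pytest.fixture
def frail_record():
    return _make_record(
        patient_id="P002",
        readmitted_30d=True,
        marital_status="single",
        language="not_english",
        fall_risk="high",
        ecog_ps=2,
        healthcare_visits_6mo=3,
        length_of_index_admission=6.0,
        n_medications=6,
        metastasis=True,
        weight_kg=50.0,  # BMI 16.3 < 19
        wbc=12.0, hemoglobin=10.0, platelets=500.0, neutrophils=1.0,
        lymphocytes=0.1, sodium=130.0, creatinine=2.0,
        corrected_calcium=11.5, albumin=3.0,
    )


@pytest.fixture
def small_cohort(record_factory):
    recs = [
        record_factory(),
        record_factory(patient_id="P002", readmitted_30d=True, survival_time=50.0),
        record_factory(patient_id="P003", event=False, survival_time=300.0,
                       sodium=None, ecog_ps=None),
    ]
    return Cohort(recs, provenance="test-fixture")
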