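from datetime import date

import pytest

from fragscore.cohort_io import (
    FractureType,
    Malignancy,
    MentalStatus,
    Mobility,
    PatientRecord,
    Residence,
    Sex,
)
from fragscore.risk_scores import load_model_config

_BASE = dict(
    patient_id="P1",
    age=83,
    sex=Sex.FEMALE,
    residence=Residence.OWN_HOME,
    mobility=Mobility.NO_AIDS,
    mental_status=MentalStatus.ALERT,
    cognitive_impairment=False,
    asa_grade=2,
    hemoglobin=12.0,
    serum_urea=5.0,
    cci=2,
    n_comorbidities=1,
    fracture_type=FractureType.FEMORAL_NECK,
    in_hospital_fracture=False,
    nursing_care_certification=False,
    copd=False,
    pneumonia=False,
    ischemic_heart_disease=False,
    prior_mi=False,
    arrhythmia=False,
    chf=False,
    malnutrition=False,
    electrolyte_disorder=False,
    renal_disease=False,
    liver_disease_moderate_severe=False,
    deficiency_anemia=False,
    chronic_pulmonary_disease=False,
    malignancy=Malignancy.NONE,
    dxa_t_score=-3.0,
    treated_surgically=True,
    admission_date=date(2020, 1, 1),
    dead_1y=False,
    followup_months=24.0,
)


def make_patient(**overrides) -> PatientRecord:
    """A healthy-baseline patient record with fields overridden as requested."""
    kw = dict(_BASE)
    kw.update(overrides)
    return PatientRecord(**kw)


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture(scope="session")
def model_config():
    return load_model_config()
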