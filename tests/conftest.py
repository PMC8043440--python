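from datetime import date

import pytest

from fracsurv.corpus import (
    AnatomicalRegion,
    CareSetting,
    ReferringClinic,
    Report,
    Sex,
)
from fracsurv.nlp import FractureClassifier


def make_report(
    text: str,
    report_id: str = "r1",
    exam_date: date = date(2020, 3, 18),
    region: AnatomicalRegion = AnatomicalRegion.hand_wrist,
    age: int = 30,
    sex: Sex = Sex.male,
    care_setting: CareSetting = CareSetting.outpatient,
    clinic: ReferringClinic = ReferringClinic.orthopedics_trauma,
) -> Report:
    return Report(
        report_id=report_id,
        exam_date=exam_date,
        anatomical_region=region,
        patient_age=age,
        sex=sex,
        care_setting=care_setting,
        referring_clinic=clinic,
        text=text,
    )


@pytest.fixture(scope="session")
def classifier() -> FractureClassifier:
    return FractureClassifier()
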