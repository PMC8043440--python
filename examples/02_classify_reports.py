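"""Classify individual German report texts and show the audit trail.

Runs the rule engine (cleansing -> sectioning -> concept matching ->
NegEx-style polarity resolution) on a few illustrative texts and prints
each concept mention with its resolved polarity and the report label.
"""

from datetime import date

from fracsurv import FractureClassifier
from fracsurv.corpus import (
    AnatomicalRegion,
    CareSetting,
    ReferringClinic,
    Report,
    Sex,
)

TEXTS = [
    "Distale Radiusfraktur mit Dislokation nach dorsal.",
    "Kein Nachweis einer frischen Fraktur.",
    "Fraktur nicht sicher auszuschließen, ergänzende CT empfohlen.",
    "Fragestellung: Frage nach Fraktur. Befund: Regelrechte ossäre Strukturen.",
    "Kein Erguss, aber dislozierte Fraktur.",
    "Alte Fraktur negiert, neue dislozierte Fraktur.",
]

clf = FractureClassifier()
for i, text in enumerate(TEXTS):
    report = Report(
        report_id=f"demo{i}",
        exam_date=date(2020, 4, 1),
        anatomical_region=AnatomicalRegion.hand_wrist,
        patient_age=40,
        sex=Sex.female,
        care_setting=CareSetting.outpatient,
        referring_clinic=ReferringClinic.orthopedics_trauma,
        text=text,
    )
    label, matches, cleansed = clf.analyze(report)
    print(f"\n{text}")
    for m in matches:
        print(
            f"  [{m.section_kind.value}] '{cleansed.text[m.start:m.end]}'"
            f" @ {m.start}-{m.end} -> {m.polarity.value}"
        )
    if not matches:
        print("  (no countable fracture mention)")
    print(f"  => {label.label.value}")

print(
    "\nA report is 'affirmed' iff any mention survives as affirmed;"
    "\nnegated, uncertain, recommendation-context, and indication-section"
    "\nmentions never count."
)
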