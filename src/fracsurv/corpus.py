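"""Report and label data model, file I/O, and study-population filters.

A :class:`Report` is one free-text radiograph report plus its RIS metadata
(exam date, anatomical region, patient age and sex, care setting, referring
clinic). Reports are exchanged as JSONL (one object per line) or CSV
(comma-separated, UTF-8, header row, quoted text field); labels as CSV with
columns ``report_id, source, label``.

The filters implement the study design of a curfew-period fracture
surveillance analysis: a fixed March 18 – April 30 window per calendar year,
outpatients referred from orthopedics/trauma or pediatrics, six appendicular
and pelvic radiograph regions, and three age strata (<18, 18–65, >65 years).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, fields
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AnatomicalRegion",
    "Sex",
    "CareSetting",
    "ReferringClinic",
    "AgeGroup",
    "Label",
    "LabelSource",
    "Report",
    "LabelRecord",
    "CorpusError",
    "read_reports",
    "write_reports",
    "read_labels",
    "write_labels",
    "filter_study_window",
    "filter_population",
    "assign_age_group",
    "STUDY_WINDOW",
]


class AnatomicalRegion(str, Enum):
    """The six radiograph regions covered by the surveillance analysis."""

    hand_wrist = "hand_wrist"
    elbow = "elbow"
    shoulder = "shoulder"
    ankle = "ankle"
    knee = "knee"
    pelvis_hip = "pelvis_hip"


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class CareSetting(str, Enum):
    outpatient = "outpatient"
    inpatient = "inpatient"


class ReferringClinic(str, Enum):
    orthopedics_trauma = "orthopedics_trauma"
    pediatrics = "pediatrics"
    other = "other"


class AgeGroup(str, Enum):
    """Age strata: <18, 18–65 (inclusive on both ends), >65 years."""

    under_18 = "under_18"
    from_18_to_65 = "from_18_to_65"
    over_65 = "over_65"


class Label(str, Enum):
    """Binary report-level label: a fracture asserted with certainty, or not.

    Negated, suspected/uncertain, and further-imaging-recommended mentions
    all map to ``not_affirmed``.
    """

    affirmed = "affirmed"
    not_affirmed = "not_affirmed"


class LabelSource(str, Enum):
    engine = "engine"
    annotator_1 = "annotator_1"
    annotator_2 = "annotator_2"
    consensus = "consensus"
    gold = "gold"


class CorpusError(Exception):
    """Fatal corpus integrity problem (missing file, duplicate report_id...)."""


# Inclusive calendar window (month, day) compared across years: the German
# curfew period of spring 2020.
STUDY_WINDOW = ((3, 18), (4, 30))


@dataclass(frozen=True, slots=True)
class Report:
    """One radiograph free-text report with its exam metadata."""

    report_id: str
    exam_date: date
    anatomical_region: AnatomicalRegion
    patient_age: int
    sex: Sex
    care_setting: CareSetting
    referring_clinic: ReferringClinic
    text: str

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if self.patient_age < 0:
            raise ValueError(f"patient_age must be >= 0, got {self.patient_age}")
        if not self.text.strip():
            raise ValueError("text must be non-empty after whitespace stripping")

    @property
    def age_group(self) -> AgeGroup:
        return assign_age_group(self.patient_age)


@dataclass(frozen=True, slots=True)
class LabelRecord:
    """Binary label for one report from one source (engine, annotator, ...)."""

    report_id: str
    source: LabelSource
    label: Label


_REPORT_FIELDS = tuple(f.name for f in fields(Report))


def assign_age_group(age: int) -> AgeGroup:
    """Map an age in completed years onto the three study strata.

    Age 65 belongs to the middle group (the 18–65 stratum is inclusive
    on both ends).
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    if age < 18:
        return AgeGroup.under_18
    if age <= 65:
        return AgeGroup.from_18_to_65
    return AgeGroup.over_65


def _report_from_record(rec: Mapping[str, object]) -> Report:
    missing = [f for f in _REPORT_FIELDS if f not in rec or rec[f] in (None, "")]
    if missing:
        raise ValueError(f"missing fields: {missing}")
    return Report(
        report_id=str(rec["report_id"]),
        exam_date=date.fromisoformat(str(rec["exam_date"])),
        anatomical_region=AnatomicalRegion(str(rec["anatomical_region"])),
        patient_age=int(rec["patient_age"]),
        sex=Sex(str(rec["sex"])),
        care_setting=CareSetting(str(rec["care_setting"])),
        referring_clinic=ReferringClinic(str(rec["referring_clinic"])),
        text=str(rec["text"]),
    )


def _report_to_record(r: Report) -> dict[str, str | int]:
    return {
        "report_id": r.report_id,
        "exam_date": r.exam_date.isoformat(),
        "anatomical_region": r.anatomical_region.value,
        "patient_age": r.patient_age,
        "sex": r.sex.value,
        "care_setting": r.care_setting.value,
        "referring_clinic": r.referring_clinic.value,
        "text": r.text,
    }


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise CorpusError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_reports(path: str | Path, format: str | None = None) -> list[Report]:
    """Read a report corpus from JSONL or CSV.

    Malformed records are skipped with a warning (the count is logged);
    a duplicate ``report_id`` is fatal, since silent double counting would
    corrupt downstream event counts.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus file not found: {path}")
    fmt = _infer_format(path, format)
    reports: list[Report] = []
    seen: set[str] = set()
    skipped = 0
    with path.open("r", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            rows: Iterable[Mapping[str, object]] = (
                json.loads(line) for line in fh if line.strip()
            )
        elif fmt == "csv":
            rows = csv.DictReader(fh)
        else:
            raise CorpusError(f"unsupported format: {fmt!r}")
        for i, row in enumerate(rows, start=1):
            try:
                report = _report_from_record(row)
            except (ValueError, KeyError, TypeError) as exc:
                skipped += 1
                logger.warning("skipping malformed record %d in %s: %s", i, path, exc)
                continue
            if report.report_id in seen:
                raise CorpusError(f"duplicate report_id {report.report_id!r} in {path}")
            seen.add(report.report_id)
            reports.append(report)
    if skipped:
        logger.warning("skipped %d malformed record(s) in %s", skipped, path)
    return reports


def write_reports(
    reports: Sequence[Report], path: str | Path, format: str | None = None
) -> None:
    """Write reports as JSONL or CSV (UTF-8, ISO dates, quoted text field)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for r in reports:
                fh.write(json.dumps(_report_to_record(r), ensure_ascii=False) + "\n")
        elif fmt == "csv":
            writer = csv.DictWriter(
                fh, fieldnames=list(_REPORT_FIELDS), quoting=csv.QUOTE_NONNUMERIC
            )
            writer.writeheader()
            for r in reports:
                writer.writerow(_report_to_record(r))
        else:
            raise CorpusError(f"unsupported format: {fmt!r}")


def read_labels(path: str | Path) -> list[LabelRecord]:
    """Read label records from CSV (report_id, source, label)."""
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"label file not found: {path}")
    labels: list[LabelRecord] = []
    seen: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rec = LabelRecord(
                report_id=row["report_id"],
                source=LabelSource(row["source"]),
                label=Label(row["label"]),
            )
            key = (rec.report_id, rec.source.value)
            if key in seen:
                raise CorpusError(f"duplicate label for {key} in {path}")
            seen.add(key)
            labels.append(rec)
    return labels


def write_labels(labels: Sequence[LabelRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["report_id", "source", "label"])
        for rec in labels:
            writer.writerow([rec.report_id, rec.source.value, rec.label.value])


def filter_study_window(reports: Sequence[Report], year: int) -> list[Report]:
    """Keep reports dated inside the March 18 – April 30 window of *year*.

    Both endpoints are inclusive; input order is preserved. Idempotent.
    """
    (m0, d0), (m1, d1) = STUDY_WINDOW
    lo, hi = date(year, m0, d0), date(year, m1, d1)
    return [r for r in reports if lo <= r.exam_date <= hi]


def filter_population(reports: Sequence[Report]) -> list[Report]:
    """Keep the study population: outpatients referred from orthopedics/
    trauma or pediatrics, radiographs of the six study regions.

    Inpatients are excluded (avoids counting post-surgical follow-up
    examinations as new events).
    """
    keep_clinics = (ReferringClinic.orthopedics_trauma, ReferringClinic.pediatrics)
    return [
        r
        for r in reports
        if r.care_setting is CareSetting.outpatient
        and r.referring_clinic in keep_clinics
        and r.anatomical_region in AnatomicalRegion.__members__.values()
    ]
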