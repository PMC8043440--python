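"""Seeded synthetic corpus of German radiograph reports with gold labels.

The generator emulates the study conditions of a curfew-window fracture
surveillance analysis: outpatient radiograph reports for six anatomical
regions and three age strata, dated March 18 – April 30 of 2015–2020, with
per-stratum yearly examination counts drawn Poisson and per-report fracture
status drawn Bernoulli. Report text is realized from a versioned template
bank (German, with correct umlauts); every template carries machine-readable
trace tags, so the gold label is constructed from the generation trace and
never by parsing text.

Labeling policy: a fracture drawn *true* but phrased as suspected/uncertain
(optionally with a CT/MRI recommendation) receives gold label
``not_affirmed`` — only fractures asserted with certainty count, matching
the annotation rule the engine is scored against.

Default rates are the printed study tables' row means: age-group and region
marginals combined by an independence (product) model
``rate(region, age) = rate_region x rate_age / rate_total``, which
reproduces both marginal tables in expectation. Baseline years 2015–2019
share the 2015–2019 mean rates; 2020 uses the 2020 column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date, timedelta
from importlib import resources
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .corpus import (
    AgeGroup,
    AnatomicalRegion,
    CareSetting,
    Label,
    LabelRecord,
    LabelSource,
    ReferringClinic,
    Report,
    Sex,
    STUDY_WINDOW,
)

__all__ = [
    "StratumRateSpec",
    "TextStyleSpec",
    "GeneratorConfig",
    "GenerationTrace",
    "paper_like_rate_specs",
    "paper_like_config",
    "generate_corpus",
    "generate_corpus_with_trace",
    "realize_text",
    "load_templates",
]


class TextStyleSpec(BaseModel):
    """Rates controlling the linguistic make-up of generated report text.

    ``distractor_rate`` is the probability of a *hard* realization: for a
    true fracture, an out-of-lexicon phrasing; for a non-fracture, either a
    blocklist compound ("Abbruch ...") or an out-of-lexicon negation. Hard
    templates are the only permitted source of engine-vs-gold disagreement.
    """

    negated_mention_rate: float = Field(0.5, ge=0.0, le=1.0)
    uncertainty_rate: float = Field(0.1, ge=0.0, le=1.0)
    recommendation_rate: float = Field(0.7, ge=0.0, le=1.0)
    distractor_rate: float = Field(0.2, ge=0.0, le=1.0)


class StratumRateSpec(BaseModel):
    """Expected examination count and fracture prevalence for one
    (region, age group, year) stratum."""

    anatomical_region: AnatomicalRegion
    age_group: AgeGroup
    year: int
    exam_rate: float = Field(ge=0.0)
    fracture_prevalence: float = Field(ge=0.0, le=1.0)


class GeneratorConfig(BaseModel):
    rate_specs: list[StratumRateSpec]
    style: TextStyleSpec = TextStyleSpec()
    years: list[int]
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if not self.years:
            raise ValueError("years must be non-empty")
        missing = [
            y for y in self.years if not any(s.year == y for s in self.rate_specs)
        ]
        if missing:
            raise ValueError(f"no rate_specs for years {missing}")
        return self


@dataclass(frozen=True, slots=True)
class GenerationTrace:
    """Per-report generation record: the oracle for gold-label consistency."""

    report_id: str
    true_fracture: bool
    phrasing: str  # affirmed | uncertain | negated | normal | distractor_*
    hard: bool
    template_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# Printed study-table marginals (baseline = 2015–2019 yearly means).

_EXAMS_AGE = {
    AgeGroup.under_18: (231.0, 93),
    AgeGroup.from_18_to_65: (526.0, 380),
    AgeGroup.over_65: (193.0, 178),
}
_FRACT_AGE = {
    AgeGroup.under_18: (81.0, 41),
    AgeGroup.from_18_to_65: (140.4, 110),
    AgeGroup.over_65: (74.0, 82),
}
_EXAMS_REGION = {
    AnatomicalRegion.hand_wrist: (293.0, 199),
    AnatomicalRegion.elbow: (99.0, 68),
    AnatomicalRegion.shoulder: (110.0, 97),
    AnatomicalRegion.ankle: (189.0, 94),
    AnatomicalRegion.knee: (154.0, 93),
    AnatomicalRegion.pelvis_hip: (104.0, 100),
}
_FRACT_REGION = {
    AnatomicalRegion.hand_wrist: (139.0, 90),
    AnatomicalRegion.elbow: (36.0, 18),
    AnatomicalRegion.shoulder: (37.0, 39),
    AnatomicalRegion.ankle: (37.0, 38),
    AnatomicalRegion.knee: (12.0, 14),
    AnatomicalRegion.pelvis_hip: (36.0, 40),
}
_TOTAL_EXAMS = (949.2, 651)
_TOTAL_FRACT = (294.8, 233)

BASELINE_YEARS = (2015, 2016, 2017, 2018, 2019)
TEST_YEAR = 2020


def paper_like_rate_specs(
    years: Sequence[int] = BASELINE_YEARS + (TEST_YEAR,),
) -> list[StratumRateSpec]:
    """Joint (region x age) rates from the printed marginal tables via the
    independence model; baseline years share the 2015–2019 means."""
    specs: list[StratumRateSpec] = []
    for year in years:
        col = 1 if year == TEST_YEAR else 0
        e_tot, f_tot = _TOTAL_EXAMS[col], _TOTAL_FRACT[col]
        p_tot = f_tot / e_tot
        for region in AnatomicalRegion:
            e_r, f_r = _EXAMS_REGION[region][col], _FRACT_REGION[region][col]
            for age in AgeGroup:
                e_a, f_a = _EXAMS_AGE[age][col], _FRACT_AGE[age][col]
                exam_rate = e_r * e_a / e_tot
                p_r, p_a = f_r / e_r, f_a / e_a
                prevalence = min(1.0, p_r * p_a / p_tot)
                specs.append(
                    StratumRateSpec(
                        anatomical_region=region,
                        age_group=age,
                        year=year,
                        exam_rate=exam_rate,
                        fracture_prevalence=prevalence,
                    )
                )
    return specs


def paper_like_config(
    seed: int = 0, years: Sequence[int] = BASELINE_YEARS + (TEST_YEAR,)
) -> GeneratorConfig:
    """The packaged default configuration emulating the study conditions."""
    return GeneratorConfig(
        rate_specs=paper_like_rate_specs(years),
        style=TextStyleSpec(),
        years=list(years),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Template bank


@dataclass(frozen=True, slots=True)
class Template:
    template_id: str
    region: str  # region value or "any"
    tags: frozenset[str]
    text: str


def load_templates() -> tuple[Template, ...]:
    with resources.files("fracsurv.resources").joinpath("templates.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return tuple(
            Template(
                r["template_id"],
                r["region"],
                frozenset(r["tags"].split(";")),
                r["text"],
            )
            for r in csv.DictReader(fh)
        )


def _bank() -> dict[str, dict[str, list[Template]]]:
    """kind -> region ('any' included) -> templates."""
    bank: dict[str, dict[str, list[Template]]] = {}
    for t in load_templates():
        kind = next(iter(t.tags - {"easy", "hard"}))
        bank.setdefault(kind, {}).setdefault(t.region, []).append(t)
    return bank


_BANK = _bank()


def _pick(rng: np.random.Generator, kind: str, region: str) -> Template:
    pool = _BANK[kind].get(region, []) + _BANK[kind].get("any", [])
    return pool[int(rng.integers(len(pool)))]


@dataclass(frozen=True, slots=True)
class Realization:
    text: str
    gold_label: Label
    phrasing: str
    hard: bool
    template_ids: tuple[str, ...]


def realize_text(
    true_label: Label,
    style: TextStyleSpec,
    region: AnatomicalRegion,
    rng: np.random.Generator,
) -> Realization:
    """Compose report text consistent with the drawn fracture status.

    The gold label is decided here from the generation path (uncertain
    phrasing of a true fracture yields ``not_affirmed``), and recorded in
    the returned trace fields — never recovered from the text.
    """
    parts: list[str] = []
    ids: list[str] = []

    def use(kind: str) -> str:
        t = _pick(rng, kind, region.value)
        ids.append(t.template_id)
        return t.text

    if rng.random() < 0.5:
        parts.append(use("indication"))

    if true_label is Label.affirmed:
        uncertain = rng.random() < style.uncertainty_rate
        if uncertain:
            sentence = use("uncertain")
            if rng.random() < style.recommendation_rate:
                sentence += ", " + use("recommendation")
            parts.append("Befund: " + sentence + ".")
            gold, phrasing, hard = Label.not_affirmed, "uncertain", False
        elif rng.random() < style.distractor_rate:
            parts.append("Befund: " + use("hard_affirmed"))
            gold, phrasing, hard = Label.affirmed, "affirmed", True
        else:
            body = use("affirmed")
            if rng.random() < 0.5:
                body += " " + use("filler")
            parts.append("Befund: " + body)
            if rng.random() < 0.5:
                parts.append(use("impression_affirmed"))
            gold, phrasing, hard = Label.affirmed, "affirmed", False
    else:
        if rng.random() < style.distractor_rate:
            kind = (
                "distractor_blocklist" if rng.random() < 0.5 else "distractor_negation"
            )
            parts.append("Befund: " + use(kind))
            gold, phrasing, hard = Label.not_affirmed, kind, True
        elif rng.random() < style.negated_mention_rate:
            parts.append("Befund: " + use("negated"))
            gold, phrasing, hard = Label.not_affirmed, "negated", False
        else:
            parts.append("Befund: " + use("normal"))
            gold, phrasing, hard = Label.not_affirmed, "normal", False

    return Realization(" ".join(parts), gold, phrasing, hard, tuple(ids))


# ---------------------------------------------------------------------------
# Corpus generation

_AGE_RANGES = {
    AgeGroup.under_18: (1, 17),
    AgeGroup.from_18_to_65: (18, 65),
    AgeGroup.over_65: (66, 95),
}


def _window_dates(year: int) -> list[date]:
    (m0, d0), (m1, d1) = STUDY_WINDOW
    lo, hi = date(year, m0, d0), date(year, m1, d1)
    return [lo + timedelta(days=i) for i in range((hi - lo).days + 1)]


def generate_corpus_with_trace(
    config: GeneratorConfig,
) -> tuple[list[Report], list[LabelRecord], list[GenerationTrace]]:
    """Generate reports, gold labels, and the per-report generation trace.

    Identical config (including seed) reproduces the output bit-exactly.
    Strata are visited in a fixed sorted order so determinism does not
    depend on dict ordering.
    """
    rng = np.random.default_rng(config.seed)
    reports: list[Report] = []
    gold: list[LabelRecord] = []
    traces: list[GenerationTrace] = []
    specs = sorted(
        (s for s in config.rate_specs if s.year in config.years),
        key=lambda s: (s.year, s.anatomical_region.value, s.age_group.value),
    )
    for spec in specs:
        n = int(rng.poisson(spec.exam_rate))
        dates = _window_dates(spec.year)
        a_lo, a_hi = _AGE_RANGES[spec.age_group]
        for i in range(n):
            report_id = (
                f"R{spec.year}-{spec.anatomical_region.value}"
                f"-{spec.age_group.value}-{i:05d}"
            )
            exam_date = dates[int(rng.integers(len(dates)))]
            age = int(rng.integers(a_lo, a_hi + 1))
            sex = Sex.male if rng.random() < 0.5 else Sex.female
            clinic = (
                ReferringClinic.pediatrics
                if spec.age_group is AgeGroup.under_18
                else ReferringClinic.orthopedics_trauma
            )
            true_label = (
                Label.affirmed
                if rng.random() < spec.fracture_prevalence
                else Label.not_affirmed
            )
            real = realize_text(true_label, config.style, spec.anatomical_region, rng)
            reports.append(
                Report(
                    report_id=report_id,
                    exam_date=exam_date,
                    anatomical_region=spec.anatomical_region,
                    patient_age=age,
                    sex=sex,
                    care_setting=CareSetting.outpatient,
                    referring_clinic=clinic,
                    text=real.text,
                )
            )
            gold.append(LabelRecord(report_id, LabelSource.gold, real.gold_label))
            traces.append(
                GenerationTrace(
                    report_id,
                    true_label is Label.affirmed,
                    real.phrasing,
                    real.hard,
                    real.template_ids,
                )
            )
    return reports, gold, traces


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[Report], list[LabelRecord]]:
    """Generate a synthetic corpus and its gold labels (see module docs)."""
    reports, gold, _ = generate_corpus_with_trace(config)
    return reports, gold
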