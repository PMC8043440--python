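"""Lexicon resources for fracture-concept recognition and trigger scoping.

Two hot-swappable CSV resources drive the rule engine:

* fracture terms — ``term, match_mode, concept_id``: lower-cased lexemes
  mapped to the RadLex fracture concept (RID4650). ``substring`` terms match
  inside German compounds ("Radiusfraktur", "Außenknöchelbruch"); ``token``
  terms match whole tokens only. A blocklist of whole tokens (e.g.
  "Abbruch", "Durchbruch") suppresses false compound hits.
* triggers — ``phrase, kind, scope_window``: NegEx-style context triggers
  (pre/post negation, uncertainty, recommendation, pseudo-trigger,
  termination) with a token scope window (default 5, the classic NegEx
  convention).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "MatchMode",
    "TriggerKind",
    "FractureTerm",
    "FractureLexicon",
    "Trigger",
    "TriggerLexicon",
    "load_fracture_lexicon",
    "load_trigger_lexicon",
    "DEFAULT_CONCEPT_ID",
]

DEFAULT_CONCEPT_ID = "RID4650"


class MatchMode(str, Enum):
    token = "token"
    substring = "substring"


class TriggerKind(str, Enum):
    pre_negation = "pre_negation"
    post_negation = "post_negation"
    uncertainty = "uncertainty"
    recommendation = "recommendation"
    pseudo_trigger = "pseudo_trigger"
    termination = "termination"


@dataclass(frozen=True, slots=True)
class FractureTerm:
    term: str
    match_mode: MatchMode
    concept_id: str = DEFAULT_CONCEPT_ID

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("term must be non-empty")
        if self.term != self.term.lower():
            raise ValueError(f"term must be lower-cased: {self.term!r}")


@dataclass(frozen=True)
class FractureLexicon:
    """Concept terms plus a token blocklist (never-match compounds)."""

    entries: tuple[FractureTerm, ...]
    blocklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        terms = {e.term for e in self.entries}
        if terms & self.blocklist:
            raise ValueError("blocklist must be disjoint from terms")


@dataclass(frozen=True, slots=True)
class Trigger:
    phrase: str
    kind: TriggerKind
    scope_window: int = 5

    def __post_init__(self) -> None:
        if not self.phrase:
            raise ValueError("trigger phrase must be non-empty")
        if self.phrase != self.phrase.lower():
            raise ValueError(f"trigger phrase must be lower-cased: {self.phrase!r}")


@dataclass(frozen=True)
class TriggerLexicon:
    entries: tuple[Trigger, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, TriggerKind]] = set()
        for t in self.entries:
            key = (t.phrase, t.kind)
            if key in seen:
                raise ValueError(f"duplicate trigger {key}")
            seen.add(key)

    def by_kind(self, kind: TriggerKind) -> tuple[Trigger, ...]:
        return tuple(t for t in self.entries if t.kind is kind)


def _resource_rows(name: str) -> Iterable[dict[str, str]]:
    with resources.files("fracsurv.resources").joinpath(name).open(
        "r", encoding="utf-8"
    ) as fh:
        yield from csv.DictReader(fh)


def load_fracture_lexicon(
    terms_path: str | Path | None = None, blocklist_path: str | Path | None = None
) -> FractureLexicon:
    """Load the fracture lexicon from CSV, defaulting to the packaged resource."""
    if terms_path is None:
        rows = list(_resource_rows("fracture_terms.csv"))
    else:
        with open(terms_path, "r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    entries = tuple(
        FractureTerm(r["term"], MatchMode(r["match_mode"]), r["concept_id"])
        for r in rows
    )
    if blocklist_path is None:
        brows = list(_resource_rows("fracture_blocklist.csv"))
    else:
        with open(blocklist_path, "r", encoding="utf-8") as fh:
            brows = list(csv.DictReader(fh))
    blocklist = frozenset(r["token"] for r in brows)
    return FractureLexicon(entries=entries, blocklist=blocklist)


def load_trigger_lexicon(path: str | Path | None = None) -> TriggerLexicon:
    """Load the trigger lexicon from CSV, defaulting to the packaged resource."""
    if path is None:
        rows = list(_resource_rows("triggers.csv"))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    return TriggerLexicon(
        entries=tuple(
            Trigger(r["phrase"], TriggerKind(r["kind"]), int(r["scope_window"]))
            for r in rows
        )
    )
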