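"""Rule-based fracture classification of German radiograph reports.

The pipeline mirrors the classic stages of clinical concept extraction:

1. **cleansing** — whitespace normalization and de-hyphenation of line
   breaks, with an offset map back to the raw text;
2. **contextualization** — segmentation into indication / findings /
   impression sections on German header cues, and sentence splitting with
   abbreviation protection ("V.a.", "Z.n.", "i.p.", ...);
3. **concept recognition** — lexicon lookup of fracture lexemes
   (RadLex RID4650 and synonyms), matching inside German compounds for
   substring-mode terms, with a blocklist for false compounds;
4. **negation / uncertainty detection** — a NegEx-style scope model:
   pre-negation triggers project forward over a token window, post-negation
   triggers backward, uncertainty triggers both ways; termination tokens
   ("aber", "jedoch", ...) cut scopes; pseudo-triggers block the triggers
   they contain; a recommendation trigger in the sentence demotes its
   matches to uncertain.

The report-level label is ``affirmed`` iff at least one concept mention
survives with affirmed polarity; negated-only, uncertain-only, and
mention-free reports are ``not_affirmed``. Matches in the indication
section are discarded — the clinical question ("Frage nach Fraktur") never
counts as a finding. The whole pipeline is deterministic.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

from .corpus import Label, LabelRecord, LabelSource, Report
from .lexicons import (
    FractureLexicon,
    MatchMode,
    TriggerKind,
    TriggerLexicon,
    load_fracture_lexicon,
    load_trigger_lexicon,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SectionKind",
    "Polarity",
    "CleansedText",
    "Sentence",
    "Section",
    "SectionedText",
    "ConceptMatch",
    "cleanse_text",
    "contextualize",
    "match_fracture_concepts",
    "resolve_polarity",
    "classify_report",
    "classify_corpus",
    "FractureClassifier",
]


class SectionKind(str, Enum):
    indication = "indication"
    findings = "findings"
    impression = "impression"
    other = "other"


class Polarity(str, Enum):
    affirmed = "affirmed"
    negated = "negated"
    uncertain = "uncertain"


@dataclass(frozen=True, slots=True)
class CleansedText:
    """Normalized text plus a map from cleansed to raw character offsets."""

    text: str
    offset_map: tuple[int, ...]  # offset_map[i] = raw index of cleansed char i

    def raw_span(self, start: int, end: int) -> tuple[int, int]:
        if start >= end:
            return (0, 0)
        return (self.offset_map[start], self.offset_map[end - 1] + 1)


@dataclass(frozen=True, slots=True)
class Sentence:
    start: int
    end: int  # 0-based half-open, absolute into the cleansed text


@dataclass(frozen=True, slots=True)
class Section:
    kind: SectionKind
    start: int
    end: int
    sentences: tuple[Sentence, ...]


@dataclass(frozen=True, slots=True)
class SectionedText:
    text: str
    sections: tuple[Section, ...]


@dataclass(frozen=True, slots=True)
class ConceptMatch:
    """A located fracture-concept mention with (eventually) resolved polarity."""

    report_id: str
    section_kind: SectionKind
    section_index: int
    sentence_index: int
    start: int
    end: int
    matched_lexeme: str
    concept_id: str
    polarity: Polarity | None = None


def cleanse_text(raw: str) -> CleansedText:
    """Normalize whitespace and join hyphenated line breaks.

    "Radius-\\nfraktur" becomes "Radiusfraktur"; runs of whitespace
    (including tabs and newlines) collapse to single spaces; leading and
    trailing whitespace is dropped. Umlauts and case are preserved. The
    returned offset map lets every downstream span be traced to the raw
    string.
    """
    out: list[str] = []
    omap: list[int] = []
    i, n = 0, len(raw)
    while i < n:
        c = raw[i]
        if c == "-" and out and out[-1].isalnum():
            # hyphen at a line break between word parts: drop hyphen + break
            j = i + 1
            while j < n and raw[j] in " \t":
                j += 1
            if j < n and raw[j] in "\n\r":
                k = j
                while k < n and raw[k].isspace():
                    k += 1
                if k < n and raw[k].isalpha():
                    i = k
                    continue
        if c.isspace():
            if out and out[-1] != " ":
                out.append(" ")
                omap.append(i)
            i += 1
            continue
        out.append(c)
        omap.append(i)
        i += 1
    while out and out[-1] == " ":
        out.pop()
        omap.pop()
    return CleansedText(text="".join(out), offset_map=tuple(omap))


_HEADER_RE = re.compile(
    r"(?i)\b(Indikation|Fragestellung|Anamnese|Befund|Beurteilung)\s*:"
)
_HEADER_KIND = {
    "indikation": SectionKind.indication,
    "fragestellung": SectionKind.indication,
    "anamnese": SectionKind.indication,
    "befund": SectionKind.findings,
    "beurteilung": SectionKind.impression,
}

# Abbreviations whose trailing period is not a sentence boundary.
_ABBREVIATIONS = {
    "v.a",
    "z.n",
    "i.p",
    "a.p",
    "u.a",
    "o.g",
    "ggf",
    "bzw",
    "ca",
    "st.n",
    "dd",
}


def _split_sentences(text: str, start: int, end: int) -> tuple[Sentence, ...]:
    """Sentence spans inside text[start:end], splitting on . ! ? with
    abbreviation protection."""
    sentences: list[Sentence] = []
    s = start
    i = start
    while i < end:
        c = text[i]
        if c in "!?":
            sentences.append(Sentence(s, i + 1))
            i += 1
            while i < end and text[i] == " ":
                i += 1
            s = i
            continue
        if c == ".":
            # internal dot ("V.a.", "3.5"): no boundary without following space
            if i + 1 < end and not text[i + 1].isspace():
                i += 1
                continue
            # trailing token before the period, e.g. "V.a" in "V.a."
            j = i - 1
            while j >= s and (text[j].isalnum() or text[j] == "."):
                j -= 1
            token = text[j + 1 : i].lower()
            if token in _ABBREVIATIONS:
                i += 1
                continue
            sentences.append(Sentence(s, i + 1))
            i += 1
            while i < end and text[i] == " ":
                i += 1
            s = i
            continue
        i += 1
    if s < end:
        span_text = text[s:end]
        if span_text.strip():
            sentences.append(Sentence(s, end))
    return tuple(sentences)


def contextualize(cleansed: str | CleansedText) -> SectionedText:
    """Segment cleansed text into sections and sentences.

    Header cues: "Indikation:"/"Fragestellung:"/"Anamnese:" open the
    indication, "Befund:" the findings, "Beurteilung:" the impression.
    Headerless text — including a preamble before the first header — is
    treated as findings (conservative: content is never dropped, and never
    mistaken for the clinical question).
    """
    text = cleansed.text if isinstance(cleansed, CleansedText) else cleansed
    headers = list(_HEADER_RE.finditer(text))
    sections: list[Section] = []

    def add(kind: SectionKind, start: int, end: int) -> None:
        if text[start:end].strip():
            sections.append(
                Section(kind, start, end, _split_sentences(text, start, end))
            )

    if not headers:
        add(SectionKind.findings, 0, len(text))
    else:
        if headers[0].start() > 0:
            add(SectionKind.findings, 0, headers[0].start())
        for h, nxt in zip(headers, headers[1:] + [None]):
            kind = _HEADER_KIND[h.group(1).lower()]
            start = h.end()
            while start < len(text) and text[start] == " ":
                start += 1
            end = nxt.start() if nxt is not None else len(text)
            add(kind, start, end)
    return SectionedText(text=text, sections=tuple(sections))


_TOKEN_RE = re.compile(r"\S+")
_STRIP_CHARS = ".,;:!?()[]{}\"'«»–—"


def _tokenize(text: str, start: int, end: int) -> list[tuple[str, int, int]]:
    """(normalized_token, start, end) for each whitespace token in the span.

    Normalization lower-cases and strips surrounding punctuation while
    keeping internal dots ("V.a." -> "v.a").
    """
    tokens = []
    for m in _TOKEN_RE.finditer(text, start, end):
        tok = m.group(0)
        t0, t1 = m.start(), m.end()
        stripped = tok.strip(_STRIP_CHARS)
        if not stripped:
            continue
        off = tok.index(stripped[0])
        tokens.append((stripped.lower(), t0 + off, t0 + off + len(stripped)))
    return tokens


def match_fracture_concepts(
    sectioned: SectionedText,
    lexicon: FractureLexicon,
    report_id: str = "",
) -> list[ConceptMatch]:
    """Locate fracture-concept mentions; polarity is left unset (provisionally
    affirmed).

    Substring-mode terms match inside compound tokens unless the containing
    token is blocklisted; token-mode terms match whole tokens. Indication
    sections are skipped entirely.
    """
    matches: list[ConceptMatch] = []
    sub_terms = [e for e in lexicon.entries if e.match_mode is MatchMode.substring]
    tok_terms = {e.term: e for e in lexicon.entries if e.match_mode is MatchMode.token}
    for si, section in enumerate(sectioned.sections):
        if section.kind is SectionKind.indication:
            continue
        for qi, sent in enumerate(section.sentences):
            for norm, t0, t1 in _tokenize(sectioned.text, sent.start, sent.end):
                if norm in lexicon.blocklist:
                    continue
                if norm in tok_terms:
                    e = tok_terms[norm]
                    matches.append(
                        ConceptMatch(
                            report_id, section.kind, si, qi, t0, t1, e.term, e.concept_id
                        )
                    )
                    continue
                for e in sub_terms:
                    pos = norm.find(e.term)
                    if pos >= 0:
                        matches.append(
                            ConceptMatch(
                                report_id,
                                section.kind,
                                si,
                                qi,
                                t0 + pos,
                                t0 + pos + len(e.term),
                                e.term,
                                e.concept_id,
                            )
                        )
                        break  # one concept mention per token
    return matches


def _find_trigger_hits(
    tokens: list[tuple[str, int, int]], triggers: TriggerLexicon
) -> list[tuple[TriggerKind, int, int, int]]:
    """Trigger occurrences as (kind, first_token_idx, last_token_idx, window).

    Longest phrase wins at a given position; triggers contained in a
    pseudo-trigger span are dropped.
    """
    norm = [t[0] for t in tokens]
    phrases = sorted(
        ((tuple(t.phrase.split()), t) for t in triggers.entries),
        key=lambda p: -len(p[0]),
    )
    hits: list[tuple[TriggerKind, int, int, int]] = []
    claimed: set[int] = set()
    for words, trig in phrases:
        # normalize phrase words the same way as tokens
        words = tuple(w.strip(_STRIP_CHARS + " ").lower() for w in words)
        L = len(words)
        for i in range(0, len(norm) - L + 1):
            if any(j in claimed for j in range(i, i + L)):
                continue
            if tuple(norm[i : i + L]) == words:
                hits.append((trig.kind, i, i + L - 1, trig.scope_window))
                claimed.update(range(i, i + L))
    # pseudo-triggers neutralize anything inside their span
    pseudo = [(a, b) for k, a, b, _ in hits if k is TriggerKind.pseudo_trigger]
    if pseudo:
        hits = [
            h
            for h in hits
            if h[0] is TriggerKind.pseudo_trigger
            or not any(a <= h[1] and h[2] <= b for a, b in pseudo)
        ]
    return hits


def resolve_polarity(
    matches: Sequence[ConceptMatch],
    sectioned: SectionedText,
    triggers: TriggerLexicon,
) -> list[ConceptMatch]:
    """Assign each concept mention its final polarity via trigger scoping.

    Precedence when several triggers cover one mention:
    negated > uncertain > affirmed.
    """
    resolved: list[ConceptMatch] = []
    by_sentence: dict[tuple[int, int], list[ConceptMatch]] = {}
    for m in matches:
        by_sentence.setdefault((m.section_index, m.sentence_index), []).append(m)
    for (si, qi), sent_matches in by_sentence.items():
        sent = sectioned.sections[si].sentences[qi]
        tokens = _tokenize(sectioned.text, sent.start, sent.end)
        hits = _find_trigger_hits(tokens, triggers)
        terminations = {
            i
            for k, a, b, _ in hits
            if k is TriggerKind.termination
            for i in range(a, b + 1)
        }
        has_recommendation = any(k is TriggerKind.recommendation for k, *_ in hits)

        def token_index(m: ConceptMatch) -> int:
            for idx, (_, t0, t1) in enumerate(tokens):
                if t0 <= m.start < t1:
                    return idx
            return -1

        def blocked(lo: int, hi: int) -> bool:
            """Any termination token strictly between positions lo and hi?"""
            return any(lo < t < hi for t in terminations)

        for m in sent_matches:
            mi = token_index(m)
            polarity = Polarity.affirmed
            uncertain = has_recommendation
            negated = False
            for kind, a, b, window in hits:
                if kind is TriggerKind.pre_negation:
                    if b < mi <= b + window and not blocked(b, mi):
                        negated = True
                elif kind is TriggerKind.post_negation:
                    if a - window <= mi < a and not blocked(mi, a):
                        negated = True
                elif kind is TriggerKind.uncertainty:
                    if (b < mi <= b + window and not blocked(b, mi)) or (
                        a - window <= mi < a and not blocked(mi, a)
                    ):
                        uncertain = True
            if negated:
                polarity = Polarity.negated
            elif uncertain:
                polarity = Polarity.uncertain
            resolved.append(replace(m, polarity=polarity))
    return resolved


class FractureClassifier:
    """The assembled pipeline with loaded lexicons (reusable across reports)."""

    def __init__(
        self,
        fracture_lexicon: FractureLexicon | None = None,
        trigger_lexicon: TriggerLexicon | None = None,
    ) -> None:
        self.fracture_lexicon = fracture_lexicon or load_fracture_lexicon()
        self.trigger_lexicon = trigger_lexicon or load_trigger_lexicon()

    def analyze(self, report: Report) -> tuple[LabelRecord, list[ConceptMatch], CleansedText]:
        """Full pipeline with audit output (matches + cleansed text)."""
        cleansed = cleanse_text(report.text)
        sectioned = contextualize(cleansed.text)
        matches = match_fracture_concepts(
            sectioned, self.fracture_lexicon, report.report_id
        )
        matches = resolve_polarity(matches, sectioned, self.trigger_lexicon)
        label = (
            Label.affirmed
            if any(m.polarity is Polarity.affirmed for m in matches)
            else Label.not_affirmed
        )
        return (
            LabelRecord(report.report_id, LabelSource.engine, label),
            matches,
            cleansed,
        )

    def classify(self, report: Report) -> LabelRecord:
        return self.analyze(report)[0]


def classify_report(
    report: Report,
    fracture_lexicon: FractureLexicon | None = None,
    trigger_lexicon: TriggerLexicon | None = None,
) -> LabelRecord:
    """Classify one report as fracture affirmed / not affirmed.

    A report is ``affirmed`` iff any mention resolves to affirmed polarity
    (a report may carry both an excluded and a confirmed fracture at
    different sites — the confirmed one counts).
    """
    return FractureClassifier(fracture_lexicon, trigger_lexicon).classify(report)


def classify_corpus(
    reports: Sequence[Report],
    fracture_lexicon: FractureLexicon | None = None,
    trigger_lexicon: TriggerLexicon | None = None,
) -> list[LabelRecord]:
    """Classify a corpus, order-preserving; logs per-region label tallies."""
    clf = FractureClassifier(fracture_lexicon, trigger_lexicon)
    labels = [clf.classify(r) for r in reports]
    tally: Counter[tuple[str, str]] = Counter(
        (r.anatomical_region.value, lab.label.value)
        for r, lab in zip(reports, labels)
    )
    for (region, label), count in sorted(tally.items()):
        logger.info("region=%s label=%s n=%d", region, label, count)
    return labels
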