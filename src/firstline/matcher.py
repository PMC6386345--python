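"""Text normalization, drug-mention finding and negation annotation.

Registry free text is fragmentary: telegraphic phrases, abbreviations,
inconsistent capitalization, no reliable sentence structure.  Matching
therefore runs on a normalized string (lower-case, whitespace collapsed)
and negation/uncertainty use fixed character windows around a phrase match
rather than any sentence model.  Scope windows deliberately cross
punctuation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable

from .lexicon import CompiledMatcher, PhrasePattern

__all__ = [
    "DEFAULT_NEGATION_WINDOW",
    "TextRecord",
    "DrugMention",
    "normalize_text",
    "find_mentions",
    "annotate_negation",
    "detect_no_treatment",
]

#: Characters between a phrase and a mention within which the phrase applies.
DEFAULT_NEGATION_WINDOW = 40

_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class TextRecord:
    """One free-text treatment report tied to a patient.

    ``record_date`` orders multiple reports for the same patient; it may be
    absent.  ``text`` may be empty — blank fields are legal and mean
    non-informative.
    """

    patient_id: str
    record_id: str
    text: str = ""
    record_date: date | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.record_id:
            raise ValueError("record_id must be non-empty")


@dataclass(frozen=True)
class DrugMention:
    """A located drug match in normalized text, annotated with negation status.

    ``span`` is a 0-based half-open character interval into the *normalized*
    text.  ``negated`` and ``uncertain`` are independent flags.
    """

    canonical: str
    drug_class: str
    start: int
    end: int
    matched_variant: str
    negated: bool = False
    uncertain: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def normalize_text(raw: str) -> str:
    """Lower-case, collapse whitespace runs to single spaces, strip ends.

    All downstream character offsets refer to this normalized string.
    Idempotent; empty input yields empty output.
    """
    return _WS_RE.sub(" ", raw).strip().lower()


def find_mentions(
    record: TextRecord | str,
    matcher: CompiledMatcher,
    negation_window: int = DEFAULT_NEGATION_WINDOW,
) -> list[DrugMention]:
    """All non-overlapping drug mentions in a record's normalized text.

    Longest variant wins at each position; mentions are returned sorted by
    span start and already annotated for negation and uncertainty using the
    matcher's lexicon phrase lists.
    """
    raw = record.text if isinstance(record, TextRecord) else record
    text = normalize_text(raw)
    if not text:
        return []
    phrases = matcher.lexicon.phrases
    mentions = [
        DrugMention(
            canonical=m.canonical,
            drug_class=m.drug_class,
            start=m.start,
            end=m.end,
            matched_variant=m.variant,
        )
        for m in matcher.scan(text)
    ]
    return [
        annotate_negation(text, mention, phrases, window=negation_window)
        for mention in mentions
    ]


def _phrase_applies(
    text: str,
    mention: DrugMention,
    phrase: PhrasePattern,
    window: int,
) -> bool:
    """Does a mention-window phrase cover this mention?

    Forward scope: the mention starts within ``window`` characters after the
    phrase ends.  Backward scope: the phrase starts within ``window``
    characters after the mention ends.
    """
    for m in phrase.compiled.finditer(text):
        forward = phrase.direction in ("forward", "both")
        backward = phrase.direction in ("backward", "both")
        if forward and m.end() <= mention.start <= m.end() + window:
            return True
        if backward and mention.end <= m.start() <= mention.end + window:
            return True
    return False


def annotate_negation(
    text: str,
    mention: DrugMention,
    phrases: Iterable[PhrasePattern],
    window: int = DEFAULT_NEGATION_WINDOW,
) -> DrugMention:
    """Return the mention with ``negated`` and ``uncertain`` flags set.

    A mention is negated when a negation phrase matches within its scope
    window ("not a candidate for X", "X recommended but refused"), and
    uncertain when an uncertainty phrase does ("X recommended, unknown if
    given").  The two flags are independent; span and canonical are never
    altered.
    """
    if mention.end > len(text):
        raise ValueError(
            f"mention span [{mention.start}, {mention.end}) exceeds text length {len(text)}"
        )
    negated = False
    uncertain = False
    for phrase in phrases:
        if phrase.scope != "mention_window":
            continue
        if phrase.kind == "negation" and not negated:
            negated = _phrase_applies(text, mention, phrase, window)
        elif phrase.kind == "uncertainty" and not uncertain:
            uncertain = _phrase_applies(text, mention, phrase, window)
    if negated == mention.negated and uncertain == mention.uncertain:
        return mention
    return replace(mention, negated=negated, uncertain=uncertain)


def detect_no_treatment(text: str, phrases: Iterable[PhrasePattern]) -> bool:
    """True iff a whole-record no-treatment statement matches the text.

    Matching is phrase-template based with flexible whitespace; the input is
    normalized first so callers may pass raw text.
    """
    norm = normalize_text(text)
    if not norm:
        return False
    for phrase in phrases:
        if phrase.kind == "no_treatment" and phrase.scope == "whole_record":
            if phrase.compiled.search(norm):
                return True
    return False
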