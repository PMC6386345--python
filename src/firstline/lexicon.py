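"""Drug vocabulary and phrase lists that drive all text matching.

A :class:`Lexicon` bundles two things: the drug terms (generic names with
their brand names, abbreviations and curated misspellings, each assigned to
one of five drug classes) and the phrase patterns used for negation,
uncertainty and whole-record no-treatment detection.  The packaged default
lexicon covers the systemic agents in routine use for stage IV non-small
cell lung cancer in the 2012-2014 era; every term and phrase is
user-replaceable through the delimited file format described in
:func:`load_lexicon`.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

__all__ = [
    "DRUG_CLASSES",
    "PHRASE_KINDS",
    "DrugTerm",
    "PhrasePattern",
    "Lexicon",
    "LexiconError",
    "CompiledMatcher",
    "RawMatch",
    "load_lexicon",
    "loads_lexicon",
    "write_lexicon",
    "dumps_lexicon",
    "default_lexicon",
    "compile_lexicon",
]

DRUG_CLASSES = ("platinum", "pemetrexed", "bevacizumab", "tki", "other_chemo")
PHRASE_KINDS = ("negation", "uncertainty", "no_treatment")
PHRASE_SCOPES = ("mention_window", "whole_record")
PHRASE_DIRECTIONS = ("forward", "backward", "both")

# Internal separators tolerated inside multi-word variants: registry text is
# telegraphic ("carbo/taxol", "nab paclitaxel", "cis+gem").
_SEP_RE = re.compile(r"[\s/+\-]+")
_SEP_PATTERN = r"[\s/+\-]+"


class LexiconError(ValueError):
    """Raised for malformed lexicon files or invariant violations."""


@dataclass(frozen=True)
class DrugTerm:
    """One drug: a canonical generic name plus its surface variants.

    ``canonical`` is implicitly searchable alongside ``variants``.  With
    ``match_as_word`` (the default) every variant is matched only at word
    boundaries, so "carbo" does not fire inside "carbohydrate".
    """

    canonical: str
    drug_class: str
    variants: tuple[str, ...] = ()
    match_as_word: bool = True

    def __post_init__(self) -> None:
        canonical = self.canonical.strip().lower()
        if not canonical:
            raise LexiconError("DrugTerm canonical must be non-empty")
        if self.drug_class not in DRUG_CLASSES:
            raise LexiconError(
                f"unknown drug_class {self.drug_class!r} for {canonical!r}; "
                f"expected one of {DRUG_CLASSES}"
            )
        variants = tuple(v.strip().lower() for v in self.variants)
        if any(not v for v in variants):
            raise LexiconError(f"empty variant in term {canonical!r}")
        object.__setattr__(self, "canonical", canonical)
        object.__setattr__(self, "variants", variants)

    @property
    def surfaces(self) -> tuple[str, ...]:
        """All searchable strings: canonical first, then variants, deduplicated."""
        seen: dict[str, None] = {self.canonical: None}
        for v in self.variants:
            seen.setdefault(v, None)
        return tuple(seen)


@dataclass(frozen=True)
class PhrasePattern:
    """A negation / uncertainty / no-treatment phrase as a regex source.

    Literal spaces in ``pattern`` are compiled as flexible whitespace.
    ``direction`` controls which side of the phrase a mention-window pattern
    covers; whole-record patterns ignore it.
    """

    kind: str
    pattern: str
    scope: str
    direction: str = "forward"

    def __post_init__(self) -> None:
        if self.kind not in PHRASE_KINDS:
            raise LexiconError(f"unknown phrase kind {self.kind!r}")
        if self.scope not in PHRASE_SCOPES:
            raise LexiconError(f"unknown phrase scope {self.scope!r}")
        if self.direction not in PHRASE_DIRECTIONS:
            raise LexiconError(f"unknown phrase direction {self.direction!r}")
        if self.kind == "no_treatment" and self.scope != "whole_record":
            raise LexiconError(
                f"no_treatment phrase {self.pattern!r} must have whole_record scope"
            )
        try:
            self.compiled  # noqa: B018 - forces compilation check
        except re.error as exc:
            raise LexiconError(
                f"phrase pattern {self.pattern!r} does not compile: {exc}"
            ) from exc

    @property
    def compiled(self) -> re.Pattern[str]:
        return re.compile(self.pattern.replace(" ", r"\s+"), re.IGNORECASE)


@dataclass(frozen=True)
class Lexicon:
    """A validated set of drug terms and phrase patterns."""

    terms: tuple[DrugTerm, ...]
    phrases: tuple[PhrasePattern, ...] = ()
    version: str = "0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "phrases", tuple(self.phrases))
        self._validate()

    def _validate(self) -> None:
        seen_canonical: set[str] = set()
        surface_owner: dict[str, str] = {}
        for term in self.terms:
            if term.canonical in seen_canonical:
                raise LexiconError(f"duplicate canonical {term.canonical!r}")
            seen_canonical.add(term.canonical)
            for surface in term.surfaces:
                owner = surface_owner.get(surface)
                if owner is not None and owner != term.canonical:
                    raise LexiconError(
                        f"variant {surface!r} maps to both {owner!r} "
                        f"and {term.canonical!r}"
                    )
                surface_owner[surface] = term.canonical

    def phrases_of(self, kind: str) -> tuple[PhrasePattern, ...]:
        return tuple(p for p in self.phrases if p.kind == kind)

    def terms_of(self, drug_class: str) -> tuple[DrugTerm, ...]:
        return tuple(t for t in self.terms if t.drug_class == drug_class)

    def term(self, canonical: str) -> DrugTerm:
        for t in self.terms:
            if t.canonical == canonical:
                return t
        raise KeyError(canonical)


def _parse_bool(value: str, line_no: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes", ""):
        return True
    if v in ("false", "0", "no"):
        return False
    raise LexiconError(f"line {line_no}: cannot parse boolean {value!r}")


_TERM_HEADER = ["canonical", "drug_class", "variants", "match_as_word"]
_PHRASE_HEADER = ["kind", "pattern", "scope"]


def loads_lexicon(text: str, version: str = "0") -> Lexicon:
    """Parse a lexicon from its delimited text representation.

    The format is two CSV sections separated by one or more blank lines:
    drug terms under the header ``canonical,drug_class,variants,match_as_word``
    (variants pipe-separated) and phrases under ``kind,pattern,scope`` with an
    optional fourth ``direction`` column.  The phrase section may be absent.
    """
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        raise LexiconError("empty lexicon file")

    # Split into sections on blank lines, keeping original line numbers.
    sections: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    for i, line in enumerate(lines, start=1):
        if line.strip():
            current.append((i, line))
        elif current:
            sections.append(current)
            current = []
    if current:
        sections.append(current)

    terms: list[DrugTerm] = []
    phrases: list[PhrasePattern] = []
    for section in sections:
        header_no, header_line = section[0]
        delimiter = "\t" if "\t" in header_line else ","
        header = next(csv.reader([header_line], delimiter=delimiter))
        header = [h.strip().lower() for h in header]
        if header[: len(_TERM_HEADER)] == _TERM_HEADER or header[:2] == _TERM_HEADER[:2]:
            parse_row = _parse_term_row
            sink: list = terms
        elif header[: len(_PHRASE_HEADER)] == _PHRASE_HEADER:
            parse_row = _parse_phrase_row
            sink = phrases
        else:
            raise LexiconError(
                f"line {header_no}: unrecognized section header {header_line!r}"
            )
        for line_no, line in section[1:]:
            row = next(csv.reader([line], delimiter=delimiter))
            try:
                sink.append(parse_row(row, line_no))
            except LexiconError:
                raise
            except Exception as exc:  # malformed row
                raise LexiconError(f"line {line_no}: malformed row: {exc}") from exc

    if not terms:
        raise LexiconError("lexicon file defines no drug terms")
    return Lexicon(terms=tuple(terms), phrases=tuple(phrases), version=version)


def _parse_term_row(row: Sequence[str], line_no: int) -> DrugTerm:
    if len(row) < 2:
        raise LexiconError(f"line {line_no}: expected at least canonical,drug_class")
    canonical, drug_class = row[0], row[1]
    variants = tuple(v for v in (row[2].split("|") if len(row) > 2 and row[2] else []))
    match_as_word = _parse_bool(row[3], line_no) if len(row) > 3 else True
    try:
        return DrugTerm(canonical, drug_class.strip().lower(), variants, match_as_word)
    except LexiconError as exc:
        raise LexiconError(f"line {line_no}: {exc}") from exc


def _parse_phrase_row(row: Sequence[str], line_no: int) -> PhrasePattern:
    if len(row) < 3:
        raise LexiconError(f"line {line_no}: expected kind,pattern,scope")
    direction = row[3].strip().lower() if len(row) > 3 and row[3].strip() else "forward"
    try:
        return PhrasePattern(row[0].strip().lower(), row[1], row[2].strip().lower(), direction)
    except LexiconError as exc:
        raise LexiconError(f"line {line_no}: {exc}") from exc


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon from a delimited text file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return loads_lexicon(path.read_text(encoding="utf-8"), version=path.stem)


def dumps_lexicon(lex: Lexicon) -> str:
    """Serialize a lexicon to the text format accepted by :func:`loads_lexicon`."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_TERM_HEADER)
    for term in lex.terms:
        writer.writerow(
            [
                term.canonical,
                term.drug_class,
                "|".join(term.variants),
                "true" if term.match_as_word else "false",
            ]
        )
    if lex.phrases:
        buf.write("\n")
        writer.writerow(_PHRASE_HEADER + ["direction"])
        for phrase in lex.phrases:
            writer.writerow([phrase.kind, phrase.pattern, phrase.scope, phrase.direction])
    return buf.getvalue()


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    Path(path).write_text(dumps_lexicon(lex), encoding="utf-8")


def default_lexicon() -> Lexicon:
    """The packaged default lexicon for 2012-2014 stage IV NSCLC regimens.

    Covers platinum agents, pemetrexed, bevacizumab, the first- and
    second-generation TKIs, and the common non-platinum cytotoxics, each with
    brand names, abbreviations and curated misspellings, plus default
    negation, uncertainty and no-treatment phrase lists.
    """
    data = resources.files("firstline.data").joinpath("default_lexicon.csv")
    lex = loads_lexicon(data.read_text(encoding="utf-8"), version="default-1")
    return lex


@dataclass(frozen=True)
class RawMatch:
    """A located variant match before negation annotation."""

    start: int
    end: int
    canonical: str
    drug_class: str
    variant: str


class CompiledMatcher:
    """A lexicon compiled to a single case-insensitive scanning regex.

    Longer variants are tried before shorter ones so that "carboplatin"
    beats "carbo" at the same position, and scanning is non-overlapping:
    a character position belongs to at most one match.
    """

    def __init__(self, lexicon: Lexicon):
        self.lexicon = lexicon
        self._groups: dict[str, tuple[str, str, str]] = {}
        alternatives: list[str] = []
        surfaces: list[tuple[str, DrugTerm]] = [
            (surface, term) for term in lexicon.terms for surface in term.surfaces
        ]
        # Longest-match preference across terms.
        surfaces.sort(key=lambda st: (-len(st[0]), st[0]))
        for i, (surface, term) in enumerate(surfaces):
            name = f"v{i}"
            try:
                pat = _surface_pattern(surface, term.match_as_word)
                re.compile(pat)
            except re.error as exc:
                raise LexiconError(
                    f"variant {surface!r} of {term.canonical!r} does not compile: {exc}"
                ) from exc
            self._groups[name] = (term.canonical, term.drug_class, surface)
            alternatives.append(f"(?P<{name}>{pat})")
        self._regex = re.compile("|".join(alternatives), re.IGNORECASE)

    def scan(self, text: str) -> list[RawMatch]:
        """All non-overlapping matches in ``text``, left to right."""
        out: list[RawMatch] = []
        for m in self._regex.finditer(text):
            canonical, drug_class, variant = self._groups[m.lastgroup]  # type: ignore[index]
            out.append(RawMatch(m.start(), m.end(), canonical, drug_class, variant))
        return out


def _surface_pattern(surface: str, match_as_word: bool) -> str:
    """Regex source for one variant: flexible internal separators, optional
    word boundaries."""
    parts = [re.escape(p) for p in _SEP_RE.split(surface) if p]
    pat = _SEP_PATTERN.join(parts) if parts else re.escape(surface)
    if match_as_word:
        pat = rf"\b(?:{pat})\b"
    return pat


def compile_lexicon(lex: Lexicon) -> CompiledMatcher:
    """Compile a validated lexicon into an opaque matcher."""
    return CompiledMatcher(lex)
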