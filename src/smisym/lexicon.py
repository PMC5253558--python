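"""Symptom lexicon: loading, validation and pattern compilation.

The lexicon defines the 50 severe-mental-illness (SMI) symptom constructs
targeted by the pipeline.  Each concept carries one or more keyword phrase
patterns (token sequences, trailing ``*`` = prefix match), optional modifier
patterns with a mode (``none`` / ``optional`` / ``mandatory``), SNOMED-CT
identifiers, a symptom domain (positive, negative, disorganisation, manic,
catatonic) and a status flag recording how the construct is handled
downstream:

``ml_model``
    a per-concept SVM sentence classifier is trained (43 concepts);
``keyword_only``
    the keyword match alone is accepted (mutism);
``hand_annotate``
    too rare to model — detected mentions are routed to human review
    (catalepsy, echopraxia);
``excluded``
    keyword too ambiguous for reliable modelling; not extracted
    (loosening of associations, stereotypy, low mood, poor motivation).

Two editions ship with the package: ``table1_verbatim`` (exact transcription
of the published keyword table) and ``curated`` (default; widens two keyword
patterns — ``hallucinat*``, ``flight of idea*`` — to the forms used in the
published worked examples).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "DOMAINS",
    "STATUSES",
    "MODIFIER_MODES",
    "LexiconError",
    "PhrasePattern",
    "SymptomConcept",
    "Lexicon",
    "parse_phrase",
    "token_matches",
    "phrase_matches_at",
    "compile_patterns",
    "load_lexicon",
    "save_lexicon",
    "default_lexicon",
    "domain_of",
]

DOMAINS = ("positive", "negative", "disorganisation", "manic", "catatonic")
STATUSES = ("ml_model", "keyword_only", "hand_annotate", "excluded")
MODIFIER_MODES = ("none", "optional", "mandatory")


class LexiconError(ValueError):
    """Raised for malformed or invalid lexicon content."""


# A phrase pattern is a tuple of token patterns; a token pattern ending in
# '*' matches any token sharing the prefix, otherwise the token must match
# exactly (always case-insensitive: patterns and tokens are lower-cased).
PhrasePattern = tuple[str, ...]


def parse_phrase(phrase: str) -> PhrasePattern:
    """Parse a whitespace-separated phrase into a token-pattern tuple."""
    toks = tuple(phrase.lower().split())
    if not toks:
        raise LexiconError(f"empty phrase pattern: {phrase!r}")
    for tok in toks:
        if "*" in tok[:-1] or tok == "*":
            raise LexiconError(
                f"'*' may only appear at the end of a token: {tok!r} in {phrase!r}"
            )
    return toks


def token_matches(pattern_token: str, token_text: str) -> bool:
    """Case-insensitive single-token match (trailing '*' = prefix match)."""
    text = token_text.lower()
    if pattern_token.endswith("*"):
        return text.startswith(pattern_token[:-1])
    return text == pattern_token


def phrase_matches_at(pattern: PhrasePattern, tokens: Sequence[str], start: int) -> bool:
    """Whether ``pattern`` matches the token texts beginning at ``start``."""
    if start + len(pattern) > len(tokens):
        return False
    return all(token_matches(p, tokens[start + i]) for i, p in enumerate(pattern))


@dataclass(frozen=True)
class SymptomConcept:
    """One lexicon row: a symptom construct and its matching rules."""

    name: str
    keyword_patterns: tuple[PhrasePattern, ...]
    modifier_patterns: tuple[PhrasePattern, ...] = ()
    modifier_mode: str = "none"
    snomed_ids: tuple[str, ...] = ()
    domain: str = "positive"
    status: str = "ml_model"

    def __post_init__(self) -> None:
        if not self.name:
            raise LexiconError("concept name must be non-empty")
        if not self.keyword_patterns:
            raise LexiconError(f"{self.name}: at least one keyword pattern required")
        if self.modifier_mode not in MODIFIER_MODES:
            raise LexiconError(f"{self.name}: bad modifier_mode {self.modifier_mode!r}")
        if (self.modifier_mode == "none") != (len(self.modifier_patterns) == 0):
            raise LexiconError(
                f"{self.name}: modifier_mode 'none' iff modifier list is empty"
            )
        if self.domain not in DOMAINS:
            raise LexiconError(f"{self.name}: bad domain {self.domain!r}")
        if self.status not in STATUSES:
            raise LexiconError(f"{self.name}: bad status {self.status!r}")

    @property
    def requires_modifier(self) -> bool:
        return self.modifier_mode == "mandatory"


@dataclass(frozen=True)
class CompiledConcept:
    """Matcher set for one concept (patterns are already token tuples)."""

    concept: SymptomConcept

    def keyword_matches_at(self, tokens: Sequence[str], start: int) -> list[int]:
        """Lengths of keyword patterns matching at ``start`` (may be several)."""
        return [
            len(p)
            for p in self.concept.keyword_patterns
            if phrase_matches_at(p, tokens, start)
        ]

    def modifier_matches_at(self, tokens: Sequence[str], start: int) -> list[tuple[PhrasePattern, int]]:
        return [
            (p, len(p))
            for p in self.concept.modifier_patterns
            if phrase_matches_at(p, tokens, start)
        ]


def compile_patterns(concept: SymptomConcept) -> CompiledConcept:
    """Return the matcher set for ``concept``.

    Patterns are stored pre-tokenised and lower-cased, so compilation is a
    thin wrapper; it exists so callers depend on the matcher interface, not
    on the pattern representation.
    """
    return CompiledConcept(concept)


@dataclass
class Lexicon:
    """An ordered collection of uniquely named symptom concepts."""

    concepts: list[SymptomConcept]
    version: str = "unversioned"
    _by_name: dict[str, SymptomConcept] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.concepts:
            raise LexiconError("a lexicon must contain at least one concept")
        self._by_name = {}
        for c in self.concepts:
            if c.name in self._by_name:
                raise LexiconError(f"duplicate concept name: {c.name!r}")
            self._by_name[c.name] = c

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self) -> Iterator[SymptomConcept]:
        return iter(self.concepts)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> SymptomConcept:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown concept: {name!r}") from None

    def active_concepts(self) -> list[SymptomConcept]:
        """Concepts that participate in extraction (status != excluded)."""
        return [c for c in self.concepts if c.status != "excluded"]

    def subset(self, names: Iterable[str]) -> "Lexicon":
        chosen = [self[n] for n in names]
        return Lexicon(chosen, version=f"{self.version}:subset")

    def domain_of(self, name: str) -> str:
        return self[name].domain


def domain_of(lexicon: Lexicon, name: str) -> str:
    """Symptom domain of ``name`` (KeyError for unknown concepts)."""
    return lexicon.domain_of(name)


_COLUMNS = ["concept", "keywords", "modifiers", "modifier_mode", "snomed_ids", "domain", "status"]


def _parse_row(row: dict[str, str], lineno: int) -> SymptomConcept:
    def split_field(value: str, sep: str) -> tuple[str, ...]:
        return tuple(s.strip() for s in value.split(sep) if s.strip())

    try:
        keywords = tuple(parse_phrase(p) for p in split_field(row["keywords"], "|"))
        modifiers = tuple(parse_phrase(p) for p in split_field(row["modifiers"], "|"))
        return SymptomConcept(
            name=row["concept"].strip(),
            keyword_patterns=keywords,
            modifier_patterns=modifiers,
            modifier_mode=row["modifier_mode"].strip(),
            snomed_ids=split_field(row["snomed_ids"], ","),
            domain=row["domain"].strip(),
            status=row["status"].strip(),
        )
    except LexiconError as exc:
        raise LexiconError(f"line {lineno}: {exc}") from None


def load_lexicon(path: str | Path, version: str | None = None) -> Lexicon:
    """Load and validate a lexicon from its TSV serialisation.

    The dialect: tab-separated, UTF-8, ``#`` comment lines, a header row
    naming the columns ``concept``, ``keywords`` (|-separated phrases),
    ``modifiers`` (|-separated, may be empty), ``modifier_mode``,
    ``snomed_ids`` (comma-separated), ``domain``, ``status``.
    """
    path = Path(path)
    rows: list[SymptomConcept] = []
    with open(path, encoding="utf-8", newline="") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = next(csv.reader([line], delimiter="\t"))
            if header is None:
                header = [f.strip() for f in fields]
                if header != _COLUMNS:
                    raise LexiconError(
                        f"{path}: line {lineno}: expected header {_COLUMNS}, got {header}"
                    )
                continue
            if len(fields) != len(_COLUMNS):
                raise LexiconError(
                    f"{path}: line {lineno}: expected {len(_COLUMNS)} fields, got {len(fields)}"
                )
            rows.append(_parse_row(dict(zip(_COLUMNS, fields)), lineno))
    if header is None or not rows:
        raise LexiconError(f"{path}: no lexicon rows found")
    return Lexicon(rows, version=version or path.stem)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Serialise a lexicon back to the TSV dialect read by :func:`load_lexicon`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for c in lexicon.concepts:
            writer.writerow(
                [
                    c.name,
                    "|".join(" ".join(p) for p in c.keyword_patterns),
                    "|".join(" ".join(p) for p in c.modifier_patterns),
                    c.modifier_mode,
                    ",".join(c.snomed_ids),
                    c.domain,
                    c.status,
                ]
            )


def default_lexicon(edition: str = "curated") -> Lexicon:
    """Load a shipped lexicon edition (``curated`` or ``table1_verbatim``)."""
    if edition not in ("curated", "table1_verbatim"):
        raise LexiconError(f"unknown lexicon edition: {edition!r}")
    ref = resources.files("smisym.data") / f"lexicon_{edition}.tsv"
    with resources.as_file(ref) as path:
        return load_lexicon(path, version=edition)
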