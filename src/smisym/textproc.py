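"""Document processing: sentence segmentation, tokenization, keyword and
modifier matching, and candidate-instance construction.

The unit of classification is the sentence.  A *candidate instance* is a
sentence containing a concept keyword match, plus — for concepts whose
modifier mode is mandatory — at least one modifier term within eight words
of the keyword.  "Word" for the window means a token containing at least
one letter or digit; punctuation-only tokens do not count.  The window is
measured between the nearest edges of the modifier and keyword spans,
excluding the spans themselves, in either direction, within one sentence.

All offsets are 0-based, half-open character offsets into the original
document string, so every span slices back to the exact source text.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

from .lexicon import Lexicon, SymptomConcept, compile_patterns

if TYPE_CHECKING:  # pragma: no cover
    from .context import ContextFlags

__all__ = [
    "Token",
    "Sentence",
    "KeywordMatch",
    "ModifierMatch",
    "CandidateInstance",
    "MODIFIER_WINDOW",
    "segment_sentences",
    "tokenize",
    "match_keywords",
    "attach_modifiers",
    "build_instances",
    "coarse_pos_tag",
]

MODIFIER_WINDOW = 8  # max intervening words between keyword and modifier

_TERMINALS = ".!?"
_STRIP = set(string.punctuation)


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int
    pos: str = "X"
    index: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty token span [{self.start},{self.end})")

    @property
    def is_word(self) -> bool:
        """True for tokens that count towards the modifier window."""
        return any(ch.isalnum() for ch in self.text)


@dataclass(frozen=True)
class Sentence:
    doc_id: str
    start: int
    end: int
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        prev_end = self.start
        for tok in self.tokens:
            if tok.start < prev_end or tok.end > self.end:
                raise ValueError(
                    f"token [{tok.start},{tok.end}) outside/overlapping in "
                    f"sentence [{self.start},{self.end})"
                )
            prev_end = tok.end

    @property
    def token_texts(self) -> tuple[str, ...]:
        return tuple(t.text for t in self.tokens)

    def text(self, document: str) -> str:
        return document[self.start : self.end]


@dataclass(frozen=True)
class KeywordMatch:
    concept: str
    first: int  # token index of first matched token
    last: int   # token index of last matched token (inclusive)
    matched_text: str

    @property
    def token_span(self) -> tuple[int, int]:
        return (self.first, self.last)


@dataclass(frozen=True)
class ModifierMatch:
    pattern: str        # matched modifier phrase pattern, space-joined
    first: int
    last: int
    matched_text: str
    distance: int       # intervening word-token count to the keyword span

    def __post_init__(self) -> None:
        if not (0 <= self.distance <= MODIFIER_WINDOW):
            raise ValueError(f"modifier distance {self.distance} outside window")


@dataclass
class CandidateInstance:
    """A sentence containing a concept keyword (the classification unit)."""

    doc_id: str
    sentence: Sentence
    concept: str
    keyword: KeywordMatch
    modifiers: tuple[ModifierMatch, ...] = ()
    context: Optional["ContextFlags"] = None

    def key(self) -> tuple[str, int, int, str]:
        """Identity of the instance: (doc_id, sentence span, concept)."""
        return (self.doc_id, self.sentence.start, self.sentence.end, self.concept)


# ---------------------------------------------------------------------------
# Segmentation and tokenization


def segment_sentences(text: str, doc_id: str = "") -> list[Sentence]:
    """Split a document into sentences with exact source offsets.

    Boundaries fall after runs of sentence-final punctuation (``.!?``) that
    are followed by whitespace or end-of-text, and at hard line breaks.
    Internal periods (``3.5``, ``F20.0``) do not split.  Whitespace-only
    segments are dropped; empty text yields an empty list.
    """
    sentences: list[Sentence] = []
    n = len(text)
    seg_start = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch == "\n":
            _append_sentence(sentences, text, doc_id, seg_start, i)
            seg_start = i + 1
            i += 1
            continue
        if ch in _TERMINALS:
            j = i
            while j + 1 < n and text[j + 1] in _TERMINALS:
                j += 1
            if j + 1 >= n or text[j + 1].isspace():
                _append_sentence(sentences, text, doc_id, seg_start, j + 1)
                seg_start = j + 1
            i = j + 1
            continue
        i += 1
    _append_sentence(sentences, text, doc_id, seg_start, n)
    return sentences


def _append_sentence(out: list[Sentence], text: str, doc_id: str, start: int, end: int) -> None:
    # trim surrounding whitespace so the span slices to visible text
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start >= end:
        return
    out.append(Sentence(doc_id, start, end, tokenize(text, start, end)))


def tokenize(text: str, start: int, end: int) -> tuple[Token, ...]:
    """Tokenize ``text[start:end]``: whitespace split, then peel leading and
    trailing punctuation off each chunk into separate tokens.  Internal
    punctuation (hyphens, apostrophes, decimal points) is kept."""
    raw: list[tuple[int, int]] = []
    i = start
    while i < end:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < end and not text[j].isspace():
            j += 1
        raw.extend(_split_punct(text, i, j))
        i = j
    tokens = tuple(
        Token(text[a:b], a, b, pos=coarse_pos_tag(text[a:b]), index=k)
        for k, (a, b) in enumerate(raw)
    )
    return tokens


def _split_punct(text: str, a: int, b: int) -> list[tuple[int, int]]:
    lead: list[tuple[int, int]] = []
    trail: list[tuple[int, int]] = []
    while a < b and text[a] in _STRIP:
        lead.append((a, a + 1))
        a += 1
    while b > a and text[b - 1] in _STRIP:
        trail.append((b - 1, b))
        b -= 1
    core = [(a, b)] if a < b else []
    return lead + core + list(reversed(trail))


# ---------------------------------------------------------------------------
# Coarse part-of-speech tagging (feature-only; never gates matching)

_POS_CLOSED = {
    "DET": {"the", "a", "an", "this", "that", "these", "those", "no", "any",
            "some", "each", "every", "his", "her", "their", "its", "our", "my"},
    "PRON": {"he", "she", "it", "they", "i", "we", "you", "him", "them",
             "himself", "herself", "who", "which", "what"},
    "ADP": {"of", "in", "on", "at", "by", "for", "with", "to", "from",
            "during", "over", "under", "about", "into", "within", "towards"},
    "CONJ": {"and", "or", "but", "nor", "so", "yet", "because", "although",
             "however", "if", "while", "when"},
    "AUX": {"is", "was", "are", "were", "be", "been", "being", "has", "have",
            "had", "will", "would", "can", "could", "may", "might", "should",
            "must", "does", "did", "do", "am"},
    "ADV": {"not", "very", "quite", "rather", "also", "still", "now", "today",
            "never", "always", "often", "sometimes"},
}
_POS_BY_WORD = {w: tag for tag, words in _POS_CLOSED.items() for w in words}


def coarse_pos_tag(token_text: str) -> str:
    """Heuristic coarse POS tag.

    A deterministic closed-class-list + suffix tagger; tags feed classifier
    features only, so coverage matters more than fine accuracy.
    """
    t = token_text.lower()
    if not any(ch.isalnum() for ch in t):
        return "PUNCT"
    if any(ch.isdigit() for ch in t):
        return "NUM"
    if t in _POS_BY_WORD:
        return _POS_BY_WORD[t]
    if t.endswith("ly"):
        return "ADV"
    if t.endswith(("ed", "ing", "ise", "ize", "ises", "izes")):
        return "VERB"
    if t.endswith(("ous", "ive", "ful", "less", "able", "ible", "al", "ant", "ent")):
        return "ADJ"
    return "NOUN"


# ---------------------------------------------------------------------------
# Matching


def _concept_matches(sentence: Sentence, concept: SymptomConcept) -> list[KeywordMatch]:
    """All keyword matches of one concept, reduced leftmost-longest."""
    texts = sentence.token_texts
    spans: list[tuple[int, int]] = []  # (first, last) inclusive
    matcher = compile_patterns(concept)
    for start in range(len(texts)):
        for length in matcher.keyword_matches_at(texts, start):
            spans.append((start, start + length - 1))
    # leftmost-longest, drop overlaps within this concept
    spans.sort(key=lambda s: (s[0], -(s[1] - s[0])))
    kept: list[tuple[int, int]] = []
    for first, last in spans:
        if kept and first <= kept[-1][1]:
            continue
        kept.append((first, last))
    return [
        KeywordMatch(
            concept=concept.name,
            first=first,
            last=last,
            matched_text=" ".join(texts[first : last + 1]),
        )
        for first, last in kept
    ]


def match_keywords(sentence: Sentence, lexicon: Lexicon) -> list[KeywordMatch]:
    """Every keyword match of every non-excluded concept in the sentence.

    Within a concept, overlapping matches are reduced to the
    leftmost-longest; matches from distinct concepts are all kept, even when
    they share tokens (shared keywords such as ``withdraw*`` or ``speech*``
    yield one match per concept).
    """
    out: list[KeywordMatch] = []
    for concept in lexicon.active_concepts():
        out.extend(_concept_matches(sentence, concept))
    return out


def _word_distance(sentence: Sentence, span_a: tuple[int, int], span_b: tuple[int, int]) -> int | None:
    """Intervening word-token count between two disjoint token spans."""
    if span_a[0] > span_b[1]:
        span_a, span_b = span_b, span_a
    elif span_a[1] >= span_b[0]:
        return None  # overlapping spans have no between-gap
    between = sentence.tokens[span_a[1] + 1 : span_b[0]]
    return sum(1 for t in between if t.is_word)


def attach_modifiers(
    match: KeywordMatch, sentence: Sentence, concept: SymptomConcept
) -> list[ModifierMatch]:
    """Modifier matches of ``concept`` within eight words of ``match``.

    Both directions are allowed; the distance is the number of intervening
    word tokens between the nearest span edges.  Modifier spans overlapping
    the keyword span are not attached.
    """
    if not concept.modifier_patterns:
        return []
    texts = sentence.token_texts
    out: list[ModifierMatch] = []
    matcher = compile_patterns(concept)
    for start in range(len(texts)):
        for pattern, length in matcher.modifier_matches_at(texts, start):
            span = (start, start + length - 1)
            dist = _word_distance(sentence, span, match.token_span)
            if dist is not None and dist <= MODIFIER_WINDOW:
                out.append(
                    ModifierMatch(
                        pattern=" ".join(pattern),
                        first=span[0],
                        last=span[1],
                        matched_text=" ".join(texts[span[0] : span[1] + 1]),
                        distance=dist,
                    )
                )
    return out


def build_instances(text: str, doc_id: str, lexicon: Lexicon) -> list[CandidateInstance]:
    """Candidate instances of every non-excluded concept in a document.

    One instance per (sentence, concept, keyword match).  Concepts with a
    mandatory modifier mode require at least one attached modifier; optional
    and modifier-free concepts require only the keyword.  Context flags are
    left unset (the context module fills them).
    """
    instances: list[CandidateInstance] = []
    if not text.strip():
        return instances
    for sentence in segment_sentences(text, doc_id):
        for match in match_keywords(sentence, lexicon):
            concept = lexicon[match.concept]
            modifiers = tuple(attach_modifiers(match, sentence, concept))
            if concept.requires_modifier and not modifiers:
                continue
            instances.append(
                CandidateInstance(
                    doc_id=doc_id,
                    sentence=sentence,
                    concept=concept.name,
                    keyword=match,
                    modifiers=modifiers,
                )
            )
    return instances
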