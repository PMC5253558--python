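"""Contextual-property detection for candidate instances.

A ConText-style rule layer: trigger phrases scanned in the sentence assign
negation, experiencer (patient vs other) and temporality (recent,
historical, hypothetical) to the keyword mention.  A forward trigger's
scope runs from the trigger to the end of the sentence, a backward
trigger's from the start of the sentence to the trigger; termination terms
("but", "however", ...) cut a scope short.  Pseudo-negation phrases
("no increase", ...) block negation by consuming the tokens that would
otherwise fire a shorter negation trigger: overlapping trigger matches are
resolved leftmost-longest, with pseudo-negation winning length ties.

The resulting flags serve two purposes: features for the SVM sentence
classifier, and a rules-only baseline label (`context_only_label`) against
which the hybrid classifier is compared.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from .lexicon import LexiconError, PhrasePattern, parse_phrase, phrase_matches_at
from .textproc import CandidateInstance, Sentence

__all__ = [
    "CONTEXT_PROPERTIES",
    "ContextFlags",
    "Trigger",
    "TriggerTable",
    "load_triggers",
    "default_triggers",
    "apply_context",
    "context_only_label",
]

CONTEXT_PROPERTIES = (
    "negation",
    "pseudo_negation",
    "experiencer",
    "historical",
    "hypothetical",
)
_DIRECTIONS = ("forward", "backward", "both")
_ACTIONS = ("set", "terminate")


@dataclass(frozen=True)
class ContextFlags:
    """Contextual properties of one keyword mention.

    ``triggers`` records every applied (phrase, property, scope token span)
    so each non-default flag is justified by at least one entry.
    """

    negated: bool = False
    experiencer: str = "patient"       # {patient, other}
    temporality: str = "recent"        # {recent, historical, hypothetical}
    triggers: tuple[tuple[str, str, tuple[int, int]], ...] = ()


@dataclass(frozen=True)
class Trigger:
    phrase: PhrasePattern
    property: str
    direction: str
    action: str

    def __post_init__(self) -> None:
        if self.property not in CONTEXT_PROPERTIES:
            raise LexiconError(f"bad trigger property {self.property!r}")
        if self.direction not in _DIRECTIONS:
            raise LexiconError(f"bad trigger direction {self.direction!r}")
        if self.action not in _ACTIONS:
            raise LexiconError(f"bad trigger action {self.action!r}")


@dataclass(frozen=True)
class TriggerTable:
    triggers: tuple[Trigger, ...]

    def __add__(self, other: "TriggerTable") -> "TriggerTable":
        return TriggerTable(self.triggers + other.triggers)

    def __len__(self) -> int:
        return len(self.triggers)


_COLUMNS = ["phrase", "property", "direction", "action"]


def load_triggers(path: str | Path) -> TriggerTable:
    """Load a trigger table from TSV (columns phrase/property/direction/action,
    ``#`` comments, UTF-8)."""
    path = Path(path)
    rows: list[Trigger] = []
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
                raise LexiconError(f"{path}: line {lineno}: expected 4 fields")
            try:
                rows.append(
                    Trigger(
                        phrase=parse_phrase(fields[0]),
                        property=fields[1].strip(),
                        direction=fields[2].strip(),
                        action=fields[3].strip(),
                    )
                )
            except LexiconError as exc:
                raise LexiconError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise LexiconError(f"{path}: no trigger rows found")
    return TriggerTable(tuple(rows))


@lru_cache(maxsize=4)
def default_triggers(uk_overlay: bool = False) -> TriggerTable:
    """The shipped base trigger table, optionally with the UK-dialect overlay."""
    base_ref = resources.files("smisym.data") / "context_triggers.tsv"
    with resources.as_file(base_ref) as path:
        table = load_triggers(path)
    if uk_overlay:
        ov_ref = resources.files("smisym.data") / "context_triggers_uk_overlay.tsv"
        with resources.as_file(ov_ref) as path:
            table = table + load_triggers(path)
    return table


# ---------------------------------------------------------------------------
# Matching and scope resolution


@dataclass(frozen=True)
class _TriggerMatch:
    trigger: Trigger
    first: int
    last: int  # inclusive


def _find_trigger_matches(sentence: Sentence, table: TriggerTable) -> list[_TriggerMatch]:
    """All trigger matches, resolved leftmost-longest over shared tokens.

    At each position the longest matching phrase wins; pseudo-negation wins
    length ties so it can mask shorter negation triggers.  The winning match
    consumes its tokens: no other trigger may start inside it.
    """
    texts = sentence.token_texts
    n = len(texts)
    out: list[_TriggerMatch] = []
    i = 0
    while i < n:
        candidates: list[tuple[int, int, Trigger]] = []  # (length, pseudo-priority, trig)
        for trig in table.triggers:
            if phrase_matches_at(trig.phrase, texts, i):
                pseudo = 1 if trig.property == "pseudo_negation" else 0
                candidates.append((len(trig.phrase), pseudo, trig))
        if not candidates:
            i += 1
            continue
        length = max(c[0] for c in candidates)
        best = [c for c in candidates if c[0] == length]
        best.sort(key=lambda c: -c[1])
        # every equally long winner at this locus is kept (e.g. the same
        # termination term for several properties)
        top_pseudo = best[0][1]
        for _, pseudo, trig in best:
            if pseudo == top_pseudo:
                out.append(_TriggerMatch(trig, i, i + length - 1))
        i += length
    return out


def _scope(
    m: _TriggerMatch, n_tokens: int, terminators: list[_TriggerMatch]
) -> list[tuple[int, int]]:
    """Scope token ranges (inclusive) of a set-action trigger match."""
    spans: list[tuple[int, int]] = []
    same_prop = [t for t in terminators if t.trigger.property == m.trigger.property]
    if m.trigger.direction in ("forward", "both"):
        lo, hi = m.last + 1, n_tokens - 1
        for t in same_prop:
            if t.first > m.last:
                hi = min(hi, t.first - 1)
        if lo <= hi:
            spans.append((lo, hi))
    if m.trigger.direction in ("backward", "both"):
        lo, hi = 0, m.first - 1
        for t in same_prop:
            if t.last < m.first:
                lo = max(lo, t.last + 1)
        if lo <= hi:
            spans.append((lo, hi))
    return spans


def apply_context(
    instance: CandidateInstance, table: TriggerTable | None = None
) -> ContextFlags:
    """Compute the context flags for an instance's keyword mention.

    Deterministic given the sentence and the keyword span.  A property
    applies iff the keyword span lies entirely inside a set-trigger's scope.
    When both historical and hypothetical triggers cover the keyword,
    hypothetical wins (the more conservative reading for labelling).
    """
    if table is None:
        table = default_triggers()
    sentence = instance.sentence
    kw = instance.keyword
    matches = _find_trigger_matches(sentence, table)
    terminators = [m for m in matches if m.trigger.action == "terminate"]
    setters = [m for m in matches if m.trigger.action == "set"]

    negated = False
    experiencer = "patient"
    hist = False
    hypo = False
    applied: list[tuple[str, str, tuple[int, int]]] = []
    n = len(sentence.tokens)
    for m in setters:
        if m.trigger.property == "pseudo_negation":
            continue  # blocking is handled by token consumption in matching
        for lo, hi in _scope(m, n, terminators):
            if lo <= kw.first and kw.last <= hi:
                applied.append((" ".join(m.trigger.phrase), m.trigger.property, (lo, hi)))
                if m.trigger.property == "negation":
                    negated = True
                elif m.trigger.property == "experiencer":
                    experiencer = "other"
                elif m.trigger.property == "historical":
                    hist = True
                elif m.trigger.property == "hypothetical":
                    hypo = True
                break
    temporality = "hypothetical" if hypo else ("historical" if hist else "recent")
    return ContextFlags(
        negated=negated,
        experiencer=experiencer,
        temporality=temporality,
        triggers=tuple(applied),
    )


def context_only_label(flags: ContextFlags) -> str:
    """Rules-only binary label: positive iff the mention is an affirmed,
    patient-experienced, non-hypothetical observation."""
    if flags.negated or flags.experiencer != "patient" or flags.temporality == "hypothetical":
        return "negative"
    return "positive"
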