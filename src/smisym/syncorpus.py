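"""Seeded synthetic discharge-summary generator with a gold ledger.

The study corpus behind this method is a protected clinical database, so
every downstream module is exercised on synthetic documents with planted,
gold-labelled symptom mentions.  Templates are deliberately stylised
mental-state-examination phrasing: the generator tests extraction and
classification mechanics, not linguistic generality.

Each planted mention belongs to one of five context classes:

``affirmed``
    plain clinical observation (expected label: positive);
``negated``
    negation phrasing; a third of the negated templates use UK-dialect
    negation ("nil ...") that the base US-English trigger table does not
    cover, emulating the dialect gap that costs a rules-only system
    precision;
``hypothetical``
    screening / conditional phrasing ("examined the patient for ...");
``other_experiencer``
    symptom attributed to a relative;
``irrelevant_homograph``
    the keyword used in a non-clinical sense ("a leaflet on paranoia ...").

Only ``affirmed`` plants are expected positives.  All randomness flows
from one seed through named child streams (patients, docs, mentions,
context, templates, fillers, shuffle — spawned in that fixed order), so
adding draws to one purpose never shifts another's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .classifier import LabelledInstance
from .context import TriggerTable, apply_context, default_triggers
from .corpus import Document
from .lexicon import Lexicon, default_lexicon
from .textproc import CandidateInstance, build_instances

__all__ = [
    "CONTEXT_CLASSES",
    "DEFAULT_CONCEPTS",
    "GeneratorConfig",
    "PlantRecord",
    "GoldLedger",
    "generate_corpus",
    "make_training_set",
    "extract_instances",
    "MENTION_REALISATIONS",
]

CONTEXT_CLASSES = (
    "affirmed",
    "negated",
    "hypothetical",
    "other_experiencer",
    "irrelevant_homograph",
)

DEFAULT_CONCEPTS = (
    "Paranoia",
    "Hallucinations",
    "Poverty of speech",
    "Elevated mood",
    "Poor rapport",
)

# Surface realisations per concept.  Every phrase must satisfy the
# concept's instance definition (keyword + mandatory modifier within the
# window) and contain no other active concept's keyword; tests assert both.
MENTION_REALISATIONS: dict[str, tuple[str, ...]] = {
    "Paranoia": ("paranoia", "paranoid ideation"),
    "Hallucinations": ("auditory hallucinations", "visual hallucinations", "hallucinations"),
    "Poverty of speech": ("poverty of speech", "impoverished speech"),
    "Elevated mood": ("elevated mood", "mood that was elevated"),
    "Poor rapport": ("poor rapport", "limited rapport"),
    "Delusions": ("delusions", "delusional beliefs"),
    "Aggression": ("aggression", "aggressive behaviour"),
    "Agitation": ("agitation",),
    "Grandiosity": ("grandiosity", "grandiose ideas"),
    "Insomnia": ("insomnia",),
    "Disturbed sleep": ("poor sleep", "disturbed sleep"),
    "Pressured speech": ("pressured speech", "pressure of speech"),
    "Diminished eye contact": ("reduced eye contact",),
    "Tangential speech": ("tangentiality",),
    "Thought block": ("thought block",),
}

_AFFIRMED = (
    "He displayed prominent {m} on examination.",
    "She continues to experience {m}.",
    "There was clear evidence of {m} during the ward round.",
    "Ongoing {m} was observed by nursing staff.",
    "He presented with {m} at interview.",
    "Staff observed {m} throughout the admission.",
)
_NEGATED = (
    "There was no evidence of {m}.",
    "She denies {m}.",
    "He did not exhibit {m}.",
    "No {m} was elicited at interview.",
    "Nil {m} reported today.",        # UK dialect, uncovered by base triggers
    "Nil {m} on review.",             # UK dialect, uncovered by base triggers
)
_HYPOTHETICAL = (
    "I examined the patient for {m} today.",
    "Return to clinic if {m} develops.",
    "We will screen for {m} at the next review.",
    "Staff will monitor for {m} overnight.",
)
_OTHER = (
    "His mother has a history of {m}.",
    "Her brother suffers from {m}.",
    "There is a family history of {m} in this case.",
)
_HOMOGRAPH = (
    "A leaflet on {m} was given at discharge.",
    "The {m} support group meets every Tuesday.",
    "She attended a talk on {m} at the recovery college.",
)
_TEMPLATES = {
    "affirmed": _AFFIRMED,
    "negated": _NEGATED,
    "hypothetical": _HYPOTHETICAL,
    "other_experiencer": _OTHER,
    "irrelevant_homograph": _HOMOGRAPH,
}

# Filler sentences: verified keyword-free against the shipped lexicon.
_FILLERS = (
    "He attended the ward round with the team.",
    "Medication was continued at the current dose.",
    "The care plan was reviewed and updated.",
    "She engaged well with occupational therapy.",
    "Follow-up was arranged with the community team.",
    "He remained settled on the ward overnight.",
    "Physical observations were within normal limits.",
    "The discharge planning meeting took place on Tuesday.",
)

_GROUP_CODES = {
    "F20": (("F20.0",), ("F20.1",)),
    "F25": (("F25.1",), ("F25.0",)),
    "F31": (("F31.2",), ("F31.4",)),
    "Multiple": (("F20.0", "F31.2"), ("F25.1", "F31.4")),
    "NonSMI": (("F33.1",), ("F41.1",), ("F60.3",), ("F32.0",)),
    "Unclassified": ((), ("F32.3",)),
}


class GeneratorConfig(BaseModel):
    """Study conditions for one synthetic corpus (identical config + seed
    yields an identical corpus)."""

    n_patients: int = Field(300, gt=0)
    mean_docs_per_patient: float = Field(3.0, ge=1.0)
    concepts: tuple[str, ...] = DEFAULT_CONCEPTS
    mention_rate: float = Field(0.8, ge=0.0)  # Poisson mean per concept per doc
    context_mix: dict[str, float] = {
        "affirmed": 0.55,
        "negated": 0.20,
        "hypothetical": 0.10,
        "other_experiencer": 0.075,
        "irrelevant_homograph": 0.075,
    }
    diagnosis_mix: dict[str, float] = {
        "F20": 0.25,
        "F25": 0.10,
        "F31": 0.15,
        "Multiple": 0.10,
        "NonSMI": 0.30,
        "Unclassified": 0.10,
    }
    fillers_per_doc: tuple[int, int] = (2, 6)
    seed: int = 0

    @field_validator("context_mix", "diagnosis_mix")
    @classmethod
    def _proportions(cls, v: dict[str, float]) -> dict[str, float]:
        if any(p < 0 for p in v.values()):
            raise ValueError("proportions must be non-negative")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(v.values())}")
        return v

    @model_validator(mode="after")
    def _keys(self) -> "GeneratorConfig":
        if set(self.context_mix) - set(CONTEXT_CLASSES):
            raise ValueError(f"unknown context classes: {set(self.context_mix) - set(CONTEXT_CLASSES)}")
        if set(self.diagnosis_mix) - set(_GROUP_CODES):
            raise ValueError(f"unknown diagnosis groups: {set(self.diagnosis_mix) - set(_GROUP_CODES)}")
        lo, hi = self.fillers_per_doc
        if not 0 <= lo <= hi:
            raise ValueError("fillers_per_doc must be an ordered non-negative pair")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True),
            encoding="utf-8",
        )


@dataclass(frozen=True)
class PlantRecord:
    doc_id: str
    sentence_start: int
    sentence_end: int
    concept: str
    context_class: str
    expected_label: str  # positive iff context_class == affirmed


@dataclass
class GoldLedger:
    """Ground truth for a generated corpus: every planted mention, and the
    per-patient truth table of (affirmed) symptoms."""

    records: list[PlantRecord]
    truth: dict[str, frozenset[str]]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for r in self.records:
                fh.write(json.dumps({"type": "plant", **r.__dict__}, sort_keys=True) + "\n")
            for pid in sorted(self.truth):
                fh.write(
                    json.dumps(
                        {"type": "truth", "patient_id": pid, "symptoms": sorted(self.truth[pid])},
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "GoldLedger":
        records, truth = [], {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                kind = rec.pop("type")
                if kind == "plant":
                    records.append(PlantRecord(**rec))
                else:
                    truth[rec["patient_id"]] = frozenset(rec["symptoms"])
        return cls(records, truth)


class SynthesisError(ValueError):
    pass


def generate_corpus(
    config: GeneratorConfig, lexicon: Lexicon | None = None
) -> tuple[list[Document], GoldLedger]:
    """Generate documents and their gold ledger from ``config``.

    Raises ``SynthesisError`` for concepts missing from the lexicon,
    excluded there, or without shipped surface realisations.
    """
    lexicon = lexicon or default_lexicon()
    for name in config.concepts:
        if name not in lexicon:
            raise SynthesisError(f"concept {name!r} not in lexicon")
        if lexicon[name].status == "excluded":
            raise SynthesisError(f"concept {name!r} is excluded from extraction")
        if name not in MENTION_REALISATIONS:
            raise SynthesisError(f"no surface realisations shipped for {name!r}")

    names = ("patients", "docs", "mentions", "context", "templates", "fillers", "shuffle")
    streams = dict(zip(names, map(np.random.default_rng, np.random.SeedSequence(config.seed).spawn(len(names)))))

    ctx_classes = list(config.context_mix)
    ctx_probs = np.array([config.context_mix[c] for c in ctx_classes])
    dx_groups = list(config.diagnosis_mix)
    dx_probs = np.array([config.diagnosis_mix[g] for g in dx_groups])

    documents: list[Document] = []
    records: list[PlantRecord] = []
    truth: dict[str, set[str]] = {}
    doc_counter = 0
    lo, hi = config.fillers_per_doc

    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        group = dx_groups[streams["patients"].choice(len(dx_groups), p=dx_probs)]
        variants = _GROUP_CODES[group]
        codes = variants[streams["patients"].integers(len(variants))]
        truth[pid] = set()
        n_docs = 1 + streams["docs"].poisson(config.mean_docs_per_patient - 1.0)
        for _ in range(n_docs):
            doc_id = f"D{doc_counter:06d}"
            doc_counter += 1
            planted: list[tuple[str, str, str]] = []  # (sentence, concept, class)
            for concept in config.concepts:
                for _ in range(streams["mentions"].poisson(config.mention_rate)):
                    cls = ctx_classes[streams["context"].choice(len(ctx_classes), p=ctx_probs)]
                    bank = _TEMPLATES[cls]
                    template = bank[streams["templates"].integers(len(bank))]
                    reals = MENTION_REALISATIONS[concept]
                    if cls == "irrelevant_homograph":
                        mention = reals[0]
                    else:
                        mention = reals[streams["templates"].integers(len(reals))]
                    planted.append((template.format(m=mention), concept, cls))
                    if cls == "affirmed":
                        truth[pid].add(concept)
            n_fill = int(streams["fillers"].integers(lo, hi + 1))
            fillers = [
                _FILLERS[streams["fillers"].integers(len(_FILLERS))] for _ in range(n_fill)
            ]
            slots: list[tuple[str, str | None, str | None]] = [
                (s, c, k) for s, c, k in planted
            ] + [(f, None, None) for f in fillers]
            order = streams["shuffle"].permutation(len(slots))
            offset = 0
            parts: list[str] = []
            for idx in order:
                sent, concept, cls = slots[idx]
                start = offset
                parts.append(sent)
                end = start + len(sent)
                offset = end + 1  # single joining space
                if concept is not None:
                    records.append(
                        PlantRecord(
                            doc_id=doc_id,
                            sentence_start=start,
                            sentence_end=end,
                            concept=concept,
                            context_class=cls,  # type: ignore[arg-type]
                            expected_label="positive" if cls == "affirmed" else "negative",
                        )
                    )
            documents.append(
                Document(
                    doc_id=doc_id,
                    patient_id=pid,
                    text=" ".join(parts),
                    icd10_codes=tuple(codes),
                    date="2014-01-01",
                )
            )
    ledger = GoldLedger(records, {p: frozenset(s) for p, s in truth.items()})
    return documents, ledger


def extract_instances(
    document: Document,
    lexicon: Lexicon | None = None,
    triggers: TriggerTable | None = None,
) -> list[CandidateInstance]:
    """Build candidate instances for a document and fill their context flags."""
    lexicon = lexicon or default_lexicon()
    triggers = triggers or default_triggers()
    instances = build_instances(document.text, document.doc_id, lexicon)
    for inst in instances:
        inst.context = apply_context(inst, triggers)
    return instances


def make_training_set(
    documents: Sequence[Document],
    ledger: GoldLedger,
    concept: str,
    lexicon: Lexicon | None = None,
    triggers: TriggerTable | None = None,
) -> list[LabelledInstance]:
    """Human-equivalent labels for every extracted instance of ``concept``.

    Extracted instances are joined to the ledger on (doc_id, concept,
    overlapping sentence span); the expected label is positive only for
    affirmed plants.  Instances found outside the ledger (homograph or
    incidental keyword occurrences) are labelled negative.  A ledger
    referring to documents absent from the corpus is an error.
    """
    doc_ids = {d.doc_id for d in documents}
    ledger_doc_ids = {rec.doc_id for rec in ledger.records}
    if documents and ledger.records and not (doc_ids & ledger_doc_ids):
        raise SynthesisError(
            "ledger/corpus mismatch: no ledger record refers to any supplied document"
        )
    plants: dict[str, list[PlantRecord]] = {}
    for rec in ledger.records:
        if rec.doc_id in doc_ids and rec.concept == concept:
            plants.setdefault(rec.doc_id, []).append(rec)
    out: list[LabelledInstance] = []
    for doc in documents:
        for inst in extract_instances(doc, lexicon, triggers):
            if inst.concept != concept:
                continue
            label = "negative"
            for rec in plants.get(doc.doc_id, ()):
                if inst.sentence.start < rec.sentence_end and rec.sentence_start < inst.sentence.end:
                    label = rec.expected_label
                    break
            out.append(LabelledInstance(instance=inst, label=label, source="human"))
    return out
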