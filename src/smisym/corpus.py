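"""Corpus records and line-delimited serialisation.

A corpus is a JSON-lines file of document records with fields ``doc_id``,
``patient_id``, ``doc_type``, ``date``, ``icd10_codes`` and ``text``.
Candidate instances and labelled instances serialise to JSON-lines with
0-based half-open character offsets so every span audits back to the
source document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .classifier import LabelledInstance
from .textproc import CandidateInstance

__all__ = [
    "Document",
    "read_corpus",
    "write_corpus",
    "instance_to_record",
    "write_instances",
    "read_instances",
]


@dataclass(frozen=True)
class Document:
    doc_id: str
    patient_id: str
    text: str
    doc_type: str = "discharge_summary"
    date: str = ""
    icd10_codes: tuple[str, ...] = ()

    def to_record(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "patient_id": self.patient_id,
            "doc_type": self.doc_type,
            "date": self.date,
            "icd10_codes": list(self.icd10_codes),
            "text": self.text,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Document":
        return cls(
            doc_id=str(rec["doc_id"]),
            patient_id=str(rec["patient_id"]),
            text=rec["text"],
            doc_type=rec.get("doc_type", "discharge_summary"),
            date=rec.get("date", ""),
            icd10_codes=tuple(rec.get("icd10_codes", ())),
        )


def write_corpus(documents: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(json.dumps(doc.to_record(), sort_keys=True) + "\n")


def read_corpus(path: str | Path) -> list[Document]:
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                docs.append(Document.from_record(json.loads(line)))
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}: line {lineno}: bad corpus record ({exc})")
    return docs


def instance_to_record(
    inst: CandidateInstance, label: str | None = None, confidence: float | None = None
) -> dict:
    sent = inst.sentence
    rec = {
        "doc_id": inst.doc_id,
        "concept": inst.concept,
        "sentence_start": sent.start,
        "sentence_end": sent.end,
        "keyword_text": inst.keyword.matched_text,
        "keyword_tokens": [inst.keyword.first, inst.keyword.last],
        "modifiers": [
            {"pattern": m.pattern, "text": m.matched_text, "distance": m.distance}
            for m in inst.modifiers
        ],
    }
    if inst.context is not None:
        rec["context"] = {
            "negated": inst.context.negated,
            "experiencer": inst.context.experiencer,
            "temporality": inst.context.temporality,
        }
    if label is not None:
        rec["label"] = label
    if confidence is not None:
        rec["confidence"] = confidence
    return rec


def write_instances(
    items: Sequence[CandidateInstance] | Sequence[LabelledInstance], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for item in items:
            if isinstance(item, LabelledInstance):
                rec = instance_to_record(item.instance, item.label, item.confidence)
            else:
                rec = instance_to_record(item)
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_instances(path: str | Path) -> list[dict]:
    """Read instance records (audit/prediction files) as plain dicts."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(json.loads(line))
    return out
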