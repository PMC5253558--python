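"""Patient-level symptom profiles, diagnosis-group crosstabs and coverage.

Diagnosis groups follow the ICD-10 code families: SMI = schizophrenia
(F20x), schizoaffective disorder (F25x), bipolar disorder (F31x), with
``Multiple`` for patients carrying more than one distinct SMI family.
The non-SMI comparison group is F32 (excluding F32.3), F33 (excluding
F33.3), F40–F48 or F60 with no SMI code; the two psychotic-depression
codes are excluded so the cohorts cannot overlap.  Everything else is
``Unclassified`` and is dropped from crosstabs (with a logged count).

A patient *has* a symptom iff at least one instance of that concept is
labelled positive in any of their documents — unique-patient semantics
throughout.  Percentages are rounded half-away-from-zero to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classifier import POSITIVE, LabelledInstance
from .corpus import Document
from .lexicon import DOMAINS, Lexicon

__all__ = [
    "DIAGNOSIS_GROUPS",
    "SMI_GROUPS",
    "PatientProfile",
    "assign_diagnosis_group",
    "build_profiles",
    "crosstab_domains",
    "coverage_stats",
    "CoverageReport",
    "add_total_row",
    "round_half_up_pct",
]

DIAGNOSIS_GROUPS = ("F20", "F25", "F31", "Multiple", "NonSMI", "Unclassified")
Prediction = LabelledInstance | Mapping  # labelled instance or its JSON record


def _as_triple(item: Prediction) -> tuple[str, str, str]:
    """Normalise a prediction to (doc_id, concept, label)."""
    if isinstance(item, LabelledInstance):
        return item.instance.doc_id, item.instance.concept, item.label
    return str(item["doc_id"]), str(item["concept"]), str(item["label"])
SMI_GROUPS = ("F20", "F25", "F31", "Multiple")
_SMI_FAMILIES = ("F20", "F25", "F31")
_NONSMI_EXCLUDED = ("F32.3", "F33.3")


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    diagnosis_group: str
    symptoms: frozenset[str]
    domains: frozenset[str]
    n_documents: int


def assign_diagnosis_group(icd10_codes: Sequence[str]) -> str:
    """Deterministic diagnosis-group mapping from a patient's ICD-10 codes.

    SMI families take precedence over non-SMI codes; ``Multiple`` requires
    at least two distinct SMI families (F20/F25/F31), not merely two codes.
    An empty list maps to ``Unclassified``.
    """
    codes = [c.strip().upper() for c in icd10_codes if c.strip()]
    smi = {fam for fam in _SMI_FAMILIES if any(c.startswith(fam) for c in codes)}
    if len(smi) > 1:
        return "Multiple"
    if len(smi) == 1:
        return smi.pop()
    for code in codes:
        if any(code.startswith(x) for x in _NONSMI_EXCLUDED):
            continue
        if code.startswith(("F32", "F33", "F60")):
            return "NonSMI"
        if code.startswith("F4") and code[:3] in {f"F4{i}" for i in range(9)}:
            return "NonSMI"
    return "Unclassified"


def build_profiles(
    predictions: Sequence[Prediction],
    documents: Sequence[Document],
    lexicon: Lexicon,
) -> list[PatientProfile]:
    """Patient symptom profiles from model-labelled instances.

    Every patient with at least one document gets a profile (possibly with
    no symptoms).  Predictions referring to unknown documents are errors.
    """
    by_doc = {d.doc_id: d for d in documents}
    patients: dict[str, dict] = {}
    for doc in documents:
        if not doc.patient_id:
            raise ValueError(f"document {doc.doc_id!r} has no patient_id")
        entry = patients.setdefault(
            doc.patient_id, {"codes": set(), "n_docs": 0, "symptoms": set()}
        )
        entry["codes"].update(doc.icd10_codes)
        entry["n_docs"] += 1
    for li in predictions:
        doc_id, concept, label = _as_triple(li)
        doc = by_doc.get(doc_id)
        if doc is None:
            raise ValueError(f"prediction references unknown doc_id {doc_id!r}")
        if label == POSITIVE:
            patients[doc.patient_id]["symptoms"].add(concept)
    profiles = []
    for pid in sorted(patients):
        entry = patients[pid]
        symptoms = frozenset(entry["symptoms"])
        profiles.append(
            PatientProfile(
                patient_id=pid,
                diagnosis_group=assign_diagnosis_group(sorted(entry["codes"])),
                symptoms=symptoms,
                domains=frozenset(lexicon.domain_of(s) for s in symptoms),
                n_documents=entry["n_docs"],
            )
        )
    return profiles


def add_total_row(table: pd.DataFrame, label: str = "Total") -> pd.DataFrame:
    """Append a column-sum Total row (the crosstab totalling rule)."""
    out = table.copy()
    out.loc[label] = table.sum(axis=0)
    return out


def crosstab_domains(profiles: Sequence[PatientProfile]) -> pd.DataFrame:
    """Unique-patient counts by diagnosis group × symptom domain, plus a
    Total row summed over the five groups.  Unclassified patients are
    dropped; their count is recorded in ``df.attrs["n_unclassified"]``."""
    if not profiles:
        raise ValueError("no profiles supplied")
    groups = [g for g in DIAGNOSIS_GROUPS if g != "Unclassified"]
    counts = pd.DataFrame(0, index=groups, columns=list(DOMAINS))
    n_unclassified = 0
    for p in profiles:
        if p.diagnosis_group == "Unclassified":
            n_unclassified += 1
            continue
        for domain in p.domains:
            counts.loc[p.diagnosis_group, domain] += 1
    out = add_total_row(counts)
    out.attrs["n_unclassified"] = n_unclassified
    return out


def round_half_up_pct(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-away-from-zero (so 86.5 -> 87)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class CoverageReport:
    cohort: str
    n_symptom_instances: int
    n_documents: int
    n_documents_covered: int
    pct_documents: int
    n_patients: int
    n_patients_covered: int
    pct_patients: int


def coverage_stats(
    predictions: Sequence[Prediction],
    documents: Sequence[Document],
    profiles: Sequence[PatientProfile],
) -> dict[str, CoverageReport]:
    """Per-cohort coverage: positive instance totals, documents with at
    least one positive instance, and patients with at least one symptom
    (of those with at least one document)."""
    by_doc = {d.doc_id: d for d in documents}
    group_of = {p.patient_id: p.diagnosis_group for p in profiles}

    def cohort_of(patient_id: str) -> str | None:
        g = group_of.get(patient_id)
        if g in SMI_GROUPS:
            return "SMI"
        if g == "NonSMI":
            return "NonSMI"
        return None

    stats = {
        c: {"instances": 0, "docs": set(), "covered_docs": set(), "patients": set(), "covered_patients": set()}
        for c in ("SMI", "NonSMI")
    }
    for doc in documents:
        c = cohort_of(doc.patient_id)
        if c:
            stats[c]["docs"].add(doc.doc_id)
            stats[c]["patients"].add(doc.patient_id)
    for li in predictions:
        doc_id, _concept, label = _as_triple(li)
        if label != POSITIVE:
            continue
        doc = by_doc[doc_id]
        c = cohort_of(doc.patient_id)
        if c:
            stats[c]["instances"] += 1
            stats[c]["covered_docs"].add(doc.doc_id)
            stats[c]["covered_patients"].add(doc.patient_id)
    out = {}
    for cohort, s in stats.items():
        if not s["docs"]:
            raise ValueError(f"cohort {cohort!r} contains no documents")
        out[cohort] = CoverageReport(
            cohort=cohort,
            n_symptom_instances=s["instances"],
            n_documents=len(s["docs"]),
            n_documents_covered=len(s["covered_docs"]),
            pct_documents=round_half_up_pct(len(s["covered_docs"]), len(s["docs"])),
            n_patients=len(s["patients"]),
            n_patients_covered=len(s["covered_patients"]),
            pct_patients=round_half_up_pct(len(s["covered_patients"]), len(s["patients"])),
        )
    return out
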