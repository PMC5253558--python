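"""Gold-standard validation, inter-annotator agreement, and cross-arm
summaries.

Metrics are computed over the positive class only (precision, recall, F1
of affirmed symptom mentions), matching the binary annotation scheme.
Undefined ratios (zero denominators) are reported as missing values, never
as zeros, and are excluded from cross-concept aggregates with a footnote
count — averaging in zeros would silently bias the summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import POSITIVE, LabelledInstance

__all__ = [
    "AlignmentError",
    "PRFReport",
    "AgreementReport",
    "GoldStandardReport",
    "score_predictions",
    "cohens_kappa",
    "validate_gold_standard",
    "summarize_across_concepts",
    "MIN_GOLD_POSITIVES",
]

MIN_GOLD_POSITIVES = 100  # working criterion for an adequate gold standard


class AlignmentError(ValueError):
    """Gold and predicted instance sets do not describe the same instances."""


@dataclass(frozen=True)
class PRFReport:
    """Positive-class confusion counts and derived metrics for one concept.

    ``precision``/``recall``/``f1`` are ``None`` when their denominator is
    zero (e.g. no predicted positives).
    """

    concept: str
    true_pos: int
    false_pos: int
    false_neg: int

    @property
    def precision(self) -> Optional[float]:
        d = self.true_pos + self.false_pos
        return self.true_pos / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.true_pos + self.false_neg
        return self.true_pos / d if d else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)


@dataclass(frozen=True)
class AgreementReport:
    """Inter-annotator agreement for one concept."""

    concept: str
    n_instances: int
    observed_agreement: float
    kappa: float
    degenerate: bool = False  # both raters constant and identical

    def __post_init__(self) -> None:
        if not 0 <= self.observed_agreement <= 1:
            raise ValueError("observed agreement outside [0,1]")
        if not -1 - 1e-12 <= self.kappa <= 1 + 1e-12:
            raise ValueError("kappa outside [-1,1]")


def score_predictions(
    gold: Sequence[LabelledInstance], predicted: Sequence[LabelledInstance]
) -> PRFReport:
    """Positive-class confusion of ``predicted`` against ``gold``.

    The two sets must describe exactly the same instances, keyed by
    (doc_id, sentence span, concept); duplicates or unaligned keys are
    errors, not misses — a mention correctly classified means the sentence
    and symptom type match between the human and model label.
    """
    gold_map = _keyed(gold, "gold")
    pred_map = _keyed(predicted, "predicted")
    missing = sorted(set(gold_map) - set(pred_map))
    extra = sorted(set(pred_map) - set(gold_map))
    if missing or extra:
        raise AlignmentError(
            f"unaligned instances: {len(missing)} gold-only, {len(extra)} "
            f"predicted-only; first offenders: {missing[:3] + extra[:3]}"
        )
    concepts = {li.instance.concept for li in gold}
    concept = concepts.pop() if len(concepts) == 1 else "<multiple>"
    tp = fp = fn = 0
    for key, g in gold_map.items():
        p = pred_map[key]
        if p.label == POSITIVE:
            if g.label == POSITIVE:
                tp += 1
            else:
                fp += 1
        elif g.label == POSITIVE:
            fn += 1
    return PRFReport(concept=concept, true_pos=tp, false_pos=fp, false_neg=fn)


def _keyed(items: Sequence[LabelledInstance], name: str) -> dict:
    out: dict = {}
    for li in items:
        key = li.instance.key()
        if key in out:
            raise AlignmentError(f"duplicate instance key in {name} set: {key}")
        out[key] = li
    return out


def cohens_kappa(
    labels_a: Sequence, labels_b: Sequence, concept: str = ""
) -> AgreementReport:
    """Observed agreement and Cohen's kappa for two paired raters.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    marginal label frequencies of each rater.  When both raters are
    constant and identical, p_e = 1 and kappa is reported as 1 by
    convention with the ``degenerate`` flag set.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(f"length mismatch: {len(labels_a)} vs {len(labels_b)}")
    n = len(labels_a)
    if n == 0:
        raise ValueError("need at least one paired label")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    cats = sorted(set(labels_a) | set(labels_b), key=str)
    p_e = sum(
        (sum(a == c for a in labels_a) / n) * (sum(b == c for b in labels_b) / n)
        for c in cats
    )
    if math.isclose(p_e, 1.0):
        # both raters constant and identical (p_o must be 1 here)
        return AgreementReport(concept, n, p_o, kappa=1.0, degenerate=True)
    kappa = (p_o - p_e) / (1 - p_e)
    return AgreementReport(concept, n, p_o, kappa=kappa)


@dataclass(frozen=True)
class GoldStandardReport:
    n_instances: int
    n_positive: int
    n_negative: int
    passes: bool
    minimum: int = MIN_GOLD_POSITIVES


def validate_gold_standard(
    gold: Sequence[LabelledInstance], minimum: int = MIN_GOLD_POSITIVES
) -> GoldStandardReport:
    """Report whether a gold standard meets the minimum positive-mention
    count (report-only; never raises)."""
    n_pos = sum(li.label == POSITIVE for li in gold)
    return GoldStandardReport(
        n_instances=len(gold),
        n_positive=n_pos,
        n_negative=len(gold) - n_pos,
        passes=n_pos >= minimum,
        minimum=minimum,
    )


def summarize_across_concepts(
    reports: Mapping[str, Sequence[PRFReport] | Mapping[str, PRFReport]],
    excluded_concepts: Sequence[str] = (),
) -> pd.DataFrame:
    """Mean and median of P/R/F1 per arm across concepts.

    ``reports`` maps an arm label (e.g. ``"hybrid"``, ``"rules"``) to its
    per-concept reports (a sequence, or a concept-keyed mapping).  Concepts named in ``excluded_concepts`` (e.g.
    hand-annotated or keyword-only ones) are dropped and recorded in
    ``df.attrs["excluded_concepts"]``; undefined metrics are excluded from
    the aggregates, with per-metric counts in ``df.attrs["n_undefined"]``.
    """
    rows = []
    n_undefined: dict[tuple[str, str], int] = {}
    excluded = set(excluded_concepts)
    for arm, arm_reports in reports.items():
        if isinstance(arm_reports, Mapping):
            arm_reports = list(arm_reports.values())
        kept = [r for r in arm_reports if r.concept not in excluded]
        if not kept:
            raise ValueError(f"arm {arm!r} has no reports after exclusions")
        for metric in ("precision", "recall", "f1"):
            values = [getattr(r, metric) for r in kept]
            defined = [v for v in values if v is not None]
            n_undefined[(arm, metric)] = len(values) - len(defined)
            rows.append(
                {
                    "arm": arm,
                    "metric": metric,
                    "n_concepts": len(defined),
                    "mean": float(np.mean(defined)) if defined else float("nan"),
                    "median": float(np.median(defined)) if defined else float("nan"),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["excluded_concepts"] = sorted(excluded)
    df.attrs["n_undefined"] = n_undefined
    return df
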