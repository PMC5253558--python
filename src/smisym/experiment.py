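"""End-to-end synthetic experiment: the hybrid (rules + SVM with margin
abstention) arm against the rules-only arm, mirroring the two-arm model
comparison design.

Patients are split into train / calibration / evaluation partitions, one
model is trained per concept, its margin is calibrated to a target
precision on the calibration partition, and both arms are scored on the
evaluation partition over exactly the same instance set (so the paired
comparison is well defined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (
    CalibrationResult,
    LabelledInstance,
    SymptomModel,
    TrainConfig,
    train_model,
)
from .context import TriggerTable, context_only_label, default_triggers
from .corpus import Document
from .evaluation import PRFReport, score_predictions, summarize_across_concepts
from .lexicon import Lexicon, default_lexicon
from .syncorpus import GeneratorConfig, generate_corpus, make_training_set

__all__ = ["ExperimentResult", "split_patients", "run_experiment", "rules_labels"]


@dataclass
class ExperimentResult:
    models: dict[str, SymptomModel]
    calibrations: dict[str, CalibrationResult]
    reports: dict[str, dict[str, PRFReport]]  # arm -> concept -> report
    summary: pd.DataFrame
    n_train: dict[str, int]
    n_eval: dict[str, int]

    def report_table(self) -> pd.DataFrame:
        rows = []
        for arm, by_concept in self.reports.items():
            for concept, r in by_concept.items():
                rows.append(
                    {
                        "arm": arm,
                        "concept": concept,
                        "tp": r.true_pos,
                        "fp": r.false_pos,
                        "fn": r.false_neg,
                        "precision": r.precision,
                        "recall": r.recall,
                        "f1": r.f1,
                    }
                )
        return pd.DataFrame(rows).sort_values(["arm", "concept"]).reset_index(drop=True)


def split_patients(
    documents: Sequence[Document],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[Document], list[Document], list[Document]]:
    """Deterministic patient-level train/calibration/evaluation split
    (documents of one patient never straddle partitions)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    patients = sorted({d.patient_id for d in documents})
    order = np.random.default_rng(seed).permutation(len(patients))
    shuffled = [patients[i] for i in order]
    n = len(shuffled)
    a = int(round(fractions[0] * n))
    b = a + int(round(fractions[1] * n))
    parts = (set(shuffled[:a]), set(shuffled[a:b]), set(shuffled[b:]))
    return tuple([d for d in documents if d.patient_id in part] for part in parts)  # type: ignore[return-value]


def rules_labels(gold: Sequence[LabelledInstance]) -> list[LabelledInstance]:
    """Rules-only predictions over a gold set's instances."""
    out = []
    for li in gold:
        if li.instance.context is None:
            raise ValueError("instance has no context flags")
        out.append(
            LabelledInstance(
                instance=li.instance,
                label=context_only_label(li.instance.context),
                source="model",
                confidence=0.0,
            )
        )
    return out


def run_experiment(
    config: GeneratorConfig,
    target_precision: float = 0.85,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    train_config: TrainConfig | None = None,
    lexicon: Lexicon | None = None,
    triggers: TriggerTable | None = None,
    excluded_from_summary: Sequence[str] = (),
) -> ExperimentResult:
    """Generate a corpus and run the full two-arm comparison.

    All randomness (generation, splitting, fold assignment, solver) derives
    from ``config.seed``.
    """
    lexicon = lexicon or default_lexicon()
    triggers = triggers or default_triggers()
    documents, ledger = generate_corpus(config, lexicon)
    train_docs, calib_docs, eval_docs = split_patients(documents, fractions, seed=config.seed)

    models: dict[str, SymptomModel] = {}
    calibrations: dict[str, CalibrationResult] = {}
    reports: dict[str, dict[str, PRFReport]] = {"hybrid": {}, "rules": {}}
    n_train: dict[str, int] = {}
    n_eval: dict[str, int] = {}
    for concept in config.concepts:
        train_set = make_training_set(train_docs, ledger, concept, lexicon, triggers)
        calib_set = make_training_set(calib_docs, ledger, concept, lexicon, triggers)
        eval_set = make_training_set(eval_docs, ledger, concept, lexicon, triggers)
        model = train_model(train_set, train_config, seed=config.seed)
        calibrations[concept] = model.calibrate_margin(calib_set, target_precision)
        models[concept] = model
        hybrid_pred = [model.predict(li.instance) for li in eval_set]
        rules_pred = rules_labels(eval_set)
        reports["hybrid"][concept] = score_predictions(eval_set, hybrid_pred)
        reports["rules"][concept] = score_predictions(eval_set, rules_pred)
        n_train[concept] = len(train_set)
        n_eval[concept] = len(eval_set)
    summary = summarize_across_concepts(reports, excluded_concepts=excluded_from_summary)
    return ExperimentResult(
        models=models,
        calibrations=calibrations,
        reports=reports,
        summary=summary,
        n_train=n_train,
        n_eval=n_eval,
    )
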