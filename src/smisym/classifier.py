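"""Per-concept SVM sentence classification with confidence-margin abstention.

Each symptom concept gets its own binary linear SVM over sparse
bag-of-words features (sentence unigrams/bigrams, the matched keyword,
position-indexed tokens around it, coarse POS tags, attached modifiers)
combined with the rule-derived context flags.  Regularisation strength is
chosen by stratified 10-fold cross-validation on positive-class F1; the
final model is refit on all data.

Because clinical records restate symptoms across visits, precision is
favoured over recall: a *confidence margin filter* demotes positive
predictions whose distance from the decision boundary falls below a
threshold, which is calibrated on held-out data to reach a target
precision (``calibrate_margin``).  Abstentions fold into the negative
class — the downstream evaluation is strictly binary.

The surface follows the model/results convention: ``SymptomClassifier``
holds the data and configuration, ``fit()`` returns a ``SymptomModel``
results object carrying weights, the CV report, the margin threshold and a
``summary()`` table; ``train_model`` / ``predict`` / ``calibrate_margin``
are functional wrappers over the same objects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction import DictVectorizer
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .context import ContextFlags
from .textproc import CandidateInstance

__all__ = [
    "TrainingError",
    "CalibrationError",
    "FeatureConfigError",
    "LabelledInstance",
    "FeatureConfig",
    "TrainConfig",
    "CalibrationResult",
    "SymptomClassifier",
    "SymptomModel",
    "extract_features",
    "train_model",
    "predict",
    "calibrate_margin",
]

POSITIVE, NEGATIVE = "positive", "negative"


class TrainingError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


class FeatureConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LabelledInstance:
    """A candidate instance with a human or model label.

    Human labels carry no confidence; model labels carry the absolute SVM
    decision value.
    """

    instance: CandidateInstance
    label: str
    source: str = "human"  # {human, model}
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be binary, got {self.label!r}")
        if self.source not in ("human", "model"):
            raise ValueError(f"bad source {self.source!r}")
        if self.source == "human" and self.confidence is not None:
            raise ValueError("human labels carry no confidence")


@dataclass(frozen=True)
class FeatureConfig:
    """Versioned feature-extraction settings (must match between train and
    predict)."""

    version: str = "bow-ctx-1"
    window: int = 5          # positional-token window around the keyword
    use_pos: bool = True
    use_context: bool = True


@dataclass(frozen=True)
class TrainConfig:
    n_folds: int = 10
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    features: FeatureConfig = FeatureConfig()


def extract_features(
    instance: CandidateInstance, config: FeatureConfig | None = None
) -> dict[str, float]:
    """Sparse feature map for one instance (deterministic given instance and
    config).  Requires context flags to be filled in."""
    if config is None:
        config = FeatureConfig()
    sent = instance.sentence
    words = [t.text.lower() for t in sent.tokens]
    feats: dict[str, float] = {}
    for w in words:
        feats[f"uni={w}"] = 1.0
    for a, b in zip(words, words[1:]):
        feats[f"bi={a}_{b}"] = 1.0
    kw = instance.keyword
    feats[f"kw={kw.matched_text.lower()}"] = 1.0
    w = config.window
    for off in range(1, w + 1):
        i = kw.first - off
        if i >= 0:
            feats[f"p[-{off}]={words[i]}"] = 1.0
            if config.use_pos:
                feats[f"pos[-{off}]={sent.tokens[i].pos}"] = 1.0
        j = kw.last + off
        if j < len(words):
            feats[f"p[+{off}]={words[j]}"] = 1.0
            if config.use_pos:
                feats[f"pos[+{off}]={sent.tokens[j].pos}"] = 1.0
    if config.use_pos:
        feats[f"pos[kw]={sent.tokens[kw.first].pos}"] = 1.0
    if instance.modifiers:
        feats["has_modifier"] = 1.0
        for m in instance.modifiers:
            feats[f"mod={m.matched_text.lower()}"] = 1.0
    if config.use_context:
        flags = instance.context
        if flags is None:
            raise ValueError("instance has no context flags; run apply_context first")
        feats["ctx_negated"] = 1.0 if flags.negated else 0.0
        feats[f"ctx_experiencer={flags.experiencer}"] = 1.0
        feats[f"ctx_temporality={flags.temporality}"] = 1.0
    return feats


# ---------------------------------------------------------------------------
# Results object


@dataclass
class SymptomModel:
    """Fitted per-concept classifier (the results object).

    ``weights`` maps feature name to coefficient; the decision value of an
    instance is ``sum(weights[f] * v) + intercept`` over its feature map,
    unknown features contributing nothing.
    """

    concept: str
    weights: dict[str, float]
    intercept: float
    feature_config: FeatureConfig
    margin_threshold: float
    cv_report: pd.DataFrame
    best_c: float
    seed: int
    n_train: int

    def __post_init__(self) -> None:
        if self.margin_threshold < 0:
            raise ValueError("margin_threshold must be >= 0")

    # -- prediction -----------------------------------------------------

    def decision_value(self, instance: CandidateInstance) -> float:
        feats = extract_features(instance, self.feature_config)
        return sum(self.weights.get(f, 0.0) * v for f, v in feats.items()) + self.intercept

    def predict(
        self, instance: CandidateInstance, feature_config: FeatureConfig | None = None
    ) -> LabelledInstance:
        """Label an instance: positive iff the decision value is positive
        *and* clears the margin threshold; filtered positives fold into
        negative.  Confidence is the absolute decision value."""
        if feature_config is not None and feature_config != self.feature_config:
            raise FeatureConfigError(
                f"feature config mismatch: model has {self.feature_config}, "
                f"caller supplied {feature_config}"
            )
        d = self.decision_value(instance)
        label = POSITIVE if (d > 0 and abs(d) >= self.margin_threshold) else NEGATIVE
        return LabelledInstance(instance=instance, label=label, source="model", confidence=abs(d))

    def calibrate_margin(
        self, held_out: Sequence[LabelledInstance], target_precision: float
    ) -> "CalibrationResult":
        result = calibrate_margin(self, held_out, target_precision)
        self.margin_threshold = result.threshold
        return result

    # -- reporting ------------------------------------------------------

    def summary(self, top_k: int = 8) -> str:
        cv = self.cv_report
        ranked = sorted(self.weights.items(), key=lambda kv: kv[1])
        neg = ", ".join(f"{k} ({v:+.2f})" for k, v in ranked[:top_k])
        pos = ", ".join(f"{k} ({v:+.2f})" for k, v in ranked[::-1][:top_k])
        lines = [
            f"Symptom model: {self.concept}",
            "=" * 60,
            f"training instances      {self.n_train}",
            f"regularisation C        {self.best_c:g} (10-fold CV, positive-class F1)",
            f"CV precision mean       {cv['precision'].mean():.3f}",
            f"CV recall mean          {cv['recall'].mean():.3f}",
            f"CV F1 mean              {cv['f1'].mean():.3f}",
            f"margin threshold        {self.margin_threshold:.4f}",
            f"seed                    {self.seed}",
            f"top positive features   {pos}",
            f"top negative features   {neg}",
        ]
        return "\n".join(lines)

    # -- persistence (text-only artefact directory) ---------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "concept": self.concept,
            "intercept": self.intercept,
            "feature_config": asdict(self.feature_config),
            "margin_threshold": self.margin_threshold,
            "best_c": self.best_c,
            "seed": self.seed,
            "n_train": self.n_train,
            "weights": self.weights,
        }
        (path / "model.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8"
        )
        self.cv_report.to_csv(path / "cv_report.csv", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "SymptomModel":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text(encoding="utf-8"))
        return cls(
            concept=meta["concept"],
            weights={k: float(v) for k, v in meta["weights"].items()},
            intercept=float(meta["intercept"]),
            feature_config=FeatureConfig(**meta["feature_config"]),
            margin_threshold=float(meta["margin_threshold"]),
            cv_report=pd.read_csv(path / "cv_report.csv"),
            best_c=float(meta["best_c"]),
            seed=int(meta["seed"]),
            n_train=int(meta["n_train"]),
        )


# ---------------------------------------------------------------------------
# Model (estimator) object


class SymptomClassifier:
    """Unfitted per-concept classifier bound to labelled training data."""

    def __init__(
        self, data: Sequence[LabelledInstance], config: TrainConfig | None = None
    ) -> None:
        if not data:
            raise TrainingError("training data is empty")
        concepts = {li.instance.concept for li in data}
        if len(concepts) != 1:
            raise TrainingError(f"training data mixes concepts: {sorted(concepts)}")
        labels = {li.label for li in data}
        if len(labels) < 2:
            raise TrainingError(
                f"training data contains a single class ({labels.pop()}); "
                "both positive and negative labels are required"
            )
        self.data = list(data)
        self.config = config or TrainConfig()
        self.concept = concepts.pop()

    def fit(self, seed: int = 0) -> SymptomModel:
        cfg = self.config
        y = np.array([1 if li.label == POSITIVE else 0 for li in self.data])
        feats = [extract_features(li.instance, cfg.features) for li in self.data]
        n_min_class = int(min(np.sum(y == 1), np.sum(y == 0)))
        if n_min_class < cfg.n_folds:
            raise TrainingError(
                f"smallest class has {n_min_class} instances, fewer than "
                f"{cfg.n_folds} folds; reduce n_folds via TrainConfig"
            )
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(np.zeros(len(y)), y))
        grid_rows: dict[float, list[dict]] = {c: [] for c in cfg.c_grid}
        for k, (tr, te) in enumerate(folds):
            vec = DictVectorizer(sparse=True)
            x_tr = _csr32(vec.fit_transform([feats[i] for i in tr]))
            x_te = _csr32(vec.transform([feats[i] for i in te]))
            for c in cfg.c_grid:
                clf = _fit_silent(_svc(c, seed), x_tr, y[tr])
                pred = clf.predict(x_te)
                grid_rows[c].append({"fold": k, **_prf(y[te], pred)})
        grid = {c: pd.DataFrame(rows) for c, rows in grid_rows.items()}
        # best C by mean positive-class F1; ties go to the smaller C
        best_c = max(sorted(cfg.c_grid), key=lambda c: (grid[c]["f1"].mean(), -c))
        vec = DictVectorizer(sparse=True)
        x_all = _csr32(vec.fit_transform(feats))
        clf = _fit_silent(_svc(best_c, seed), x_all, y)
        names = vec.get_feature_names_out()
        coefs = np.asarray(clf.coef_).ravel()
        weights = {str(n): float(w) for n, w in zip(names, coefs) if w != 0.0}
        report = grid[best_c].copy()
        report["C"] = best_c
        return SymptomModel(
            concept=self.concept,
            weights=weights,
            intercept=float(clf.intercept_[0]),
            feature_config=cfg.features,
            margin_threshold=0.0,
            cv_report=report,
            best_c=best_c,
            seed=seed,
            n_train=len(self.data),
        )


def _csr32(x):
    # liblinear accepts only 32-bit sparse indices
    x = x.tocsr()
    x.indices = x.indices.astype(np.int32)
    x.indptr = x.indptr.astype(np.int32)
    return x


def _svc(c: float, seed: int) -> LinearSVC:
    # fixed iteration cap keeps large-C fits bounded; results stay
    # deterministic for a given seed either way
    return LinearSVC(C=c, random_state=seed, tol=1e-4, max_iter=5000, dual=True)


def _fit_silent(clf: LinearSVC, x, y) -> LinearSVC:
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        clf.fit(x, y)
    return clf


def _prf(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return {"precision": p, "recall": r, "f1": f1}


def train_model(
    data: Sequence[LabelledInstance],
    config: TrainConfig | None = None,
    seed: int = 0,
) -> SymptomModel:
    """Cross-validate, select C, and refit on all data (see module docstring)."""
    return SymptomClassifier(data, config).fit(seed)


def predict(model: SymptomModel, instance: CandidateInstance) -> LabelledInstance:
    return model.predict(instance)


@dataclass(frozen=True)
class CalibrationResult:
    threshold: float
    precision: float | None
    recall: float
    reached_target: bool


def calibrate_margin(
    model: SymptomModel,
    held_out: Sequence[LabelledInstance],
    target_precision: float,
) -> CalibrationResult:
    """Smallest margin threshold reaching ``target_precision`` on ``held_out``.

    Sweeps the observed positive decision values in ascending order; if the
    target is unreachable the maximum observed positive decision value is
    returned with a warning.  ``held_out`` must carry gold labels and
    contain at least one positive.
    """
    if not 0 < target_precision <= 1:
        raise ValueError("target_precision must be in (0, 1]")
    if not any(li.label == POSITIVE for li in held_out):
        raise ValueError("held_out contains no positive labels")
    ds = np.array([model.decision_value(li.instance) for li in held_out])
    gold = np.array([li.label == POSITIVE for li in held_out])
    pos_ds = sorted({float(d) for d in ds if d > 0})
    if not pos_ds:
        raise CalibrationError("no positive predictions at any threshold")

    def stats(t: float) -> tuple[float | None, float]:
        pred = (ds > 0) & (np.abs(ds) >= t)
        tp = int(np.sum(pred & gold))
        fp = int(np.sum(pred & ~gold))
        fn = int(np.sum(~pred & gold))
        p = tp / (tp + fp) if tp + fp else None
        r = tp / (tp + fn) if tp + fn else 0.0
        return p, r

    for t in [0.0] + pos_ds:
        p, r = stats(t)
        if p is not None and p >= target_precision:
            return CalibrationResult(t, p, r, reached_target=True)
    t = pos_ds[-1]
    p, r = stats(t)
    warnings.warn(
        f"{model.concept}: target precision {target_precision:.2f} unreachable "
        f"on held-out data (best {p}); using maximum observed margin {t:.4f}",
        stacklevel=2,
    )
    return CalibrationResult(t, p, r, reached_target=False)
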