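"""Feature extraction, SVM training, margin abstention and calibration."""

import numpy as np
import pandas as pd
import pytest

from smisym.classifier import (
    CalibrationError,
    FeatureConfig,
    FeatureConfigError,
    LabelledInstance,
    SymptomModel,
    TrainConfig,
    TrainingError,
    calibrate_margin,
    extract_features,
    predict,
    train_model,
)


def label(inst, y):
    return LabelledInstance(instance=inst, label=y, source="human")


@pytest.fixture(scope="module")
def separable_data(mk_instance):
    """Linearly separable labelled instances: a unique cue token marks the
    positive class."""
    data = []
    for i in range(60):
        pos = mk_instance(f"zzzcue paranoia was evident in review {i}.", "Paranoia", doc_id=f"p{i}")
        neg = mk_instance(f"qqqfoil paranoia was evident in review {i}.", "Paranoia", doc_id=f"n{i}")
        data.append(label(pos, "positive"))
        data.append(label(neg, "negative"))
    return data


class TestFeatures:
    def test_expected_features_present(self, mk_instance):
        inst = mk_instance(
            "has been having auditory command hallucinations telling him things.",
            "Hallucinations",
        )
        feats = extract_features(inst)
        assert feats["kw=hallucinations"] == 1.0
        assert feats["mod=auditory"] == 1.0
        assert feats["has_modifier"] == 1.0
        assert feats["ctx_negated"] == 0.0
        assert feats["uni=command"] == 1.0
        assert feats["bi=command_hallucinations"] == 1.0
        assert feats["p[-1]=command"] == 1.0

    def test_determinism(self, mk_instance):
        a = extract_features(mk_instance("mood remained elevated today.", "Elevated mood"))
        b = extract_features(mk_instance("mood remained elevated today.", "Elevated mood"))
        assert a == b

    def test_negation_changes_only_context_and_trigger_ngrams(self, mk_instance):
        plain = extract_features(mk_instance("he has paranoia today.", "Paranoia"))
        negated = extract_features(mk_instance("he has no paranoia today.", "Paranoia"))
        changed = set(plain.items()) ^ set(negated.items())
        for feat, _ in changed:
            name = feat.split("=", 1)
            assert feat.startswith(("ctx_", "uni=no", "bi=", "p[", "pos[")), feat

    def test_missing_context_is_an_error(self, lexicon):
        from smisym.textproc import build_instances

        (inst,) = build_instances("paranoia was evident.", "d", lexicon)
        with pytest.raises(ValueError, match="context"):
            extract_features(inst)


class TestTraining:
    def test_separable_data_reaches_perfect_cv_f1(self, separable_data):
        model = train_model(separable_data, seed=0)
        assert len(model.cv_report) == 10
        assert model.cv_report["f1"].mean() == pytest.approx(1.0)
        assert model.margin_threshold == 0.0

    def test_cue_word_ranks_top_weight(self, separable_data):
        model = train_model(separable_data, seed=0)
        top = max(model.weights, key=lambda k: model.weights[k])
        assert "zzzcue" in top

    def test_reproducible_weights(self, separable_data):
        a = train_model(separable_data, seed=7)
        b = train_model(separable_data, seed=7)
        assert a.weights == b.weights
        assert a.intercept == b.intercept
        assert a.cv_report.equals(b.cv_report)

    def test_label_permuted_data_is_at_chance(self, mk_instance):
        rng = np.random.default_rng(42)
        vocab = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
        data = []
        for i in range(200):
            w = [vocab[j] for j in rng.integers(0, len(vocab), 3)]
            inst = mk_instance(f"{w[0]} {w[1]} paranoia {w[2]} noted {i}.", "Paranoia", doc_id=f"d{i}")
            data.append(label(inst, "positive" if rng.random() < 0.5 else "negative"))
        model = train_model(data, seed=1)
        # labels are independent of features at prevalence 0.5: chance-level
        # F1 for an uninformed classifier lies well below the separable 1.0
        assert model.cv_report["f1"].mean() < 0.75

    def test_single_class_is_an_error(self, separable_data):
        pos_only = [li for li in separable_data if li.label == "positive"]
        with pytest.raises(TrainingError, match="single class"):
            train_model(pos_only)

    def test_too_few_instances_suggests_fewer_folds(self, separable_data):
        with pytest.raises(TrainingError, match="n_folds"):
            train_model(separable_data[:8])

    def test_mixed_concepts_rejected(self, separable_data, mk_instance):
        other = mk_instance("delusions were evident.", "Delusions")
        with pytest.raises(TrainingError, match="concept"):
            train_model(separable_data + [label(other, "positive")])

    def test_human_labels_carry_no_confidence(self, mk_instance):
        inst = mk_instance("paranoia was evident.", "Paranoia")
        with pytest.raises(ValueError, match="confidence"):
            LabelledInstance(instance=inst, label="positive", source="human", confidence=1.0)


def _manual_model(decision_map, concept="Paranoia"):
    """A model whose decision value for sentence 'tokNNN <kw> ...' is set
    directly through a per-token weight."""
    weights = {f"uni={tok}": v for tok, v in decision_map.items()}
    return SymptomModel(
        concept=concept,
        weights=weights,
        intercept=0.0,
        feature_config=FeatureConfig(),
        margin_threshold=0.0,
        cv_report=pd.DataFrame({"fold": range(10), "precision": 1.0, "recall": 1.0, "f1": 1.0}),
        best_c=1.0,
        seed=0,
        n_train=0,
    )


@pytest.fixture(scope="module")
def ranked_eval_set(mk_instance):
    """Instances with controlled decision values and gold labels."""
    spec = [
        ("tok0", 3.0, "positive"),
        ("tok1", 2.8, "positive"),
        ("tok2", 2.0, "negative"),   # high-margin false positive
        ("tok3", 1.9, "negative"),   # high-margin false positive
        ("tok4", 1.0, "positive"),
        ("tok5", 0.5, "positive"),
        ("tok6", -0.5, "negative"),
        ("tok7", -1.0, "positive"),  # missed positive
    ]
    model = _manual_model({tok: d for tok, d, _ in spec})
    held_out = [
        label(mk_instance(f"{tok} paranoia noted.", "Paranoia", doc_id=tok), y)
        for tok, _, y in spec
    ]
    return model, held_out, spec


class TestPredict:
    def test_margin_rule(self, ranked_eval_set):
        model, held_out, spec = ranked_eval_set
        model.margin_threshold = 0.6
        by_tok = {s[0]: s for s in spec}
        for li in held_out:
            tok = li.instance.doc_id
            d = by_tok[tok][1]
            out = model.predict(li.instance)
            assert out.label == ("positive" if d > 0 and abs(d) >= 0.6 else "negative")
            assert out.confidence == pytest.approx(abs(d))
            assert out.source == "model"
        model.margin_threshold = 0.0

    def test_zero_threshold_is_plain_sign_rule(self, ranked_eval_set):
        model, held_out, spec = ranked_eval_set
        model.margin_threshold = 0.0
        labels = [model.predict(li.instance).label for li in held_out]
        assert labels == ["positive" if d > 0 else "negative" for _, d, _ in spec]

    def test_feature_config_mismatch(self, ranked_eval_set):
        model, held_out, _ = ranked_eval_set
        with pytest.raises(FeatureConfigError):
            model.predict(held_out[0].instance, feature_config=FeatureConfig(window=3))

    def test_monotone_shrinkage_over_threshold_sweep(self, ranked_eval_set):
        model, held_out, _ = ranked_eval_set
        prev_pos = None
        prev_recall = None
        for t in [0.0, 0.4, 0.9, 1.95, 2.5, 2.9, 3.5]:
            model.margin_threshold = t
            pos = {li.instance.doc_id for li in held_out
                   if model.predict(li.instance).label == "positive"}
            n_gold_pos = sum(li.label == "positive" for li in held_out)
            tp = sum(1 for li in held_out
                     if li.label == "positive" and li.instance.doc_id in pos)
            recall = tp / n_gold_pos
            if prev_pos is not None:
                assert pos <= prev_pos
                assert recall <= prev_recall
            prev_pos, prev_recall = pos, recall
        model.margin_threshold = 0.0


class TestCalibration:
    def test_perfect_ranking_needs_no_margin(self, mk_instance):
        model = _manual_model({"hit": 1.0, "miss": -1.0})
        held_out = [
            label(mk_instance(f"hit paranoia noted {i}.", "Paranoia", doc_id=f"h{i}"), "positive")
            for i in range(5)
        ] + [
            label(mk_instance(f"miss paranoia noted {i}.", "Paranoia", doc_id=f"m{i}"), "negative")
            for i in range(5)
        ]
        result = calibrate_margin(model, held_out, 1.0)
        assert result.threshold == 0.0
        assert result.precision == 1.0 and result.recall == 1.0

    def test_sweep_matches_exhaustive_enumeration(self, ranked_eval_set):
        model, held_out, spec = ranked_eval_set
        target = 0.85
        # oracle: enumerate every candidate threshold directly
        best = None
        for t in sorted({0.0} | {d for _, d, _ in spec if d > 0}):
            pred_pos = [(tok, y) for tok, d, y in spec if d > 0 and d >= t]
            if not pred_pos:
                continue
            prec = sum(y == "positive" for _, y in pred_pos) / len(pred_pos)
            if prec >= target:
                best = t
                break
        result = calibrate_margin(model, held_out, target)
        assert result.reached_target
        assert result.threshold == pytest.approx(best)
        # the two mid-ranked false positives force the threshold above them
        assert result.threshold > 2.0

    def test_unreachable_target_warns_and_returns_max(self, mk_instance):
        model = _manual_model({"dud": 2.0, "ok": 1.0})
        held_out = [
            label(mk_instance("dud paranoia noted.", "Paranoia", doc_id="a"), "negative"),
            label(mk_instance("ok paranoia noted.", "Paranoia", doc_id="b"), "positive"),
        ]
        with pytest.warns(UserWarning, match="unreachable"):
            result = calibrate_margin(model, held_out, 1.0)
        assert result.threshold == 2.0
        assert not result.reached_target

    def test_no_positive_predictions_is_an_error(self, mk_instance):
        model = _manual_model({"neg": -1.0})
        held_out = [
            label(mk_instance("neg paranoia noted.", "Paranoia", doc_id="a"), "positive"),
        ]
        with pytest.raises(CalibrationError):
            calibrate_margin(model, held_out, 0.9)

    def test_requires_positive_gold(self, ranked_eval_set):
        model, held_out, _ = ranked_eval_set
        negs = [li for li in held_out if li.label == "negative"]
        with pytest.raises(ValueError, match="positive"):
            calibrate_margin(model, negs, 0.9)


class TestPersistence:
    def test_save_load_round_trip(self, separable_data, tmp_path):
        model = train_model(separable_data, seed=3)
        model.margin_threshold = 0.25
        model.save(tmp_path / "m")
        again = SymptomModel.load(tmp_path / "m")
        assert again.weights == model.weights
        assert again.margin_threshold == 0.25
        assert again.feature_config == model.feature_config
        inst = separable_data[0].instance
        assert again.decision_value(inst) == pytest.approx(model.decision_value(inst))
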