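"""One-vs-all classification, decision-table fusion and metrics."""

import numpy as np
import pytest

from vadeeg.classifier import (
    OneVsAllClassifier,
    VADModel,
    classify_level,
    classify_vad,
    evaluate,
    final_decision,
    train_vad_model,
)
from vadeeg.exceptions import RangeError, SchemaError
from vadeeg.io import DIMENSIONS, EmotionalState, NEUTRAL_STATE
from vadeeg.rnn import LMConfig, RNNParams


def constant_clf(dim, level, value, n_input=2):
    """Classifier whose raw output is tanh(value) regardless of input:
    zero weights, output bias = value."""
    p = RNNParams(
        W_ax=np.zeros((2, n_input)), W_aa=np.zeros((2, 2)),
        W_ya=np.zeros((1, 2)), b_a=np.zeros(2), b_y=np.array([value]),
    )
    return OneVsAllClassifier(dim, level, p)


def constant_model(raws):
    """VADModel with fixed raw outputs per (dimension, level)."""
    return VADModel({
        (d, l): constant_clf(d, l, np.arctanh(raws[(d, l)]))
        for d in DIMENSIONS for l in ("upper", "lower")
    })


class TestFinalDecision:
    @pytest.mark.parametrize(
        "upper,lower,expected",
        [
            ("target", "target", "error"),
            ("target", "outlier", "upper"),
            ("outlier", "target", "lower"),
            ("outlier", "outlier", "neutral"),
        ],
    )
    def test_truth_table(self, upper, lower, expected):
        assert final_decision(upper, lower) == expected

    def test_bad_label_rejected(self):
        with pytest.raises(SchemaError):
            final_decision("yes", "outlier")


class TestClassifyLevel:
    def test_positive_output_is_target(self):
        clf = constant_clf("valence", "upper", np.arctanh(0.8))
        label, raw = classify_level(clf, np.zeros(2))
        assert label == "target"
        assert raw == pytest.approx(0.8)

    def test_negative_output_is_outlier(self):
        clf = constant_clf("valence", "upper", np.arctanh(-0.8))
        label, _ = classify_level(clf, np.zeros(2))
        assert label == "outlier"

    def test_tie_at_threshold_is_outlier(self):
        clf = constant_clf("arousal", "lower", 0.0)
        label, raw = classify_level(clf, np.zeros(2))
        assert raw == 0.0 == clf.threshold
        assert label == "outlier"

    def test_length_mismatch_rejected(self):
        clf = constant_clf("valence", "upper", 0.1)
        with pytest.raises(SchemaError):
            classify_level(clf, np.zeros(5))


class TestClassifyVad:
    def test_all_negative_raw_gives_all_neutral(self):
        raws = {(d, l): -0.5 for d in DIMENSIONS for l in ("upper", "lower")}
        dec = classify_vad(np.zeros(2), constant_model(raws))
        assert all(dec.outcome(d) == "neutral" for d in DIMENSIONS)

    def test_valence_upper_only(self):
        raws = {(d, l): -0.5 for d in DIMENSIONS for l in ("upper", "lower")}
        raws[("valence", "upper")] = 0.7
        dec = classify_vad(np.zeros(2), constant_model(raws))
        assert dec.outcome("valence") == "upper"
        assert dec.outcome("arousal") == "neutral"
        assert dec.outcome("dominance") == "neutral"

    def test_both_valence_positive_is_error(self):
        raws = {(d, l): -0.5 for d in DIMENSIONS for l in ("upper", "lower")}
        raws[("valence", "upper")] = 0.7
        raws[("valence", "lower")] = 0.6
        dec = classify_vad(np.zeros(2), constant_model(raws))
        assert dec.outcome("valence") == "error"

    def test_missing_classifier_rejected(self):
        with pytest.raises(SchemaError):
            VADModel({("valence", "upper"): constant_clf("valence", "upper", 0.1)})


class TestTrainVadModel:
    def test_separable_features_classify_perfectly(self):
        """Each (dimension, level) marked by its own feature column."""
        rng = np.random.default_rng(0)
        states = []
        rows = []
        for v in ("upper", "lower"):
            for a in ("upper", "lower"):
                for d in ("upper", "lower"):
                    for _ in range(6):
                        f = np.zeros(6)
                        f[0 if v == "upper" else 1] = 1.0
                        f[2 if a == "upper" else 3] = 1.0
                        f[4 if d == "upper" else 5] = 1.0
                        rows.append(f + rng.normal(0, 0.05, 6))
                        states.append(EmotionalState(v, a, d))
        for _ in range(8):
            rows.append(rng.normal(0, 0.05, 6))
            states.append(NEUTRAL_STATE)
        F = np.stack(rows)
        model, _ = train_vad_model(F, states, n_hidden=12, seed=3)
        preds = classify_vad(F, model)
        for p, s in zip(preds, states):
            for dim in DIMENSIONS:
                assert p.outcome(dim) == s.level(dim)


class TestEvaluate:
    def _decision(self, v, a, d):
        raws = {}
        for dim, out in zip(DIMENSIONS, (v, a, d)):
            raws[(dim, "upper")] = 0.5 if out in ("upper", "error") else -0.5
            raws[(dim, "lower")] = 0.5 if out in ("lower", "error") else -0.5
        return classify_vad(np.zeros(2), constant_model(raws))

    def test_perfect_predictions(self):
        states = [EmotionalState("upper", "lower", "upper")] * 4
        preds = [self._decision("upper", "lower", "upper")] * 4
        rep = evaluate(preds, states)
        assert rep.decision_accuracy == {d: 100.0 for d in DIMENSIONS}
        cm = rep.confusion["valence"]
        assert cm.loc["upper", "upper"] == 100.0

    def test_toy_set_matches_hand_computed_metrics(self):
        """10 items, valence truth/prediction fixed; metrics hand-derived.

        truth:      U U U U L L L N N N
        predicted:  U U L N L L U N N E
        one-vs-rest for 'upper': TP=2, FN=2, FP=1, TN=5
        """
        truth_levels = ["upper"] * 4 + ["lower"] * 3 + ["neutral"] * 3
        pred_levels = ["upper", "upper", "lower", "neutral", "lower",
                       "lower", "upper", "neutral", "neutral", "error"]
        truth = [EmotionalState(t, "neutral", "neutral") for t in truth_levels]
        preds = [self._decision(p, "neutral", "neutral") for p in pred_levels]
        rep = evaluate(preds, truth)
        row = rep.per_level[
            (rep.per_level.dimension == "valence")
            & (rep.per_level.level == "upper")
            & (rep.per_level.basis == "decision")
        ].iloc[0]
        assert row.accuracy == pytest.approx(70.0)
        assert row.precision == pytest.approx(100 * 2 / 3)
        assert row.recall == pytest.approx(50.0)
        assert row.specificity == pytest.approx(100 * 5 / 6)
        p, r = 2 / 3, 0.5
        assert row.f1 == pytest.approx(100 * 2 * p * r / (p + r))
        # decision accuracy: 6 of 10 outcomes equal the true level
        assert rep.decision_accuracy["valence"] == pytest.approx(60.0)
        # confusion rows sum to 100 (incl. the error column)
        cm = rep.confusion["valence"]
        np.testing.assert_allclose(cm.sum(axis=1), 100.0, atol=0.1)
        assert cm.loc["neutral", "error"] == pytest.approx(100 / 3)

    def test_all_neutral_predictions_have_zero_upper_recall(self):
        truth = [EmotionalState("upper", "upper", "upper")] * 5
        preds = [self._decision("neutral", "neutral", "neutral")] * 5
        rep = evaluate(preds, truth)
        row = rep.per_level[
            (rep.per_level.dimension == "valence")
            & (rep.per_level.level == "upper")
            & (rep.per_level.basis == "decision")
        ].iloc[0]
        assert row.recall == 0.0

    def test_f1_is_harmonic_mean_of_precision_recall(self, rng):
        levels = ["upper", "lower", "neutral"]
        truth = [EmotionalState(levels[i % 3], "neutral", "neutral") for i in range(30)]
        preds = [
            self._decision(levels[int(rng.integers(3))], "neutral", "neutral")
            for _ in range(30)
        ]
        rep = evaluate(preds, truth)
        for _, row in rep.per_level.iterrows():
            p, r = row.precision, row.recall
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert row.f1 == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(RangeError):
            evaluate([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            evaluate([self._decision("upper", "upper", "upper")], [])
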