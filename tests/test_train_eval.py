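import itertools
import math

import numpy as np
import pytest

from g4rep.encode import encode_dataset
from g4rep.models import ModelConfig, init_params
from g4rep.seq_io import LabeledSequence, SequenceDataset
from g4rep.train_eval import (
    TrainConfig,
    auroc_rank,
    bce_loss,
    evaluate,
    metrics_from_scores,
    predict,
    train,
)


def pair_auroc_oracle(scores, labels):
    """Exhaustive enumeration over positive-negative pairs, ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def trapezoid_auroc_oracle(scores, labels):
    """Trapezoidal area under the empirical ROC curve."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    s = np.asarray(scores)[order]
    P, N = y.sum(), len(y) - y.sum()
    tpr, fpr = [0.0], [0.0]
    tp = fp = 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        tpr.append(tp / P)
        fpr.append(fp / N)
        i = j
    return float(np.trapezoid(tpr, fpr))


class TestBceLoss:
    def test_all_half_is_ln2(self):
        assert bce_loss([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(math.log(2))

    def test_perfect_predictions_near_zero(self):
        assert bce_loss([1.0, 0.0], [1, 0]) < 1e-10

    def test_hand_computed_example(self):
        expect = -(math.log(0.9) + math.log(0.8)) / 2
        assert bce_loss([0.9, 0.2], [1, 0]) == pytest.approx(expect)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([0.5], [1, 0])


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc_rank([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc_rank([0.4] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            assert auroc_rank([0.1, 0.9], [1, 1]) is None
        assert "one class" in caplog.text

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auroc_rank(scores, labels) == pytest.approx(
            pair_auroc_oracle(scores, labels), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_trapezoidal_roc_area(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = np.round(rng.random(40), 2)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        assert auroc_rank(scores, labels) == pytest.approx(
            trapezoid_auroc_oracle(scores, labels), abs=1e-12
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert auroc_rank(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        scores = rng.random(25)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        a = auroc_rank(scores, labels)
        b = auroc_rank(np.exp(5 * scores) + 3, labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestMetrics:
    def test_confusion_and_derived_metrics(self):
        rep = metrics_from_scores([0.9, 0.8, 0.1, 0.6], [1, 1, 0, 0])
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (2, 1, 1, 0)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(1.0)
        assert rep.f1 == pytest.approx(2 * (2 / 3) / (2 / 3 + 1))

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(2)
        scores, labels = rng.random(50), rng.integers(0, 2, 50)
        rep = metrics_from_scores(scores, labels)
        assert rep.tp + rep.tn + rep.fp + rep.fn == 50


def _toy_items(n=20, seed=0):
    """Linearly separable toy set: positives are RGG-repeat rich."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n // 2):
        filler = "".join(rng.choice(list("ACDEHIKLMNPTVW"), 8))
        recs.append(LabeledSequence(f"p{i}", "RGG" * 6 + filler, label=1))
    for i in range(n // 2):
        recs.append(
            LabeledSequence(
                f"n{i}", "".join(rng.choice(list("ACDEHIKLMNPTVW"), 26)), label=0
            )
        )
    return encode_dataset(SequenceDataset(recs))


class TestTrain:
    CFG = dict(input_dim=20, lstm_hidden=4, fc_hidden=4)

    def test_loss_decreases_on_separable_toy_set(self):
        items = _toy_items()
        mcfg = ModelConfig(architecture=1, **self.CFG)
        tcfg = TrainConfig(learning_rate=1e-2, max_epochs=50,
                           early_stop_patience=50, seed=0)
        _, history = train(mcfg, tcfg, items, items)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_patience_zero_stops_one_epoch_after_first_non_improvement(self):
        items = _toy_items(8, seed=1)
        mcfg = ModelConfig(architecture=1, **self.CFG)
        # huge lr forces oscillation, so non-improvement happens early
        tcfg = TrainConfig(learning_rate=0.5, max_epochs=200,
                           early_stop_patience=0, seed=0)
        _, history = train(mcfg, tcfg, items, items)
        losses = [h["val_loss"] for h in history]
        first_flat = next(
            i for i in range(1, len(losses)) if losses[i] >= min(losses[:i])
        )
        assert len(history) == first_flat + 1

    def test_same_seed_identical_history(self):
        items = _toy_items(8, seed=2)
        mcfg = ModelConfig(architecture=1, seed=3, **self.CFG)
        tcfg = TrainConfig(learning_rate=1e-2, max_epochs=5,
                           early_stop_patience=5, seed=4)
        _, h1 = train(mcfg, tcfg, items, items)
        _, h2 = train(mcfg, tcfg, items, items)
        assert h1 == h2

    def test_returns_parameters_at_best_validation_loss(self):
        items = _toy_items(12, seed=5)
        mcfg = ModelConfig(architecture=1, **self.CFG)
        tcfg = TrainConfig(learning_rate=1e-2, max_epochs=20,
                           early_stop_patience=20, seed=0)
        params, history = train(mcfg, tcfg, items, items)
        best = min(h["val_loss"] for h in history)
        scores = np.array([p.score_B for p in predict(mcfg, params, items)])
        labels = np.array([e.label for e in items])
        assert bce_loss(scores, labels) == pytest.approx(best, abs=1e-9)

    def test_evaluate_requires_labels(self):
        items = _toy_items(8)
        for e in items:
            e.label = None
        mcfg = ModelConfig(architecture=1, **self.CFG)
        with pytest.raises(ValueError, match="label"):
            evaluate(init_params(mcfg), mcfg, items)
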