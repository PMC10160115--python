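"""Splitting, training, evaluation, shuffled-label controls."""

import numpy as np
import pytest

from stimlabel.balancing import LabeledDataset
from stimlabel.decode import (
    MLPSpec,
    SplitSpec,
    classify_subtitles,
    evaluate,
    evaluate_holdout,
    evaluate_kfold,
    shuffle_labels,
    split_data,
    train_classifier,
)
from stimlabel.synthetic import SynthConfig, gen_annotations, gen_balanced_dataset
from stimlabel.annotations import build_sentences
from stimlabel.sentiment import Lexicon, polarity_of, score_sentence


class TestSplit:
    def test_holdout_fractions_70_20_10(self, rng):
        data = LabeledDataset(rng.standard_normal((100, 3)),
                              rng.integers(0, 2, 100))
        parts = split_data(data, SplitSpec(seed=0))
        assert parts["train"].labels.size == 70
        assert parts["test"].labels.size == 20
        assert parts["validation"].labels.size == 10

    def test_partitions_disjoint_and_cover(self, rng):
        n = 57
        data = LabeledDataset(np.arange(n, dtype=float).reshape(-1, 1),
                              rng.integers(0, 2, n))
        parts = split_data(data, SplitSpec(seed=1))
        seen = np.concatenate([p.features[:, 0] for p in parts.values()])
        assert sorted(seen.tolist()) == list(range(n))

    def test_same_seed_identical_partitions(self, rng):
        data = LabeledDataset(rng.standard_normal((50, 2)),
                              rng.integers(0, 2, 50))
        a = split_data(data, SplitSpec(seed=9))
        b = split_data(data, SplitSpec(seed=9))
        assert np.array_equal(a["train"].features, b["train"].features)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SplitSpec(train=0.7, test=0.2, validation=0.2)

    def test_kfold_needs_k_ge_2(self):
        with pytest.raises(ValueError):
            SplitSpec(mode="kfold", k=1)


class TestTrainEvaluate:
    @pytest.mark.parametrize("model", ["rf", "svm", "dt", "mlp"])
    def test_separable_blobs_decoded_by_every_model(self, model):
        data = gen_balanced_dataset(300, 10, d=10.0, seed=4)
        spec = SplitSpec(seed=0)
        report = evaluate_holdout(data, model=model, spec=spec,
                                  mlp_spec=MLPSpec(epochs=60, seed=0))
        assert report.accuracy >= 0.99

    def test_single_class_training_rejected(self, rng):
        data = LabeledDataset(rng.standard_normal((20, 2)), np.zeros(20, int))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(data, "rf")

    def test_resolved_params_recorded(self, rng):
        data = gen_balanced_dataset(60, 4, d=3.0, seed=0)
        _, cfg = train_classifier(data, "rf", seed=0)
        assert cfg == {"n_estimators": 100, "criterion": "gini"}
        _, cfg = train_classifier(data, "svm", seed=0)
        assert cfg["kernel"] == "rbf" and cfg["C"] == 1.0

    def test_mlp_three_class_uses_softmax_and_categorical_loss(self):
        data = gen_balanced_dataset(150, 6, d=8.0, n_classes=3, seed=1)
        est, cfg = train_classifier(data, "mlp", seed=0,
                                    mlp_spec=MLPSpec(epochs=30, seed=0))
        assert cfg["output_activation"] == "softmax"
        assert cfg["loss"] == "sparse_categorical_cross_entropy"
        assert cfg["hidden_layers"] == [100, 90, 70, 50, 30, 20, 10]
        mlp = est.named_steps["mlp"]
        assert mlp.out_activation_ == "softmax"
        assert mlp.n_outputs_ == 3

    def test_mlp_binary_uses_logistic_output(self):
        data = gen_balanced_dataset(120, 6, d=8.0, seed=1)
        est, cfg = train_classifier(data, "mlp", seed=0,
                                    mlp_spec=MLPSpec(epochs=30, seed=0))
        assert cfg["output_activation"] == "logistic"
        assert cfg["loss"] == "binary_cross_entropy"
        assert est.named_steps["mlp"].out_activation_ == "logistic"

    def test_mlp_training_loss_decreases_toward_zero(self):
        data = gen_balanced_dataset(400, 10, d=10.0, seed=2)
        est, _ = train_classifier(data, "mlp", seed=0,
                                  mlp_spec=MLPSpec(epochs=60, seed=0))
        losses = est.named_steps["mlp"].loss_curve_
        assert losses[-1] < losses[0]
        assert losses[-1] < 0.1

    def test_perfect_predictions_all_metrics_one(self, rng):
        data = gen_balanced_dataset(200, 8, d=10.0, seed=3)
        report = evaluate_holdout(data, "rf", SplitSpec(seed=0))
        assert report.accuracy == report.precision == report.recall == 1.0

    def test_constant_predictor_macro_metrics(self):
        """A degenerate single-class training set is rejected, so emulate a
        constant predictor via a majority-dominated fit on balanced test."""
        class Constant:
            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        test = LabeledDataset(np.zeros((40, 2)),
                              np.array([0] * 20 + [1] * 20))
        report = evaluate(Constant(), test, class_labels=[0, 1])
        assert report.accuracy == pytest.approx(0.5)
        assert report.recall == pytest.approx(0.5)   # macro: (1 + 0) / 2

    def test_metrics_consistent_with_emitted_confusion(self):
        data = gen_balanced_dataset(300, 5, d=1.0, seed=5)
        report = evaluate_holdout(data, "dt", SplitSpec(seed=2))
        cm = report.confusion
        assert report.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        recalls = [cm[i, i] / cm[i].sum() for i in range(len(cm))]
        assert report.recall == pytest.approx(np.mean(recalls))

    def test_determinism_fixed_seed(self):
        data = gen_balanced_dataset(200, 6, d=1.5, seed=6)
        r1 = evaluate_holdout(data, "rf", SplitSpec(seed=3))
        r2 = evaluate_holdout(data, "rf", SplitSpec(seed=3))
        assert r1.accuracy == r2.accuracy
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_kfold_folds_cover_all_rows(self):
        from stimlabel.decode import kfold_indices
        data = gen_balanced_dataset(100, 3, d=1.0, seed=7)
        folds = kfold_indices(data, SplitSpec(mode="kfold", k=10, seed=0))
        assert len(folds) == 10
        test_idx = np.concatenate([te for _, te in folds])
        assert sorted(test_idx.tolist()) == list(range(100))
        assert all(len(te) == 10 for _, te in folds)


class TestShuffleControl:
    def test_class_histogram_preserved(self, rng):
        data = LabeledDataset(rng.standard_normal((60, 3)),
                              np.array([0] * 40 + [1] * 20))
        out = shuffle_labels(data, seed=0)
        assert out.class_counts == data.class_counts
        assert out.features is data.features

    def test_binary_shuffled_accuracy_near_half(self):
        accs = []
        for seed in range(10):
            data = gen_balanced_dataset(600, 20, d=4.0, seed=seed)
            shuffled = shuffle_labels(data, seed=seed + 100)
            report = evaluate_holdout(shuffled, "rf", SplitSpec(seed=seed))
            accs.append(report.accuracy)
        assert 0.45 <= np.mean(accs) <= 0.55

    def test_three_class_shuffled_accuracy_near_third(self):
        accs = []
        for seed in range(10):
            data = gen_balanced_dataset(600, 20, d=4.0, n_classes=3,
                                        seed=seed)
            shuffled = shuffle_labels(data, seed=seed + 100)
            report = evaluate_holdout(shuffled, "rf", SplitSpec(seed=seed))
            accs.append(report.accuracy)
        assert 0.28 <= np.mean(accs) <= 0.39


class TestSubtitleClassification:
    def _corpus(self, n=150, seed=0):
        words, _ = gen_annotations(
            SynthConfig(seed=seed, class_priors=(0.45, 0.45, 0.10)),
            n_sentences=n,
        )
        sentences = build_sentences(words)
        lex = Lexicon.demo()
        labels = [
            1 if polarity_of(score_sentence(s, lex)) >= 0 else 0
            for s in sentences
        ]
        return [s.text for s in sentences], labels

    def test_lexicon_labels_learnable_from_text(self):
        texts, labels = self._corpus()
        report = classify_subtitles(texts, labels, model="rf",
                                    spec=SplitSpec(seed=0))
        majority = max(np.bincount(labels)) / len(labels)
        assert report.accuracy > majority + 0.1

    def test_shuffled_labels_drop_to_baseline(self):
        texts, labels = self._corpus()
        rng = np.random.default_rng(1)
        shuffled = list(rng.permutation(labels))
        report = classify_subtitles(texts, shuffled, model="rf",
                                    spec=SplitSpec(seed=0))
        majority = max(np.bincount(labels)) / len(labels)
        assert report.accuracy < majority + 0.12

    def test_deterministic_under_fixed_seed(self):
        texts, labels = self._corpus(n=80)
        a = classify_subtitles(texts, labels, model="dt", spec=SplitSpec(seed=4))
        b = classify_subtitles(texts, labels, model="dt", spec=SplitSpec(seed=4))
        assert a.accuracy == b.accuracy

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classify_subtitles(["a b", "c d"], [1, 1])
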