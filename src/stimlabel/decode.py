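"""Sentiment classification from voxel patterns or vectorised sentences.

Four classifiers are supported — random forest (rf), support-vector machine
(svm), decision tree (dt) and a multilayer perceptron (mlp) with seven
hidden layers [100, 90, 70, 50, 30, 20, 10], ReLU activations and the Adam
optimiser; the output layer is logistic for two classes and softmax for
three, trained under the matching cross-entropy loss.  The tree/SVM models
run with their library defaults, pinned explicitly so "default" stays
reproducible across library versions.  Features are standardised to zero
mean / unit variance before the SVM and MLP.

Evaluation uses a 70/20/10 train/test/validation hold-out or k-fold
cross-validation (k = 10 by default), reporting accuracy, macro-averaged
precision/recall/F1 and the confusion matrix.  A shuffled-label control —
permuting the label column while leaving features untouched — establishes
the empirical chance level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balancing import LabeledDataset

MODEL_NAMES = ("rf", "svm", "dt", "mlp")

#: pinned "library default" hyperparameters, recorded into every run log
PINNED_DEFAULTS = {
    "rf": {"n_estimators": 100, "criterion": "gini"},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "dt": {"criterion": "gini"},
}


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out fractions or k-fold configuration for evaluation."""

    train: float = 0.7
    test: float = 0.2
    validation: float = 0.1
    mode: str = "holdout"  # 'holdout' | 'kfold'
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"holdout", "kfold"}:
            raise ValueError(f"unknown split mode {self.mode!r}")
        total = self.train + self.test + self.validation
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions sum to {total}, expected 1")
        if self.mode == "kfold" and self.k < 2:
            raise ValueError("kfold mode needs k >= 2")


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and training schedule of the deep classifier."""

    hidden_layers: tuple[int, ...] = (100, 90, 70, 50, 30, 20, 10)
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layers) < 1:
            raise ValueError("at least one hidden layer required")


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix plus aggregate and per-class metrics for one run."""

    accuracy: float
    precision: float  # macro
    recall: float     # macro
    f1: float         # macro
    confusion: np.ndarray
    class_labels: tuple[int, ...]
    per_class: dict
    model: str
    split: dict
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "class_labels": list(self.class_labels),
            "per_class": self.per_class,
            "model": self.model,
            "split": self.split,
            "seed": self.seed,
            "params": self.params,
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def confusion_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.confusion,
            index=[f"true_{c}" for c in self.class_labels],
            columns=[f"pred_{c}" for c in self.class_labels],
        ).to_csv(path, sep="\t")


def split_data(
    data: LabeledDataset, spec: SplitSpec
) -> dict[str, LabeledDataset]:
    """Seeded disjoint train/test/validation partitions (hold-out mode).

    Partition sizes honour the requested fractions to within one row.
    """
    n = data.labels.size
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(round(spec.train * n))
    n_test = int(round(spec.test * n))
    parts = {
        "train": order[:n_train],
        "test": order[n_train : n_train + n_test],
        "validation": order[n_train + n_test :],
    }
    return {
        name: LabeledDataset(data.features[idx], data.labels[idx])
        for name, idx in parts.items()
    }


def kfold_indices(
    data: LabeledDataset, spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint stratified folds covering every row exactly once."""
    kf = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
    return list(kf.split(data.features, data.labels))


def _build_model(model: str, n_classes: int, seed: int,
                 mlp_spec: MLPSpec | None = None, params: dict | None = None):
    params = dict(params or {})
    if model == "rf":
        cfg = {**PINNED_DEFAULTS["rf"], **params}
        return RandomForestClassifier(random_state=seed, **cfg), cfg
    if model == "dt":
        cfg = {**PINNED_DEFAULTS["dt"], **params}
        return DecisionTreeClassifier(random_state=seed, **cfg), cfg
    if model == "svm":
        cfg = {**PINNED_DEFAULTS["svm"], **params}
        est = Pipeline(
            [("scale", StandardScaler()), ("svm", SVC(random_state=seed, **cfg))]
        )
        return est, cfg
    if model == "mlp":
        spec = mlp_spec or MLPSpec(seed=seed)
        cfg = {
            "hidden_layers": list(spec.hidden_layers),
            "activation": "relu",
            "optimizer": "adam",
            "output_activation": "softmax" if n_classes > 2 else "logistic",
            "loss": (
                "sparse_categorical_cross_entropy" if n_classes > 2
                else "binary_cross_entropy"
            ),
            "epochs": spec.epochs,
            "batch_size": spec.batch_size,
            "learning_rate": spec.learning_rate,
        }
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=spec.hidden_layers,
                        activation="relu",
                        solver="adam",
                        learning_rate_init=spec.learning_rate,
                        batch_size=spec.batch_size,
                        max_iter=spec.epochs,
                        early_stopping=True,
                        validation_fraction=spec.validation_fraction,
                        n_iter_no_change=spec.epochs,
                        random_state=spec.seed,
                    ),
                ),
            ]
        )
        return est, cfg
    raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


def train_classifier(
    train: LabeledDataset,
    model: str = "rf",
    seed: int = 0,
    mlp_spec: MLPSpec | None = None,
    params: dict | None = None,
):
    """Fit one of rf/svm/dt/mlp on the training partition.

    Returns ``(fitted_estimator, resolved_params)``; the resolved parameters
    are what a run log records so that "library defaults" stay pinned.
    """
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    est, cfg = _build_model(model, classes.size, seed, mlp_spec, params)
    est.fit(train.features, train.labels)
    return est, cfg


def evaluate(
    model_est,
    test: LabeledDataset,
    model_name: str = "",
    split_meta: dict | None = None,
    seed: int = 0,
    params: dict | None = None,
    class_labels: Sequence[int] | None = None,
) -> EvalReport:
    """Score a fitted model: confusion matrix, accuracy, macro P/R/F1.

    Labels absent from training but present in the test set are scored
    normally (they simply cannot be predicted, counting against recall).
    """
    if test.labels.size == 0:
        raise ValueError("empty test partition")
    pred = model_est.predict(test.features)
    if class_labels is None:
        class_labels = np.unique(np.concatenate([test.labels, pred]))
    class_labels = np.asarray(class_labels)
    cm = sk_confusion_matrix(test.labels, pred, labels=class_labels)
    return _report_from_confusion(
        cm, class_labels, model_name, split_meta or {}, seed, params or {}
    )


def _report_from_confusion(cm, class_labels, model_name, split_meta, seed,
                           params) -> EvalReport:
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0
    per_class = {}
    precisions, recalls, f1s = [], [], []
    for i, c in enumerate(np.asarray(class_labels).tolist()):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        p = tp / (tp + fp) if (tp + fp) else 0.0
        r = tp / (tp + fn) if (tp + fn) else 0.0
        f = 2 * p * r / (p + r) if (p + r) else 0.0
        per_class[int(c)] = {"precision": p, "recall": r, "f1": f,
                             "support": int(cm[i, :].sum())}
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return EvalReport(
        accuracy=accuracy,
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        confusion=cm.astype(int),
        class_labels=tuple(int(c) for c in np.asarray(class_labels).tolist()),
        per_class=per_class,
        model=model_name,
        split=dict(split_meta),
        seed=seed,
        params=dict(params),
    )


def evaluate_holdout(
    data: LabeledDataset,
    model: str = "rf",
    spec: SplitSpec | None = None,
    seed: int | None = None,
    mlp_spec: MLPSpec | None = None,
) -> EvalReport:
    """70/20/10 hold-out evaluation (train on 70%, report on the 20% test)."""
    spec = spec or SplitSpec()
    seed = spec.seed if seed is None else seed
    parts = split_data(data, spec)
    est, cfg = train_classifier(parts["train"], model, seed=seed,
                                mlp_spec=mlp_spec)
    meta = {"mode": "holdout", "train": spec.train, "test": spec.test,
            "validation": spec.validation, "seed": spec.seed}
    return evaluate(est, parts["test"], model_name=model, split_meta=meta,
                    seed=seed, params=cfg,
                    class_labels=np.unique(data.labels))


def evaluate_kfold(
    data: LabeledDataset,
    model: str = "rf",
    spec: SplitSpec | None = None,
    seed: int | None = None,
    mlp_spec: MLPSpec | None = None,
) -> EvalReport:
    """k-fold cross-validation; metrics come from the pooled confusion matrix."""
    spec = spec or SplitSpec(mode="kfold")
    seed = spec.seed if seed is None else seed
    class_labels = np.unique(data.labels)
    cm_total = np.zeros((class_labels.size, class_labels.size), dtype=int)
    cfg: dict = {}
    for train_idx, test_idx in kfold_indices(data, spec):
        train = LabeledDataset(data.features[train_idx], data.labels[train_idx])
        test = LabeledDataset(data.features[test_idx], data.labels[test_idx])
        est, cfg = train_classifier(train, model, seed=seed, mlp_spec=mlp_spec)
        pred = est.predict(test.features)
        cm_total += sk_confusion_matrix(test.labels, pred, labels=class_labels)
    meta = {"mode": "kfold", "k": spec.k, "seed": spec.seed}
    return _report_from_confusion(cm_total, class_labels, model, meta, seed, cfg)


def shuffle_labels(data: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Permute the label column uniformly; features and class counts untouched."""
    rng = np.random.default_rng(seed)
    return LabeledDataset(
        features=data.features,
        labels=data.labels[rng.permutation(data.labels.size)],
    )


def classify_subtitles(
    texts: Sequence[str],
    labels: Sequence[int],
    model: str = "rf",
    spec: SplitSpec | None = None,
    seed: int = 0,
    mlp_spec: MLPSpec | None = None,
) -> EvalReport:
    """Classify sentences from their text alone (TF-IDF unigram features).

    The labels normally come from a sentiment analyzer over the same
    sentences, so accuracy measures how well surface word usage predicts the
    analyzer's polarity.
    """
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes among the labels")
    vec = TfidfVectorizer(lowercase=True, min_df=1)
    X = vec.fit_transform([str(t) for t in texts])
    if X.shape[1] == 0:
        raise ValueError("empty vocabulary after vectorization")
    data = LabeledDataset(features=X.toarray(), labels=labels)
    spec = spec or SplitSpec(seed=seed)
    if spec.mode == "kfold":
        return evaluate_kfold(data, model, spec, seed=seed, mlp_spec=mlp_spec)
    return evaluate_holdout(data, model, spec, seed=seed, mlp_spec=mlp_spec)
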