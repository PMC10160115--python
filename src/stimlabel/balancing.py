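"""Class balancing by random oversampling (ROS) and SMOTE.

Naturalistic-stimulus labels are heavily imbalanced (movies contain far more
positive than negative dialogue), so minority classes are grown to the
majority count before classification.  ROS duplicates existing minority rows
uniformly with replacement; SMOTE synthesises new minority points on the
segment between a minority point and one of its k nearest minority
neighbours: x_new = x + u * (z - x), u ~ U[0, 1].

By default balancing is applied to the whole dataset before splitting, which
mirrors the common (leakage-prone) usage in which duplicated rows may appear
in both train and test partitions and inflate ROS accuracies; the
leakage-free alternative is to pass only the training partition here
(``balance-train-only`` in the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.neighbors import NearestNeighbors

DEFAULT_K_NEIGHBORS = 5


@dataclass(frozen=True)
class LabeledDataset:
    """A feature matrix with one class label per row."""

    features: np.ndarray  # (n, p)
    labels: np.ndarray    # (n,)

    def __post_init__(self) -> None:
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.size:
            raise ValueError("features and labels disagree in length")

    @property
    def class_counts(self) -> Mapping[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


def _check_classes(data: LabeledDataset) -> dict[int, np.ndarray]:
    """Per-class row indices; requires >=2 non-empty classes."""
    by_class = {
        int(c): np.flatnonzero(data.labels == c) for c in np.unique(data.labels)
    }
    if len(by_class) < 2:
        raise ValueError("balancing needs at least two classes")
    return by_class


def random_oversample(data: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Equalise class counts by duplicating minority rows.

    Added rows are exact copies of existing minority rows drawn uniformly
    with replacement; already-balanced input is returned unchanged.
    """
    by_class = _check_classes(data)
    target = max(len(idx) for idx in by_class.values())
    rng = np.random.default_rng(seed)

    extra_feats, extra_labels = [], []
    for cls, idx in sorted(by_class.items()):
        deficit = target - len(idx)
        if deficit == 0:
            continue
        picks = rng.choice(idx, size=deficit, replace=True)
        extra_feats.append(data.features[picks])
        extra_labels.append(np.full(deficit, cls, dtype=data.labels.dtype))
    if not extra_feats:
        return data
    return LabeledDataset(
        features=np.vstack([data.features, *extra_feats]),
        labels=np.concatenate([data.labels, *extra_labels]),
    )


def smote_oversample(
    data: LabeledDataset,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> LabeledDataset:
    """Equalise class counts with synthetic minority interpolation (SMOTE).

    For each needed synthetic sample: pick a minority point x uniformly, one
    of its k nearest same-class neighbours z (Euclidean, k capped at class
    size − 1), and u ~ U[0, 1]; emit x + u·(z − x).  Original rows are kept
    verbatim.  Singleton minority classes cannot be interpolated — use
    :func:`random_oversample` for those.
    """
    by_class = _check_classes(data)
    target = max(len(idx) for idx in by_class.values())
    rng = np.random.default_rng(seed)

    extra_feats, extra_labels = [], []
    for cls, idx in sorted(by_class.items()):
        deficit = target - len(idx)
        if deficit == 0:
            continue
        if len(idx) < 2:
            raise ValueError(
                f"class {cls} has a single member; SMOTE cannot interpolate — "
                "use random_oversample instead"
            )
        points = data.features[idx]
        k = min(k_neighbors, len(idx) - 1)
        # +1 because each point's nearest neighbour is itself
        nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
        neigh = nn.kneighbors(points, return_distance=False)[:, 1:]

        base = rng.integers(0, len(idx), size=deficit)
        pick = rng.integers(0, k, size=deficit)
        u = rng.random(size=deficit)
        x = points[base]
        z = points[neigh[base, pick]]
        extra_feats.append(x + u[:, None] * (z - x))
        extra_labels.append(np.full(deficit, cls, dtype=data.labels.dtype))

    if not extra_feats:
        return data
    return LabeledDataset(
        features=np.vstack([data.features, *extra_feats]),
        labels=np.concatenate([data.labels, *extra_labels]),
    )


def balance(
    data: LabeledDataset,
    method: str = "none",
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> LabeledDataset:
    """Dispatch on ``method`` ∈ {'none', 'ros', 'smote'}."""
    if method == "none":
        return data
    if method == "ros":
        return random_oversample(data, seed=seed)
    if method == "smote":
        return smote_oversample(data, k_neighbors=k_neighbors, seed=seed)
    raise ValueError(f"unknown balancing method {method!r}")
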