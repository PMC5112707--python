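"""Linear one-vs-one SVM classification with leave-one-out evaluation.

Multiclass decisions are made by majority vote over all class-pair linear
SVMs; ties are broken by the largest sum of signed decision values among
the tied labels, then by label order.  Features are standardized to zero
mean / unit deviation using training samples only (refit inside every
leave-one-out fold, so no information leaks from the held-out sample).

The pairwise classifiers are fitted through libsvm's one-vs-one
decomposition (:class:`sklearn.svm.SVC` with a linear kernel); the voting
and tie-breaking on top of the raw pairwise decision values are our own so
the decision rule is fully specified and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from herbleaf.features import FeatureVector

logger = logging.getLogger("herbleaf")

ALL_BLOCKS = ("fs1", "fs2", "fs3")


class ClassificationError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """Integer confusion counts; rows = true class, columns = predicted."""

    counts: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.labels):
            raise ValueError("labels must match matrix size")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")


@dataclass
class TrainedModel:
    """Standardization + one linear decision function per unordered class pair."""

    class_labels: list[str]
    mean: np.ndarray
    scale: np.ndarray
    svc: SVC = field(repr=False)
    C: float = 1.0

    @property
    def n_pairwise(self) -> int:
        k = len(self.class_labels)
        return k * (k - 1) // 2

    @property
    def pairs(self) -> list[tuple[str, str]]:
        labs = self.class_labels
        return [(labs[i], labs[j]) for i in range(len(labs)) for j in range(i + 1, len(labs))]


def _to_matrix(features, blocks: tuple[str, ...]) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=np.float64)
        return X if X.ndim == 2 else X[None, :]
    return np.asarray([f.concat(blocks) for f in features], dtype=np.float64)


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    scale = np.where(std > 0, std, 1.0)  # zero-deviation dims pass through
    return mean, scale


def train(
    features,
    labels: Sequence[str],
    C: float = 1.0,
    blocks: tuple[str, ...] = ALL_BLOCKS,
) -> TrainedModel:
    """Fit one soft-margin linear SVM per class pair on standardized features."""
    X = _to_matrix(features, blocks)
    y = np.asarray([str(l) for l in labels])
    if len(X) != len(y):
        raise ClassificationError("features and labels length mismatch")
    bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if len(bad):
        raise ClassificationError(f"non-finite feature values in sample(s) {bad.tolist()}")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ClassificationError("need at least 2 classes to train")
    mean, scale = _standardize_params(X)
    Xs = (X - mean) / scale
    svc = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    svc.fit(Xs, y)
    return TrainedModel(
        class_labels=list(svc.classes_), mean=mean, scale=scale, svc=svc, C=C
    )


def pairwise_decisions(model: TrainedModel, features) -> np.ndarray:
    """Raw signed decision values, one column per class pair (i, j), i < j.

    A positive value favors the first label of the pair.
    """
    X = _to_matrix(features, ALL_BLOCKS) if not isinstance(features, np.ndarray) else np.atleast_2d(features)
    if X.shape[1] != len(model.mean):
        raise ClassificationError(
            f"feature dimension {X.shape[1]} does not match model ({len(model.mean)})"
        )
    Xs = (X - model.mean) / model.scale
    dec = model.svc.decision_function(Xs)
    if len(model.class_labels) == 2:
        # binary SVC returns one value with positive favoring classes_[1];
        # flip so positive favors the first label of the (only) pair
        dec = -np.atleast_2d(dec).T
    return dec


def vote(
    decisions: np.ndarray, class_labels: Sequence[str]
) -> list[str]:
    """Majority vote over pairwise decisions with deterministic tie-breaking."""
    labs = list(class_labels)
    k = len(labs)
    dec = np.atleast_2d(decisions)
    votes = np.zeros((len(dec), k))
    scores = np.zeros((len(dec), k))
    col = 0
    for i in range(k):
        for j in range(i + 1, k):
            d = dec[:, col]
            votes[:, i] += d > 0
            votes[:, j] += d <= 0
            scores[:, i] += d
            scores[:, j] -= d
            col += 1
    out = []
    for v, s in zip(votes, scores):
        top = np.flatnonzero(v == v.max())
        if len(top) > 1:
            top = top[s[top] == s[top].max()]
        out.append(labs[top[0]])  # remaining ties -> label order
    return out


def predict(model: TrainedModel, feature) -> str:
    """Predict the label of a single feature vector."""
    if isinstance(feature, FeatureVector):
        feature = feature.concat(ALL_BLOCKS)
    dec = pairwise_decisions(model, np.atleast_2d(np.asarray(feature, dtype=np.float64)))
    return vote(dec, model.class_labels)[0]


def predict_batch(model: TrainedModel, features) -> list[str]:
    dec = pairwise_decisions(model, _to_matrix(features, ALL_BLOCKS))
    return vote(dec, model.class_labels)


def loo_evaluate(
    features,
    labels: Sequence[str],
    C: float = 1.0,
    blocks: tuple[str, ...] = ALL_BLOCKS,
) -> tuple[float, ConfusionMatrix]:
    """Leave-one-out evaluation; standardization refit inside every fold."""
    X = _to_matrix(features, blocks)
    y = np.asarray([str(l) for l in labels])
    n = len(y)
    if n < 2:
        raise ClassificationError("need at least 2 samples for leave-one-out")
    all_labels = sorted(set(y))
    index = {lab: i for i, lab in enumerate(all_labels)}
    counts = np.zeros((len(all_labels), len(all_labels)), dtype=np.int64)
    correct = 0
    warned_singleton = False
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        fold_classes = set(y[keep])
        if y[i] not in fold_classes and not warned_singleton:
            logger.info(
                "leave-one-out: class %r has a single sample; it cannot be "
                "predicted correctly in its own fold", y[i]
            )
            warned_singleton = True
        model = train(X[keep], y[keep], C=C)
        pred = vote(pairwise_decisions(model, X[i: i + 1]), model.class_labels)[0]
        counts[index[y[i]], index[pred]] += 1
        correct += pred == y[i]
    return correct / n, ConfusionMatrix(counts=counts, labels=all_labels)


def evaluate_feature_subsets(
    features,
    labels: Sequence[str],
    subsets: Sequence[Sequence[str]],
    C: float = 1.0,
) -> pd.DataFrame:
    """Leave-one-out accuracy per feature-block subset.

    ``subsets`` is a list of block-name combinations, e.g.
    ``[("fs1",), ("fs2",), ("fs3",), ("fs1", "fs2", "fs3")]``.
    """
    rows = []
    for subset in subsets:
        subset = tuple(subset)
        if not subset:
            raise ClassificationError("empty feature subset")
        acc, _ = loo_evaluate(features, labels, C=C, blocks=subset)
        rows.append({"subset": "+".join(subset), "accuracy": acc})
    return pd.DataFrame(rows)
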