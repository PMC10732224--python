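"""Scoring and analysis of trained knot classifiers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "evaluate", "pca_projection", "accuracy_vs_classes"]


@dataclass
class ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted."""

    counts: np.ndarray
    class_names: list

    @classmethod
    def from_predictions(cls, y_true, y_pred, class_names) -> "ConfusionMatrix":
        c = len(class_names)
        counts = np.zeros((c, c), dtype=int)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            counts[int(t), int(p)] += 1
        return cls(counts, list(class_names))

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def per_class_accuracy(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        return np.where(row > 0, np.diag(self.counts) / np.maximum(row, 1), 0.0)

    def most_confused_pair(self) -> tuple[str, str, int]:
        """Off-diagonal cell with the largest count (true, predicted, count)."""
        off = self.counts.copy()
        np.fill_diagonal(off, 0)
        t, p = np.unravel_index(np.argmax(off), off.shape)
        return self.class_names[t], self.class_names[p], int(off[t, p])

    def __str__(self) -> str:
        width = max(len(n) for n in self.class_names) + 1
        lines = [" " * width + " ".join(f"{n:>{width}}" for n in self.class_names)]
        for name, row in zip(self.class_names, self.counts):
            lines.append(f"{name:>{width}}" +
                         " ".join(f"{v:>{width}}" for v in row))
        lines.append(f"accuracy = {self.accuracy:.4f}")
        return "\n".join(lines)


def evaluate(model, features: np.ndarray, labels: np.ndarray,
             class_names) -> ConfusionMatrix:
    """Confusion matrix of a trained classifier on a test set."""
    pred = model.predict(np.asarray(features, dtype=np.float64))
    return ConfusionMatrix.from_predictions(labels, pred, class_names)


def pca_projection(values: np.ndarray, n_components: int = 2) -> np.ndarray:
    """PCA scores of per-conformation features (applied to the raw
    feature space, components ordered by explained variance)."""
    from sklearn.decomposition import PCA
    flat = np.asarray(values, dtype=float).reshape(len(values), -1)
    return PCA(n_components=n_components).fit_transform(flat)


def accuracy_vs_classes(dataset_fn, class_ladder, feature_kinds,
                        seed: int = 0) -> dict:
    """Accuracy of each feature kind as the class ladder grows.

    ``dataset_fn(class_names, feature_kind)`` must return
    ``(X_train, y_train, X_test, y_test, spec, config)``; each ladder
    prefix (at least two classes) is trained and scored independently,
    at equal per-class budget.
    """
    from .models import train_classifier

    curves: dict = {kind: [] for kind in feature_kinds}
    ladder_points = []
    for upto in range(2, len(class_ladder) + 1):
        names = list(class_ladder[:upto])
        ladder_points.append(upto)
        for kind in feature_kinds:
            Xtr, ytr, Xte, yte, spec, config = dataset_fn(names, kind)
            model, _ = train_classifier(Xtr, ytr, spec, config)
            cm = evaluate(model, Xte, yte, names)
            curves[kind].append(cm.accuracy)
    return {"n_classes": ladder_points, "accuracy": curves}
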