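"""JSON-portable CART wrapper shared by the color and shape classifiers.

Trees are fitted with scikit-learn, then flattened into plain arrays so a
trained model serializes to readable JSON (split feature, threshold, leaf
class posteriors) and prediction does not depend on the sklearn object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = ["PortableTree"]


@dataclass
class PortableTree:
    """Flattened decision tree with leaf class posteriors."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    posterior: np.ndarray  # (n_nodes, n_classes) class probabilities
    classes: list = field(default_factory=list)
    training_accuracy: float = float("nan")

    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        *,
        max_depth: int = 8,
        min_samples_leaf: int = 5,
        seed: int = 0,
    ) -> "PortableTree":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        clf = DecisionTreeClassifier(
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=int(seed) & 0x7FFFFFFF,
        )
        clf.fit(X, y)
        t = clf.tree_
        counts = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
        post = counts / counts.sum(axis=1, keepdims=True)
        tree = cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            posterior=post,
            classes=[str(c) for c in clf.classes_],
        )
        tree.training_accuracy = float(np.mean(tree.predict(X) == y.astype(str)))
        return tree

    def _leaf_nodes(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.children_left[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            n = node[idx]
            go_left = X[idx, self.feature[n]] <= self.threshold[n]
            node[idx] = np.where(go_left, self.children_left[n], self.children_right[n])
            active = self.children_left[node] >= 0
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class label (string) per row of X."""
        post = self.posterior[self._leaf_nodes(X)]
        return np.asarray(self.classes)[np.argmax(post, axis=1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.posterior[self._leaf_nodes(X)]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "posterior": self.posterior.tolist(),
            "classes": list(self.classes),
            "training_accuracy": self.training_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PortableTree":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            posterior=np.asarray(d["posterior"], dtype=np.float64),
            classes=list(d["classes"]),
            training_accuracy=float(d.get("training_accuracy", float("nan"))),
        )
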