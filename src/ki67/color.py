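"""Rough nuclei-pixel detection and 3-class pixel color classification.

After STRESS enhancement, candidate nuclei pixels are the ones whose mean
RGB value is at most 225 (the enhancement pushes background towards white
and nuclei towards saturated brown/blue, so a single threshold suffices;
values in [200, 240] behave similarly).  Candidates are then classified
into POS (DAB brown), NEG (hematoxylin blue) or BACK by a decision tree
over three color features per pixel: red channel, blue channel, and HSV
hue scaled to [0, 1).  BACK pixels are discarded; the rest split into the
positive and negative nuclei masks processed downstream.

The tree is trained on — and applied to — the colors of the *preprocessed*
field, the image experts annotate.  The enhanced image only serves the
candidate threshold: envelope stretching maximizes local contrast but, in
doing so, discards the absolute color that separates the two stains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from ._tree import PortableTree

__all__ = [
    "ColorTrainingSet",
    "ColorTreeModel",
    "encode_pixels",
    "train_color_tree",
    "rough_candidate_mask",
    "split_nuclei_masks",
]

CLASSES = ("POS", "NEG", "BACK")
FEATURE_NAMES = ("red", "blue", "hue")


def encode_pixels(image: np.ndarray, selection: np.ndarray) -> np.ndarray:
    """Code selected pixels as (red, blue, hue) rows in row-major order.

    Red and blue are on the native 0–255 scale; hue comes from the standard
    RGB→HSV conversion and lies in [0, 1).
    """
    image = np.asarray(image, dtype=np.float64)
    selection = np.asarray(selection, dtype=bool)
    if selection.shape != image.shape[:2]:
        raise ValueError("selection shape must match image")
    px = image[selection]  # row-major
    if px.size == 0:
        return np.empty((0, 3), dtype=np.float64)
    hue = rgb2hsv(px[None, :, :] / 255.0)[0, :, 0] % 1.0
    return np.column_stack([px[:, 0], px[:, 2], hue])


@dataclass
class ColorTrainingSet:
    """Coded pixels and their POS/NEG/BACK labels."""

    codes: np.ndarray  # (n, 3)
    labels: np.ndarray  # (n,) str

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.codes.shape[0] != self.labels.shape[0]:
            raise ValueError("codes and labels length mismatch")

    def class_counts(self) -> dict:
        return {c: int(np.sum(self.labels == c)) for c in CLASSES}


@dataclass
class ColorTreeModel:
    """3-class pixel classifier over (red, blue, hue)."""

    tree: PortableTree
    class_counts: dict
    seed: int = 0

    @property
    def training_accuracy(self) -> float:
        return self.tree.training_accuracy

    def predict(self, codes: np.ndarray) -> np.ndarray:
        return self.tree.predict(codes)

    def save(self, path) -> None:
        payload = {
            "kind": "color_tree",
            "feature_names": list(FEATURE_NAMES),
            "class_counts": self.class_counts,
            "seed": self.seed,
            "tree": self.tree.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ColorTreeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tree=PortableTree.from_dict(d["tree"]),
            class_counts=dict(d.get("class_counts", {})),
            seed=int(d.get("seed", 0)),
        )


def train_color_tree(
    ts: ColorTrainingSet,
    seed: int = 0,
    *,
    max_depth: int = 8,
    min_samples_leaf: int = 5,
) -> ColorTreeModel:
    """Fit the 3-class pixel tree; all three classes must be present."""
    counts = ts.class_counts()
    for cls_name, n in counts.items():
        if n == 0:
            raise ValueError(f"training set has no {cls_name} pixels")
    tree = PortableTree.fit(
        ts.codes, ts.labels, max_depth=max_depth, min_samples_leaf=min_samples_leaf, seed=seed
    )
    return ColorTreeModel(tree=tree, class_counts=counts, seed=seed)


def rough_candidate_mask(enhanced: np.ndarray, threshold: float = 225.0) -> np.ndarray:
    """Pixels whose mean over R, G, B is <= threshold (boundary included)."""
    enhanced = np.asarray(enhanced, dtype=np.float64)
    return enhanced.mean(axis=2) <= threshold


def split_nuclei_masks(
    image: np.ndarray, candidates: np.ndarray, model: ColorTreeModel
) -> tuple:
    """Split candidate pixels into (positive, negative) nuclei masks.

    ``image`` is the preprocessed field whose colors the tree was trained
    on.  BACK-classified candidates are discarded; the returned masks are
    disjoint subsets of ``candidates``.
    """
    candidates = np.asarray(candidates, dtype=bool)
    m_pos = np.zeros_like(candidates)
    m_neg = np.zeros_like(candidates)
    if candidates.any():
        codes = encode_pixels(image, candidates)
        labels = model.predict(codes)
        rows, cols = np.nonzero(candidates)
        pos = labels == "POS"
        neg = labels == "NEG"
        m_pos[rows[pos], cols[pos]] = True
        m_neg[rows[neg], cols[neg]] = True
    return m_pos, m_neg
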