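"""Morphological shape statistics, region descriptors, and shape classifiers.

Nuclei in IHC fields are round-ish blobs whose size differs by stain:
DAB-positive nuclei are generally bigger than hematoxylin-negative ones.
From training annotations we harvest twelve area/radius statistics
(min/median/max of area and radius, per polarity) and describe every
candidate binary region by a 20-dimensional morphological feature vector.
Two binary decision trees — one per polarity — learn to tell nucleus-shaped
regions from everything else (elongated fragments, oversized merges, tiny
specks).

Conventions: regions are single 8-connected components; the region "ellipse"
is the second-central-moments ellipse; compactness is the isoperimetric
ratio 4*pi*A/P^2; skeleton-to-border distances come from the Euclidean
distance transform sampled on the topological skeleton; a region's scalar
radius is the mean of its min and max skeleton-to-border distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _sk_perimeter
from skimage.measure import regionprops
from skimage.morphology import skeletonize

from ._tree import PortableTree

__all__ = [
    "NucleiShapeStats",
    "ShapeTreeModel",
    "FEATURE_NAMES",
    "compute_nuclei_stats",
    "region_features",
    "train_shape_tree",
    "classify_region",
    "region_radii",
]

EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element

FEATURE_NAMES = (
    "compactness",
    "eccentricity",
    "min_axis",
    "max_axis",
    "convex_area",
    "perimeter",
    "area",
    "perim_over_area",
    "min_rad",
    "max_rad",
    "min_rad_over_max_rad",
    "bbox_area",
    "area_over_bbox",
    "area_over_min_a",
    "area_over_med_a",
    "area_over_max_a",
    "min_axis_over_min_r",
    "max_axis_over_max_r",
    "min_axis_over_med_r",
    "max_axis_over_med_r",
)


@dataclass(frozen=True)
class NucleiShapeStats:
    """Area/radius statistics of annotated nuclei, per polarity (pixels)."""

    min_ap: float
    med_ap: float
    max_ap: float
    min_an: float
    med_an: float
    max_an: float
    min_rp: float
    med_rp: float
    max_rp: float
    min_rn: float
    med_rn: float
    max_rn: float

    def __post_init__(self) -> None:
        for tag in ("ap", "an", "rp", "rn"):
            lo = getattr(self, f"min_{tag}")
            md = getattr(self, f"med_{tag}")
            hi = getattr(self, f"max_{tag}")
            if not (0 < lo <= md <= hi):
                raise ValueError(f"stats triple min/med/max_{tag} must be positive and ordered")

    def area_triple(self, polarity: str) -> tuple:
        if polarity == "POS":
            return (self.min_ap, self.med_ap, self.max_ap)
        if polarity == "NEG":
            return (self.min_an, self.med_an, self.max_an)
        raise ValueError(f"unknown polarity {polarity!r}")

    def radius_triple(self, polarity: str) -> tuple:
        if polarity == "POS":
            return (self.min_rp, self.med_rp, self.max_rp)
        if polarity == "NEG":
            return (self.min_rn, self.med_rn, self.max_rn)
        raise ValueError(f"unknown polarity {polarity!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NucleiShapeStats":
        return cls(**{k: float(v) for k, v in d.items()})


def _crop(region: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(region)
    return region[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]


def region_radii(region: np.ndarray) -> tuple:
    """(min, max) Euclidean distance from the region skeleton to the border.

    Falls back to the single deepest pixel when the region is too small to
    skeletonize.
    """
    region = np.asarray(region, dtype=bool)
    crop = np.pad(_crop(region), 1)
    edt = ndimage.distance_transform_edt(crop)
    skel = skeletonize(crop)
    if not skel.any():
        peak = float(edt.max())
        return (peak, peak)
    d = edt[skel]
    return (float(d.min()), float(d.max()))


def _validate_region(region: np.ndarray, min_pixels: int = 5) -> np.ndarray:
    region = np.asarray(region, dtype=bool)
    n = int(region.sum())
    if n < min_pixels:
        raise ValueError(f"region has {n} pixels; at least {min_pixels} required")
    _, ncomp = ndimage.label(region, structure=EIGHT)
    if ncomp != 1:
        raise ValueError(f"region must be a single 8-connected component, found {ncomp}")
    return region


def region_features(
    region: np.ndarray, stats: NucleiShapeStats, polarity: str
) -> np.ndarray:
    """20-feature morphological descriptor of one binary region.

    The first 13 entries are polarity-free geometry; the last 7 relate the
    region's area and ellipse axes to the annotated size statistics of the
    requested polarity, so the same geometry is coded differently for the
    positive- and the negative-nucleus classifier.
    """
    region = _validate_region(region)
    crop = _crop(region)
    rp = regionprops(crop.astype(np.uint8))[0]
    area = float(rp.area)
    perim = float(_sk_perimeter(crop, neighborhood=4))
    if perim <= 0:
        perim = 1.0
    min_axis = float(rp.axis_minor_length)
    max_axis = float(rp.axis_major_length)
    if max_axis <= 0:  # degenerate single-row/col blobs
        max_axis = float(max(crop.shape))
    if min_axis <= 0:
        min_axis = 1.0
    min_rad, max_rad = region_radii(crop)
    min_rad = max(min_rad, 0.5)
    max_rad = max(max_rad, min_rad)
    bbox_area = float(crop.shape[0] * crop.shape[1])
    min_a, med_a, max_a = stats.area_triple(polarity)
    min_r, med_r, max_r = stats.radius_triple(polarity)
    feats = np.array(
        [
            4.0 * math.pi * area / perim**2,
            float(rp.eccentricity),
            min_axis,
            max_axis,
            float(rp.area_convex),
            perim,
            area,
            perim / area,
            min_rad,
            max_rad,
            min_rad / max_rad,
            bbox_area,
            area / bbox_area,
            area / min_a,
            area / med_a,
            area / max_a,
            min_axis / min_r,
            max_axis / max_r,
            min_axis / med_r,
            max_axis / med_r,
        ],
        dtype=np.float64,
    )
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite region features")
    return feats


def compute_nuclei_stats(regions: Sequence, polarities: Sequence) -> NucleiShapeStats:
    """Harvest the 12 area/radius statistics from annotated nucleus regions.

    Parameters
    ----------
    regions
        Binary masks (one 8-connected component each), rasterized from the
        training polygons.
    polarities
        'POS' / 'NEG' per region.
    """
    areas = {"POS": [], "NEG": []}
    radii = {"POS": [], "NEG": []}
    for reg, pol in zip(regions, polarities):
        reg = np.asarray(reg, dtype=bool)
        if pol not in areas:
            raise ValueError(f"unknown polarity {pol!r}")
        areas[pol].append(float(reg.sum()))
        lo, hi = region_radii(reg)
        radii[pol].append(0.5 * (lo + hi))
    for pol in ("POS", "NEG"):
        if not areas[pol]:
            raise ValueError(f"no {pol} regions in annotations")
    return NucleiShapeStats(
        min_ap=min(areas["POS"]),
        med_ap=float(np.median(areas["POS"])),
        max_ap=max(areas["POS"]),
        min_an=min(areas["NEG"]),
        med_an=float(np.median(areas["NEG"])),
        max_an=max(areas["NEG"]),
        min_rp=min(radii["POS"]),
        med_rp=float(np.median(radii["POS"])),
        max_rp=max(radii["POS"]),
        min_rn=min(radii["NEG"]),
        med_rn=float(np.median(radii["NEG"])),
        max_rn=max(radii["NEG"]),
    )


@dataclass
class ShapeTreeModel:
    """Binary NUCLEUS / NOT_NUCLEUS tree for one polarity, with its stats."""

    tree: PortableTree
    polarity: str
    stats: NucleiShapeStats
    seed: int = 0

    def classify(self, region: np.ndarray) -> str:
        return classify_region(region, self)

    def save(self, path) -> None:
        payload = {
            "kind": "shape_tree",
            "polarity": self.polarity,
            "feature_names": list(FEATURE_NAMES),
            "stats": self.stats.to_dict(),
            "seed": self.seed,
            "tree": self.tree.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ShapeTreeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tree=PortableTree.from_dict(d["tree"]),
            polarity=d["polarity"],
            stats=NucleiShapeStats.from_dict(d["stats"]),
            seed=int(d.get("seed", 0)),
        )


def train_shape_tree(
    nuclei_regions: Sequence,
    background_regions: Sequence,
    stats: NucleiShapeStats,
    polarity: str,
    seed: int = 0,
    *,
    max_depth: int = 8,
) -> ShapeTreeModel:
    """Fit the nucleus-shape tree for one polarity.

    ``nuclei_regions`` are annotated nuclei of that polarity; the same
    ``background_regions`` serve both polarities but are coded with the
    polarity's own size statistics.
    """
    if len(nuclei_regions) < 5 or len(background_regions) < 5:
        raise ValueError("need at least 5 regions per class to train a shape tree")
    X, y = [], []
    for reg in nuclei_regions:
        X.append(region_features(reg, stats, polarity))
        y.append("NUCLEUS")
    for reg in background_regions:
        X.append(region_features(reg, stats, polarity))
        y.append("NOT_NUCLEUS")
    tree = PortableTree.fit(
        np.asarray(X), np.asarray(y), max_depth=max_depth, min_samples_leaf=1, seed=seed
    )
    return ShapeTreeModel(tree=tree, polarity=polarity, stats=stats, seed=seed)


def classify_region(region: np.ndarray, model: ShapeTreeModel) -> str:
    """NUCLEUS / NOT_NUCLEUS decision for one binary region."""
    feats = region_features(region, model.stats, model.polarity)
    return str(model.tree.predict(feats[None, :])[0])
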