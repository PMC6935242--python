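"""Polygon annotations: the training interface of the detector.

Experts train the system by drawing polygons around positive nuclei,
negative nuclei and background regions.  Annotations are stored as JSON::

    {"image": "<path>", "image_shape": [H, W],
     "regions": [{"class": "POS|NEG|BACK", "polygon": [[r, c], ...]}, ...]}

Polygon vertices lie on pixel *corners* (half-integer coordinates), so a
pixel belongs to the region iff its integer-coordinate centre falls
strictly inside the polygon.  That convention makes rasterization exact:
tracing the boundary of a binary mask and rasterizing the traced polygon
reproduces the mask bit for bit (for simply-connected regions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List

import numpy as np
import shapely

__all__ = [
    "AnnotationRegion",
    "AnnotationSet",
    "mask_to_edge_polygon",
    "rasterize_polygon",
]


@dataclass
class AnnotationRegion:
    label: str  # POS | NEG | BACK
    polygon: np.ndarray  # (n, 2) float (row, col) vertices

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or self.polygon.shape[0] < 3:
            raise ValueError("polygon must be an (n>=3, 2) array of (row, col) vertices")


@dataclass
class AnnotationSet:
    regions: List[AnnotationRegion] = field(default_factory=list)
    image_shape: tuple = (0, 0)
    image_path: str = ""

    def by_label(self, label: str) -> list:
        return [r for r in self.regions if r.label == label]

    def rasterize(self, region: AnnotationRegion) -> np.ndarray:
        return rasterize_polygon(region.polygon, self.image_shape)

    def to_json(self, path) -> None:
        payload = {
            "image": self.image_path,
            "image_shape": list(self.image_shape),
            "regions": [
                {"class": r.label, "polygon": r.polygon.tolist()} for r in self.regions
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "AnnotationSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            regions=[AnnotationRegion(r["class"], r["polygon"]) for r in d["regions"]],
            image_shape=tuple(d.get("image_shape", (0, 0))),
            image_path=d.get("image", ""),
        )


def rasterize_polygon(polygon: np.ndarray, shape: tuple) -> np.ndarray:
    """Binary mask of pixels whose centres lie inside the polygon."""
    polygon = np.asarray(polygon, dtype=np.float64)
    poly = shapely.Polygon(polygon)  # x = row, y = col (consistent both ways)
    if not poly.is_valid:  # rings may self-touch at corner junctions
        from shapely.validation import make_valid

        poly = make_valid(poly)
    r0 = max(int(np.floor(polygon[:, 0].min())), 0)
    r1 = min(int(np.ceil(polygon[:, 0].max())) + 1, shape[0])
    c0 = max(int(np.floor(polygon[:, 1].min())), 0)
    c1 = min(int(np.ceil(polygon[:, 1].max())) + 1, shape[1])
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    inside = shapely.contains_xy(poly, rr.ravel().astype(float), cc.ravel().astype(float))
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return mask


# directed pixel-edge segments with the region interior on the right-hand
# side (row axis pointing down): top edge runs west->east, right edge
# north->south, bottom east->west, left south->north.
_SIDES = (
    ((-1, 0), (-0.5, -0.5), (-0.5, 0.5)),
    ((0, 1), (-0.5, 0.5), (0.5, 0.5)),
    ((1, 0), (0.5, 0.5), (0.5, -0.5)),
    ((0, -1), (0.5, -0.5), (-0.5, -0.5)),
)


def mask_to_edge_polygon(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a binary region along pixel edges.

    Returns the closed loop of pixel-corner vertices (row, col), suitable
    for :func:`rasterize_polygon`.  Holes are ignored (nuclei have none).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    h, w = mask.shape
    edges: dict = {}
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows.tolist(), cols.tolist()):
        for (dr, dc), a, b in _SIDES:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w) or not mask[nr, nc]:
                start = (r + a[0], c + a[1])
                end = (r + b[0], c + b[1])
                edges.setdefault(start, []).append(end)
    # start at the outer boundary: topmost-then-leftmost vertex
    start = min(edges)
    loop = [start]
    prev_dir = None
    cur = start
    while True:
        nxts = edges[cur]
        if len(nxts) == 1 or prev_dir is None:
            nxt = nxts[0]
        else:
            # at a corner-touching junction take the sharpest left turn:
            # the walk crosses into the touching lobe and returns, so one
            # ring encloses the whole 8-connected region
            def turn(cand):
                d = (cand[0] - cur[0], cand[1] - cur[1])
                cross = prev_dir[0] * d[1] - prev_dir[1] * d[0]
                dot = prev_dir[0] * d[0] + prev_dir[1] * d[1]
                return np.arctan2(cross, dot)

            nxt = max(nxts, key=turn)
        nxts.remove(nxt)
        prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
        cur = nxt
        if cur == start:
            break
        loop.append(cur)
    return np.asarray(loop, dtype=np.float64)
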