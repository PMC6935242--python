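"""First cluster-separation pass: multiscale Laplacian-of-Gaussian voting.

Isolated nuclei-shaped components are accepted directly by the shape tree
and removed.  The remaining mask is scanned with LoG filters at every
integer radius r in [r_min, r_max] (sigma = r/3, kernel support truncated
at radius r; nuclei are darker than background so the positive LoG
response peaks at nucleus centres).  At each scale the top ``keep_frac``
of in-mask pixels by response each gain one vote.  The vote image is then
thresholded per connected region at a decreasing percentage schedule;
components of the kept pixels that the shape tree accepts are recorded as
detections and removed before the next level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .detections import detection_from_pixels
from .shape import EIGHT, ShapeTreeModel, classify_region

__all__ = [
    "LogConfig",
    "log_vote",
    "extract_isolated_nuclei",
    "iterative_vote_threshold",
    "top_pixels",
]

MIN_REGION_PIXELS = 5  # below this a component cannot be featurized; rejected


@dataclass(frozen=True)
class LogConfig:
    """Scale range and thresholds of the LoG voting pass."""

    r_min: int = 4
    r_max: int = 12
    sigma_factor: float = 1.0 / 3.0
    keep_frac: float = 0.65
    schedule: tuple = (75, 60, 45, 30, 15)

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= self.r_max):
            raise ValueError("need 0 < r_min <= r_max")
        if not (0 < self.keep_frac < 1):
            raise ValueError("keep_frac must be in (0, 1)")
        if any(b >= a for a, b in zip(self.schedule, self.schedule[1:])):
            raise ValueError("schedule must be strictly decreasing")


def top_pixels(values: np.ndarray, count: int) -> np.ndarray:
    """Indices of the ``count`` largest values; ties resolved in input
    (row-major) order so the selection is deterministic."""
    order = np.argsort(-values, kind="stable")
    return order[:count]


def log_vote(
    gray: np.ndarray, mask: np.ndarray, config: LogConfig, with_strength: bool = False
):
    """Accumulate per-pixel votes over the LoG scale range.

    Returns an int32 image; votes are zero outside ``mask`` and bounded by
    the number of scanned radii.  With ``with_strength`` also returns the
    per-pixel sum of z-scored filter responses, used downstream to break
    the large tie blocks that integer votes produce.
    """
    gray = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if gray.shape != mask.shape:
        raise ValueError("gray and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    votes = np.zeros(gray.shape, dtype=np.int32)
    strength = np.zeros(gray.shape, dtype=np.float64)
    rows, cols = np.nonzero(mask)
    n_mask = rows.size
    count = math.ceil(config.keep_frac * n_mask)
    for r in range(config.r_min, config.r_max + 1):
        sigma = config.sigma_factor * r
        # dark blobs on a bright background give a positive LoG response
        resp = ndimage.gaussian_laplace(gray, sigma=sigma, truncate=r / sigma)
        vals = resp[rows, cols]
        sel = top_pixels(vals, count)
        votes[rows[sel], cols[sel]] += 1
        sd = vals.std()
        if sd > 0:
            strength[rows, cols] += (vals - vals.mean()) / sd
    if with_strength:
        return votes, strength
    return votes


def _components(mask: np.ndarray):
    lab, n = ndimage.label(mask, structure=EIGHT)
    return lab, n


def extract_isolated_nuclei(mask: np.ndarray, model: ShapeTreeModel, tile_id: int = 0):
    """Accept already-isolated nuclei-shaped components of the mask.

    Returns ``(detections, residual)``: accepted components become
    detections tagged 'isolated' and are removed; everything else stays in
    the residual mask.
    """
    mask = np.asarray(mask, dtype=bool)
    residual = mask.copy()
    detections = []
    lab, n = _components(mask)
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() < MIN_REGION_PIXELS:
            continue
        if classify_region(comp, model) == "NUCLEUS":
            rows, cols = np.nonzero(comp)
            detections.append(
                detection_from_pixels(rows, cols, model.polarity, "isolated", tile_id)
            )
            residual[comp] = False
    return detections, residual


def iterative_vote_threshold(
    votes: np.ndarray,
    mask: np.ndarray,
    model: ShapeTreeModel,
    schedule=None,
    tile_id: int = 0,
    strength: np.ndarray = None,
):
    """Iteratively threshold the vote image per connected region.

    For each percentage in the (decreasing) schedule and each connected
    region of the current residual, keep the top perc% of region pixels by
    vote; connected components of the kept pixels that the shape tree
    accepts are recorded and removed immediately.  ``strength`` (summed
    filter response) breaks ties between equal integer votes; without it
    ties resolve in row-major order.
    """
    votes = np.asarray(votes)
    residual = np.asarray(mask, dtype=bool).copy()
    if schedule is None:
        schedule = LogConfig().schedule
    detections = []
    for perc in schedule:
        lab, n = _components(residual)
        for i in range(1, n + 1):
            rows, cols = np.nonzero(lab == i)
            if rows.size == 0:  # may already be removed this level
                continue
            count = math.ceil(perc / 100.0 * rows.size)
            v = votes[rows, cols].astype(np.float64)
            if strength is not None:
                order = np.lexsort((np.arange(v.size), -strength[rows, cols], -v))
                sel = order[:count]
            else:
                sel = top_pixels(v, count)
            kept = np.zeros_like(residual)
            kept[rows[sel], cols[sel]] = True
            sub_lab, sub_n = _components(kept)
            for j in range(1, sub_n + 1):
                comp = sub_lab == j
                if comp.sum() < MIN_REGION_PIXELS:
                    continue
                if classify_region(comp, model) == "NUCLEUS":
                    rr, cc = np.nonzero(comp)
                    detections.append(
                        detection_from_pixels(rr, cc, model.polarity, "log", tile_id)
                    )
                    residual[comp] = False
    return detections, residual
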