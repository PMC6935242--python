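"""Second cluster-separation pass: masked-STRESS re-contrast + thresholding.

Regions surviving the LoG pass are usually low-contrast clusters whose
internal nucleus boundaries are barely visible.  For each such region the
gray image is re-enhanced with masked STRESS at every radius from the
region's minimum to its median thickness (thickness = skeleton-to-border
distance), which forces the full dynamic range onto the region and makes
the seams between touching nuclei stand out.  Each enhanced image is then
thresholded at a decreasing schedule of *lowest*-value percentages (nuclei
are the dark part); connected components passing simple eligibility rules
— area strictly below the polarity's maximum annotated area, strictly
above half its minimum, moments-ellipse axis ratio above 0.6 — are
recorded and removed.  Whatever remains after all regions are processed is
admitted as-is: those leftovers are usually nuclei of atypical shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops
from skimage.morphology import skeletonize

from .detections import detection_from_pixels
from .shape import EIGHT, NucleiShapeStats
from .stress import StressParams, masked_stress

__all__ = [
    "StressSeparationConfig",
    "EligibilityRules",
    "region_thickness_range",
    "eligible_nucleus",
    "separate_region",
    "admit_leftovers",
]


@dataclass(frozen=True)
class StressSeparationConfig:
    """Thresholding schedule and STRESS sampling effort of the pass."""

    schedule: tuple = (85, 70, 55, 40, 25)
    n_iter: int = 128
    n_samples: int = 8

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.schedule, self.schedule[1:])):
            raise ValueError("schedule must be strictly decreasing")


@dataclass(frozen=True)
class EligibilityRules:
    """Area window and roundness floor a separated component must satisfy."""

    max_area: float
    min_area_half: float
    axis_ratio_min: float = 0.6
    polarity: str = "POS"

    def __post_init__(self) -> None:
        if not self.min_area_half < self.max_area:
            raise ValueError("min_area_half must be below max_area")
        if not 0 < self.axis_ratio_min < 1:
            raise ValueError("axis_ratio_min must be in (0, 1)")

    @classmethod
    def from_stats(cls, stats: NucleiShapeStats, polarity: str, axis_ratio_min: float = 0.6):
        lo, _, hi = stats.area_triple(polarity)
        return cls(max_area=hi, min_area_half=lo / 2.0, axis_ratio_min=axis_ratio_min,
                   polarity=polarity)


def region_thickness_range(region: np.ndarray) -> tuple:
    """(minimum, median) thickness of a binary region, floored to >= 1.

    Thicknesses are the Euclidean distances between the region skeleton
    and the region border.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        return (1, 1)
    rows, cols = np.nonzero(region)
    crop = np.pad(
        region[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1], 1
    )
    edt = ndimage.distance_transform_edt(crop)
    skel = skeletonize(crop)
    if not skel.any():
        return (1, 1)
    d = edt[skel]
    t_min = max(1, int(math.floor(d.min())))
    t_med = max(t_min, int(math.floor(np.median(d))))
    return (t_min, t_med)


def eligible_nucleus(region: np.ndarray, rules: EligibilityRules) -> bool:
    """All three eligibility rules, with strict inequalities."""
    region = np.asarray(region, dtype=bool)
    area = float(region.sum())
    if not (rules.min_area_half < area < rules.max_area):
        return False
    rows, cols = np.nonzero(region)
    crop = region[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    rp = regionprops(crop.astype(np.uint8))[0]
    major = float(rp.axis_major_length)
    if major <= 0:
        return False
    return float(rp.axis_minor_length) / major > rules.axis_ratio_min


def separate_region(
    gray: np.ndarray,
    region: np.ndarray,
    rules: EligibilityRules,
    config: StressSeparationConfig = StressSeparationConfig(),
    seed: int = 0,
    tile_id: int = 0,
):
    """Split one leftover region into eligible nuclei.

    Returns ``(detections, residual)``.  The region shrinks as components
    are accepted; the loops stop early once it empties.
    """
    gray = np.asarray(gray, dtype=np.float64)
    current = np.asarray(region, dtype=bool).copy()
    detections = []
    if not config.schedule or not current.any():
        return detections, current
    if current.sum() <= rules.min_area_half:
        # no subset of this region can ever satisfy the area rule
        return detections, current
    t_min, t_med = region_thickness_range(current)
    for k, thick in enumerate(range(t_min, t_med + 1)):
        if not current.any():
            break
        params = StressParams(
            n_iter=config.n_iter, n_samples=config.n_samples, radius=thick,
            seed=(seed + k) & 0x7FFFFFFF,
        )
        enhanced = masked_stress(gray, current, params)
        for perc in config.schedule:
            rows, cols = np.nonzero(current)
            if rows.size == 0:
                break
            count = math.ceil(perc / 100.0 * rows.size)
            vals = enhanced[rows, cols]
            # lowest values are nuclei; the cut is by value, so ties at the
            # cutoff are all kept (a flat region stays one whole component)
            cutoff = np.sort(vals)[count - 1]
            sel = vals <= cutoff
            kept = np.zeros_like(current)
            kept[rows[sel], cols[sel]] = True
            lab, n = ndimage.label(kept, structure=EIGHT)
            for i in range(1, n + 1):
                comp = lab == i
                if eligible_nucleus(comp, rules):
                    rr, cc = np.nonzero(comp)
                    detections.append(
                        detection_from_pixels(rr, cc, rules.polarity, "stress", tile_id)
                    )
                    current[comp] = False
    return detections, current


def admit_leftovers(
    residual: np.ndarray, polarity: str, min_area: int = 0, tile_id: int = 0
):
    """Turn every remaining connected component into one detection.

    ``min_area`` (default 0 = admit everything) filters specks if wanted.
    """
    residual = np.asarray(residual, dtype=bool)
    detections = []
    lab, n = ndimage.label(residual, structure=EIGHT)
    for i in range(1, n + 1):
        rows, cols = np.nonzero(lab == i)
        if rows.size <= min_area:
            continue
        detections.append(detection_from_pixels(rows, cols, polarity, "leftover", tile_id))
    return detections
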