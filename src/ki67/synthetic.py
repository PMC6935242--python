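"""Seeded synthetic IHC fields with exact ground truth.

The generator emulates the appearance of Ki-67-stained histochemical
fields: DAB-brown positive nuclei and hematoxylin-blue negative nuclei —
positive nuclei drawn larger, matching real material — on a light
background, with a configurable share of low-contrast ("barely visible")
nuclei, touching clusters, "weakly positive" nuclei whose color mixes
brown and blue, unspecific small color deposits, Gaussian noise and
salt-and-pepper noise.  Nuclei are rotated ellipses with axis ratio in
[0.7, 1.0] (nuclei are round-shaped).  It makes no attempt to model real
tissue texture, staining chemistry or scanner optics.

Every field comes with a per-pixel integer label image, per-nucleus
polarity/centroid/faint flags and the true ki67-index, so every stage of
the detector is testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .annotations import AnnotationRegion, AnnotationSet, mask_to_edge_polygon

__all__ = ["SyntheticConfig", "GroundTruth", "generate_field", "export_training_annotations"]

EIGHT = np.ones((3, 3), dtype=bool)


class PackingError(RuntimeError):
    """Raised when the requested nuclei cannot be placed in the field."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic field.

    Defaults describe a 512x512 field at 20x with ~150 nuclei, 30% of them
    positive, 30% placed in touching clusters of 2–3, 15% rendered faint,
    and mild acquisition noise.  Nucleus radii give median areas close to
    the real training material (positive ~192 px, negative ~115 px).
    """

    width: int = 512
    height: int = 512
    n_pos: int = 45
    n_neg: int = 105
    pos_radius_range: tuple = (6.0, 10.0)
    neg_radius_range: tuple = (5.0, 7.0)
    cluster_fraction: float = 0.3
    cluster_size_range: tuple = (2, 3)
    seam_contrast: float = 0.10
    faint_fraction: float = 0.15
    faint_alpha: float = 0.03
    mixed_fraction: float = 0.1
    background_rgb: tuple = (232, 228, 230)
    pos_rgb_mean: tuple = (145, 95, 60)
    neg_rgb_mean: tuple = (80, 90, 160)
    color_jitter_sd: float = 6.0
    rim_lightening: float = 0.15
    texture_sd: float = 12.0
    gaussian_noise_sd: float = 3.0
    salt_pepper_fraction: float = 0.002
    deposit_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("field must be at least 64x64")
        for name in ("cluster_fraction", "faint_fraction", "salt_pepper_fraction",
                     "faint_alpha", "mixed_fraction", "rim_lightening", "seam_contrast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("pos_radius_range", "neg_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive nonempty range")
        if self.cluster_size_range[0] < 2 or self.cluster_size_range[1] < self.cluster_size_range[0]:
            raise ValueError("cluster_size_range must be 2..k")


@dataclass
class GroundTruth:
    """Exact per-pixel and per-nucleus ground truth of a generated field."""

    label_image: np.ndarray  # int32, 0 = background, ids contiguous from 1
    polarity: List[str]  # per nucleus, 'POS' | 'NEG'
    centroids: np.ndarray  # (n, 2) float (row, col)
    faint: np.ndarray  # (n,) bool
    clustered: np.ndarray  # (n,) bool
    true_index: float  # percent
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def n_nuclei(self) -> int:
        return len(self.polarity)

    def nucleus_mask(self, nid: int) -> np.ndarray:
        return self.label_image == nid


def _ellipse_pixels(center, r_major, ratio, angle, shape):
    rr, cc = draw_ellipse(
        center[0], center[1], r_major, r_major * ratio, shape=shape, rotation=angle
    )
    return rr, cc


def generate_field(config: SyntheticConfig):
    """Render one synthetic IHC field.

    Returns ``(image, ground_truth)`` where image is uint8 RGB.  Identical
    configs (same seed) give bit-identical output.  Raises
    :class:`PackingError` when the requested nuclei do not fit.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    n = config.n_pos + config.n_neg
    polarity = np.array(["POS"] * config.n_pos + ["NEG"] * config.n_neg)
    rng.shuffle(polarity)
    radii = np.where(
        polarity == "POS",
        rng.uniform(*config.pos_radius_range, size=n),
        rng.uniform(*config.neg_radius_range, size=n),
    )
    ratios = rng.uniform(0.7, 1.0, size=n)
    angles = rng.uniform(0.0, math.pi, size=n)
    faint = rng.random(n) < config.faint_fraction
    mixed = (polarity == "POS") & (rng.random(n) < config.mixed_fraction)

    # partition nuclei into touching clusters and singletons
    n_clustered = int(round(config.cluster_fraction * n))
    order = rng.permutation(n)
    groups, i = [], 0
    while i < n_clustered:
        size = int(rng.integers(config.cluster_size_range[0], config.cluster_size_range[1] + 1))
        size = min(size, n_clustered - i)
        if size < 2:  # a trailing singleton joins the previous group
            if groups:
                groups[-1].append(order[i])
                i += 1
            break
        groups.append([order[j] for j in range(i, i + size)])
        i += size
    singles = list(order[i:])
    clustered = np.zeros(n, dtype=bool)
    for g in groups:
        clustered[list(g)] = True

    centers = np.full((n, 2), np.nan)
    placed: List[int] = []
    label = np.zeros((h, w), dtype=np.int32)

    def clear_of(idx, cand, min_gap=3.0, exempt=()):
        for j in placed:
            if j in exempt:
                continue
            d = math.hypot(cand[0] - centers[j][0], cand[1] - centers[j][1])
            if d < radii[idx] + radii[j] + min_gap:
                return False
        return True

    def rand_center(idx):
        m = radii[idx] + 2.0
        return (rng.uniform(m, h - m), rng.uniform(m, w - m))

    def stamp(idx, cand, group_ids=()):
        """Rasterize nucleus ``idx`` at ``cand``; earlier ids keep overlap
        pixels, so touching members share a boundary but never pixels.
        Fails when too little of the nucleus would remain visible."""
        rr, cc = _ellipse_pixels(cand, radii[idx], ratios[idx], angles[idx], (h, w))
        if rr.size < 5:
            return False
        hit = label[rr, cc]
        free = hit == 0
        if free.sum() < max(5, 0.5 * rr.size):
            return False
        if group_ids and not np.isin(hit, group_ids).any():
            return False  # member must actually touch its clump
        label[rr[free], cc[free]] = idx + 1
        centers[idx] = cand
        placed.append(idx)
        return True

    max_attempts = 400
    for g in groups:
        anchor = g[0]
        for attempt in range(max_attempts):
            cand = rand_center(anchor)
            if clear_of(anchor, cand) and stamp(anchor, cand):
                break
        else:
            raise PackingError("could not place cluster anchor; field too crowded")
        prev = [anchor]
        for member in g[1:]:
            for attempt in range(max_attempts):
                ref = prev[int(rng.integers(len(prev)))]
                theta = rng.uniform(0.0, 2.0 * math.pi)
                # nuclei abut with slight overlap; they do not interpenetrate
                d = (radii[ref] + radii[member]) * rng.uniform(0.85, 0.98)
                cand = (centers[ref][0] + d * math.cos(theta), centers[ref][1] + d * math.sin(theta))
                m = radii[member] + 2.0
                if not (m <= cand[0] <= h - m and m <= cand[1] <= w - m):
                    continue
                if clear_of(member, cand, exempt=set(g)) and stamp(
                    member, cand, group_ids=[j + 1 for j in g if j != member]
                ):
                    prev.append(member)
                    break
            else:
                raise PackingError("could not attach cluster member; field too crowded")
    for idx in singles:
        for attempt in range(max_attempts):
            cand = rand_center(idx)
            if clear_of(idx, cand) and stamp(idx, cand):
                break
        else:
            raise PackingError("could not place nucleus; field too crowded")

    # colors: per-nucleus jittered class mean; faint nuclei alpha-blend
    # toward background; 'weakly positive' nuclei mix brown and blue.
    # Real nuclei are not flat: radial shading (darkest centre, lighter
    # rim) plus smooth chromatin-like texture whose channels fluctuate
    # independently give the interior the local color structure that the
    # envelope stretch of the enhancement stage relies on.
    bg = np.asarray(config.background_rgb, dtype=np.float64)
    img = np.tile(bg, (h, w, 1))
    pos_mean = np.asarray(config.pos_rgb_mean, dtype=np.float64)
    neg_mean = np.asarray(config.neg_rgb_mean, dtype=np.float64)
    texture = None
    if config.texture_sd > 0:
        texture = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=(h, w, 3)), sigma=(1.5, 1.5, 0.0)
        )
        texture *= config.texture_sd / texture.std()
    # rim shading follows the outline of each *clump*: touching nuclei look
    # like one low-contrast blob whose internal separations are barely
    # visible, which is what makes clusters hard downstream
    depth = np.zeros((h, w))
    units = [list(g) for g in groups] + [[i] for i in singles]
    for unit in units:
        um = np.isin(label, [i + 1 for i in unit])
        rows, cols = np.nonzero(um)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        edt = ndimage.distance_transform_edt(np.pad(um[r0:r1, c0:c1], 1))[1:-1, 1:-1]
        depth[rows, cols] = edt[rows - r0, cols - c0] / max(edt.max(), 1.0)
    def class_mean(idx):
        if mixed[idx]:
            return 0.5 * (pos_mean + neg_mean)
        return pos_mean if polarity[idx] == "POS" else neg_mean

    base_color = np.empty((n, 3))
    for unit in units:
        anchor = unit[0]
        anchor_color = class_mean(anchor) + rng.normal(0.0, config.color_jitter_sd, size=3)
        base_color[anchor] = anchor_color
        for idx in unit[1:]:
            if polarity[idx] == polarity[anchor] and mixed[idx] == mixed[anchor]:
                # same stain inside a clump: nearly identical color
                base_color[idx] = anchor_color + rng.normal(0.0, 2.0, size=3)
            else:
                base_color[idx] = class_mean(idx) + rng.normal(
                    0.0, config.color_jitter_sd, size=3
                )
    base_color = np.clip(base_color, 0.0, 255.0)
    for idx in range(n):
        color = base_color[idx]
        if np.array_equal(np.round(color), np.round(bg)):
            color[1] = max(color[1] - 3.0, 0.0)
        rows, cols = np.nonzero(label == idx + 1)
        paint = np.tile(color, (rows.size, 1))
        if config.rim_lightening > 0:
            blend = config.rim_lightening * (1.0 - depth[rows, cols])
            paint = paint + blend[:, None] * (bg - paint)
        if texture is not None:
            paint = paint + texture[rows, cols]
        if faint[idx]:
            paint = bg + config.faint_alpha * (paint - bg)
        paint = np.clip(paint, 0.0, 255.0)
        # a nucleus pixel never coincides with the clean background color
        same = np.all(np.round(paint) == np.round(bg), axis=1)
        paint[same, 1] = np.maximum(paint[same, 1] - 3.0, 0.0)
        img[rows, cols] = paint

    # touching nuclei meet at a thin, slightly lighter interstice (cell
    # membranes): a subtle seam, much fainter than the nucleus/background
    # contrast.  Its visibility varies per contact — some seams are plainly
    # there, some invisible — which is exactly why the method needs both a
    # shape-scale separation pass and an intensity-amplifying one.
    if config.seam_contrast > 0:
        pair_amp: dict = {}
        seam_amp = np.zeros((h, w))
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            sa = (slice(max(dr, 0), h + min(dr, 0)), slice(max(dc, 0), w + min(dc, 0)))
            sb = (slice(max(-dr, 0), h + min(-dr, 0)), slice(max(-dc, 0), w + min(-dc, 0)))
            la, lb = label[sa], label[sb]
            touch = (la > 0) & (lb > 0) & (la != lb)
            for ia, ib in zip(la[touch].tolist(), lb[touch].tolist()):
                key = (min(ia, ib), max(ia, ib))
                if key not in pair_amp:
                    # every contact shows some optical boundary; how much varies
                    pair_amp[key] = config.seam_contrast * rng.uniform(0.3, 1.7)
            amp = np.array([pair_amp[(min(ia, ib), max(ia, ib))]
                            for ia, ib in zip(la[touch].tolist(), lb[touch].tolist())])
            for sl in (sa, sb):
                tgt_view = seam_amp[sl]
                tgt_view[touch] = np.maximum(tgt_view[touch], amp)
        rows, cols = np.nonzero(seam_amp > 0)
        img[rows, cols] += seam_amp[rows, cols, None] * (bg - img[rows, cols])

    # unspecific deposits: small, high-saturation, non-nucleus blobs on
    # background, not part of the ground truth
    away = ndimage.binary_dilation(label > 0, structure=EIGHT, iterations=3)
    deposit_colors = np.array([[120.0, 35.0, 35.0], [60.0, 45.0, 40.0], [160.0, 60.0, 140.0]])
    for k in range(config.deposit_count):
        for attempt in range(200):
            r0 = rng.uniform(6, h - 6)
            c0 = rng.uniform(6, w - 6)
            rmaj = rng.uniform(1.5, 3.0)
            ratio = rng.uniform(0.3, 0.8)
            ang = rng.uniform(0, math.pi)
            rr, cc = _ellipse_pixels((r0, c0), rmaj, ratio, ang, (h, w))
            if rr.size and not away[rr, cc].any():
                img[rr, cc] = deposit_colors[k % len(deposit_colors)]
                break

    if config.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, config.gaussian_noise_sd, size=img.shape)
    if config.salt_pepper_fraction > 0:
        flip = rng.random((h, w)) < config.salt_pepper_fraction
        vals = np.where(rng.random((h, w)) < 0.5, 0.0, 255.0)
        img[flip] = vals[flip][:, None]
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    objs = ndimage.center_of_mass(label > 0, label, index=np.arange(1, n + 1))
    centroids = np.asarray(objs, dtype=np.float64)
    true_index = 100.0 * config.n_pos / n
    gt = GroundTruth(
        label_image=label,
        polarity=list(polarity),
        centroids=centroids,
        faint=faint,
        clustered=clustered,
        true_index=true_index,
        config=config,
    )
    return image, gt


def _place_background_shape(rng, occupied, shape, kind, med_area):
    """Pixel mask of one synthetic background region (not nucleus-shaped)."""
    h, w = shape
    med_r = math.sqrt(med_area / math.pi)
    for attempt in range(400):
        r0 = rng.uniform(10, h - 10)
        c0 = rng.uniform(10, w - 10)
        ang = rng.uniform(0, math.pi)
        if kind == "bar":  # elongated: eccentric, unlike round nuclei
            rmaj = rng.uniform(1.8, 3.2) * med_r
            ratio = rng.uniform(0.2, 0.45)
        elif kind == "blob":  # round but oversized: a merged-cluster stand-in
            rmaj = rng.uniform(1.7, 2.3) * med_r
            ratio = rng.uniform(0.75, 1.0)
        elif kind == "dumbbell":  # two merged nucleus-sized lobes
            r_a = rng.uniform(0.8, 1.1) * med_r
            r_b = rng.uniform(0.8, 1.1) * med_r
            d = (r_a + r_b) * rng.uniform(0.75, 0.9)
            rr1, cc1 = draw_ellipse(r0, c0, r_a, r_a, shape=shape)
            rr2, cc2 = draw_ellipse(
                r0 + d * math.sin(ang), c0 + d * math.cos(ang), r_b, r_b, shape=shape
            )
            rr = np.concatenate([rr1, rr2])
            cc = np.concatenate([cc1, cc2])
            if rr.size < 5 or occupied[rr, cc].any():
                continue
            mask = np.zeros(shape, dtype=bool)
            mask[rr, cc] = True
            return mask
        else:  # speck: round but far too small
            rmaj = rng.uniform(1.2, 2.2)
            ratio = rng.uniform(0.7, 1.0)
        rr, cc = draw_ellipse(r0, c0, rmaj, rmaj * ratio, shape=shape, rotation=ang)
        if rr.size < 5 or occupied[rr, cc].any():
            continue
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask
    raise PackingError("could not place a background training shape")


def export_training_annotations(gt: GroundTruth, n_per_class: int, seed: int = 0) -> AnnotationSet:
    """Auto-generate the polygon annotations an expert would draw.

    Picks ``n_per_class`` nuclei of each polarity (preferring isolated
    ones, faint or not — experts outline weak nuclei too) and traces their
    exact ground-truth boundaries; adds ``n_per_class`` background regions
    placed away from all nuclei, whose shapes (elongated bars, oversized
    blobs, tiny specks) span what the shape classifiers must reject.
    """
    rng = np.random.default_rng(seed)
    shape = gt.label_image.shape
    regions = []
    pol = np.asarray(gt.polarity)
    for want in ("POS", "NEG"):
        ids = np.flatnonzero(pol == want) + 1
        if ids.size < n_per_class:
            raise ValueError(f"field has only {ids.size} {want} nuclei, need {n_per_class}")
        quality = ~gt.clustered[ids - 1]
        ranked = np.concatenate([rng.permutation(ids[quality]), rng.permutation(ids[~quality])])
        for nid in ranked[:n_per_class]:
            poly = mask_to_edge_polygon(gt.label_image == nid)
            regions.append(AnnotationRegion(want, poly))

    occupied = ndimage.binary_dilation(gt.label_image > 0, structure=EIGHT, iterations=2)
    areas = np.bincount(gt.label_image.ravel())[1:]
    med_area = float(np.median(areas))
    kinds = ["bar", "blob", "speck"]
    for k in range(n_per_class):
        mask = _place_background_shape(rng, occupied, shape, kinds[k % len(kinds)], med_area)
        regions.append(AnnotationRegion("BACK", mask_to_edge_polygon(mask)))
        occupied |= ndimage.binary_dilation(mask, structure=EIGHT, iterations=2)
    return AnnotationSet(regions=regions, image_shape=shape)
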