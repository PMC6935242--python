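"""End-to-end orchestration: preprocess, tile, detect, merge, estimate.

A field is median+Gaussian filtered, split into overlapping 512x512 tiles,
and each tile is processed independently: STRESS color enhancement, rough
candidate thresholding (mean RGB <= 225), 3-class color-tree split into
positive/negative nuclei masks, then per polarity the staged separation —
isolated-shape extraction, multiscale LoG voting, masked-STRESS separation,
leftover admission.  Tile results are recomposed by centroid-proximity
deduplication and summarized per tumor region by three ki67-index
estimators:

* ``index_est`` — percent of detected nuclei that are positive;
* ``area_est`` — percent of segmented nucleus area that is positive;
* ``no_est``   — percent positive of the nucleus *counts estimated from
  area* (polarity area divided by the annotated median nucleus area).

Method parameters were tuned at 20x (0.5 um/px); for other resolutions
every length-type parameter is multiplied by the resolution ratio
(:func:`scale_parameters`).  Ablation switches reproduce the method's
degraded variants: ``no_preproc`` collapses STRESS to identity (N=M=R=1),
``no_log`` and ``no_stress`` empty the respective threshold schedules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage

from .annotations import AnnotationSet
from .color import (
    ColorTrainingSet,
    ColorTreeModel,
    encode_pixels,
    rough_candidate_mask,
    split_nuclei_masks,
    train_color_tree,
)
from .detections import Detection
from .log_multiscale import LogConfig, extract_isolated_nuclei, iterative_vote_threshold, log_vote
from .shape import EIGHT, NucleiShapeStats, ShapeTreeModel, compute_nuclei_stats, train_shape_tree
from .stress import StressParams, stress_enhance
from .stress_separation import (
    EligibilityRules,
    StressSeparationConfig,
    admit_leftovers,
    separate_region,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "AblationFlags",
    "PipelineConfig",
    "Ki67Estimates",
    "TrainedModels",
    "RunResult",
    "scale_parameters",
    "preprocess",
    "luma",
    "tile_image",
    "merge_detections",
    "estimate_indices",
    "train_models",
    "run_field",
    "tissue_mask",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Denoising, tiling and candidate-threshold settings (20x defaults)."""

    median_size: int = 3
    gaussian_sd: float = 0.5
    tile_size: int = 512
    tile_overlap: int = 30
    candidate_threshold: float = 225.0
    resolution_tag: str = "20x"
    scale_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.median_size % 2 != 1:
            raise ValueError("median_size must be odd")
        if not 0 < self.tile_overlap < self.tile_size:
            raise ValueError("need 0 < tile_overlap < tile_size")


@dataclass(frozen=True)
class AblationFlags:
    no_preproc: bool = False  # STRESS N=M=R=1 (identity enhancement)
    no_log: bool = False  # empty LoG vote-threshold schedule
    no_stress: bool = False  # empty masked-STRESS schedule


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = PreprocessConfig()
    stress_n_iter: int = 128
    stress_n_samples: int = 8
    # STRESS sampling radius and LoG scale range default to the *extent*
    # (diameter) of the annotated nuclei: the radius statistics measure the
    # half-extent, while the envelope must reach past a whole nucleus and
    # the LoG scale r (sigma = r/3) must match whole blobs.  The method's
    # own worked example (R = 14 with ~8 px median nucleus radius) uses
    # this scale.
    nucleus_extent_factor: float = 2.0
    stress_radius: Optional[int] = None
    log_r_min: Optional[int] = None
    log_r_max: Optional[int] = None
    keep_frac: float = 0.65
    log_schedule: tuple = (75, 60, 45, 30, 15)
    stress_schedule: tuple = (85, 70, 55, 40, 25)
    # leftover components below this area are dropped; None derives the
    # floor used by the eligibility rules, half the smallest annotated
    # nucleus area (0 admits everything)
    leftover_min_area: Optional[int] = None
    match_radius: Optional[float] = None  # default: median annotated radius
    ablation: AblationFlags = AblationFlags()


@dataclass
class Ki67Estimates:
    """The three ki67-index estimators plus their raw ingredients.

    Estimates are ``None`` (undefined, not zero) when no nuclei were
    detected.
    """

    area_est: Optional[float]
    no_est: Optional[float]
    index_est: Optional[float]
    n_pos: int
    n_neg: int
    area_pos: int
    area_neg: int


@dataclass
class TrainedModels:
    color: ColorTreeModel
    shape_pos: ShapeTreeModel
    shape_neg: ShapeTreeModel

    @property
    def stats(self) -> NucleiShapeStats:
        return self.shape_pos.stats

    def validate(self) -> None:
        if self.shape_pos.polarity != "POS" or self.shape_neg.polarity != "NEG":
            raise ValueError("shape models carry wrong polarity tags")


@dataclass
class RunResult:
    estimates: Dict[int, Ki67Estimates]
    detections: Dict[int, List[Detection]]

    @property
    def all_detections(self) -> List[Detection]:
        return [d for dets in self.detections.values() for d in dets]


def _round_odd_up(x: float) -> int:
    k = int(math.ceil(x))
    return k if k % 2 == 1 else k + 1


def scale_parameters(config: PipelineConfig, ratio: float) -> PipelineConfig:
    """Adapt every length-type parameter to a new resolution.

    ``ratio`` is (new resolution)/(20x); at 40x it is 2 and e.g. the median
    filter grows from 3 to 7 px (rounded up to odd), the Gaussian sigma
    from 0.5 to 1, and the STRESS sampling effort doubles (N 128->256,
    M 8->16).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio == 1.0:
        return config
    pp = config.preprocess
    pp2 = replace(
        pp,
        median_size=_round_odd_up(pp.median_size * ratio),
        gaussian_sd=pp.gaussian_sd * ratio,
        scale_ratio=pp.scale_ratio * ratio,
        resolution_tag=f"{pp.resolution_tag}*{ratio:g}",
    )
    scale_len = lambda v: None if v is None else max(1, int(round(v * ratio)))
    return replace(
        config,
        preprocess=pp2,
        stress_n_iter=int(round(config.stress_n_iter * ratio)),
        stress_n_samples=int(round(config.stress_n_samples * ratio)),
        stress_radius=scale_len(config.stress_radius),
        log_r_min=scale_len(config.log_r_min),
        log_r_max=scale_len(config.log_r_max),
        match_radius=None if config.match_radius is None else config.match_radius * ratio,
    )


def preprocess(image: np.ndarray, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Median then Gaussian filtering, per channel."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    k = config.median_size
    out = ndimage.median_filter(img, size=(k, k, 1))
    out = ndimage.gaussian_filter(out, sigma=(config.gaussian_sd, config.gaussian_sd, 0.0))
    out = np.clip(out, 0, 255)
    return out[:, :, 0] if np.asarray(image).ndim == 2 else out


def luma(image: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 gray conversion."""
    img = np.asarray(image, dtype=np.float64)
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


def _starts(dim: int, tile: int, overlap: int) -> list:
    if dim <= tile:
        return [0]
    step = tile - overlap
    starts = list(range(0, dim - tile + 1, step))
    if starts[-1] != dim - tile:
        starts.append(dim - tile)
    return starts


def tile_image(image: np.ndarray, tile_size: int, overlap: int):
    """Overlapping tile views with their (row, col) offsets; covers the image."""
    h, w = image.shape[:2]
    tiles = []
    for r0 in _starts(h, tile_size, overlap):
        for c0 in _starts(w, tile_size, overlap):
            tiles.append((image[r0 : r0 + tile_size, c0 : c0 + tile_size], (r0, c0)))
    return tiles


_STAGE_RANK = {"isolated": 0, "log": 1, "stress": 2, "leftover": 3}


def merge_detections(dets: List[Detection], match_radius) -> List[Detection]:
    """Deduplicate double counts by centroid proximity.

    Same-polarity detections whose centroids are within ``match_radius``
    collapse onto one instance: the earlier-stage detection wins (stages
    with stricter evidence first), then the larger area.  Handles both
    tile-overlap duplicates and remnant fragments of already-separated
    nuclei.  ``match_radius`` may be a scalar or a per-polarity dict.
    """
    if not isinstance(match_radius, dict):
        match_radius = {"POS": float(match_radius), "NEG": float(match_radius)}
    merged: List[Detection] = []
    kept_pts = {"POS": [], "NEG": []}
    for det in sorted(dets, key=lambda d: (_STAGE_RANK.get(d.stage, 9), -d.area)):
        pts = kept_pts[det.polarity]
        rad = match_radius[det.polarity]
        dup = any(
            (det.centroid[0] - p[0]) ** 2 + (det.centroid[1] - p[1]) ** 2 <= rad**2
            for p in pts
        )
        if not dup:
            merged.append(det)
            pts.append(det.centroid)
    return merged


def estimate_indices(dets: List[Detection], stats: NucleiShapeStats) -> Ki67Estimates:
    """The three ki67-index estimators from a final detection set."""
    n_pos = sum(1 for d in dets if d.polarity == "POS")
    n_neg = sum(1 for d in dets if d.polarity == "NEG")
    area_pos = sum(d.area for d in dets if d.polarity == "POS")
    area_neg = sum(d.area for d in dets if d.polarity == "NEG")
    if n_pos + n_neg == 0:
        return Ki67Estimates(None, None, None, 0, 0, 0, 0)
    index_est = 100.0 * n_pos / (n_pos + n_neg)
    area_est = 100.0 * area_pos / (area_pos + area_neg) if area_pos + area_neg else None
    cnt_pos = area_pos / stats.med_ap
    cnt_neg = area_neg / stats.med_an
    no_est = 100.0 * cnt_pos / (cnt_pos + cnt_neg) if cnt_pos + cnt_neg > 0 else None
    return Ki67Estimates(area_est, no_est, index_est, n_pos, n_neg, area_pos, area_neg)


def tissue_mask(image: np.ndarray, luminance_threshold: float = 240.0) -> np.ndarray:
    """Trivial tissue-area stand-in: luminance threshold + largest component."""
    dark = luma(image) <= luminance_threshold
    lab, n = ndimage.label(dark, structure=EIGHT)
    if n == 0:
        return dark
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(np.argmax(sizes))


def train_models(
    image: np.ndarray,
    annotations: AnnotationSet,
    *,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> TrainedModels:
    """Train the color tree and both shape trees from polygon annotations.

    The field is preprocessed exactly as at run time; the color tree codes
    the preprocessed pixel colors — the appearance experts annotated.
    """
    pre = preprocess(image, config.preprocess)
    nuc_regions, nuc_pols = [], []
    back_regions = []
    for reg in annotations.regions:
        mask = annotations.rasterize(reg)
        if reg.label in ("POS", "NEG"):
            nuc_regions.append(mask)
            nuc_pols.append(reg.label)
        elif reg.label == "BACK":
            back_regions.append(mask)
        else:
            raise ValueError(f"unknown annotation class {reg.label!r}")
    stats = compute_nuclei_stats(nuc_regions, nuc_pols)

    codes, labels = [], []
    for reg, mask in zip(annotations.regions, map(annotations.rasterize, annotations.regions)):
        c = encode_pixels(pre, mask)
        codes.append(c)
        labels.append(np.full(c.shape[0], reg.label))
    ts = ColorTrainingSet(np.concatenate(codes), np.concatenate(labels))
    color = train_color_tree(ts, seed=seed)

    pos_regions = [m for m, p in zip(nuc_regions, nuc_pols) if p == "POS"]
    neg_regions = [m for m, p in zip(nuc_regions, nuc_pols) if p == "NEG"]
    shape_pos = train_shape_tree(pos_regions, back_regions, stats, "POS", seed=seed)
    shape_neg = train_shape_tree(neg_regions, back_regions, stats, "NEG", seed=seed)
    return TrainedModels(color=color, shape_pos=shape_pos, shape_neg=shape_neg)


def _attach_remnants(
    dets: List[Detection],
    leftovers: List[Detection],
    shape: tuple,
    min_radius: float,
) -> List[Detection]:
    """Attribute thin leftover fragments to the nucleus they wrap around.

    Separating a cluster removes vote/intensity cores, which can strand a
    thin arc of a nucleus's outer pixels in the residual.  Such an arc is
    thinner than any plausible nucleus and touches the detection it came
    from; its pixels belong to that nucleus, not to a new one.  Leftover
    components that are thick enough to be nuclei of atypical shape are
    kept as detections.
    """
    from .stress_separation import region_thickness_range

    owner = np.full(shape, -1, dtype=np.int64)
    for i, d in enumerate(dets):
        owner[d.rows, d.cols] = i
    kept: List[Detection] = []
    for lo in leftovers:
        m = np.zeros(shape, dtype=bool)
        m[lo.rows, lo.cols] = True
        _, t_med = region_thickness_range(m)
        contact = np.full(lo.rows.size * 9, -1, dtype=np.int64)
        k = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr = np.clip(lo.rows + dr, 0, shape[0] - 1)
                cc = np.clip(lo.cols + dc, 0, shape[1] - 1)
                contact[k : k + lo.rows.size] = owner[rr, cc]
                k += lo.rows.size
        contact = contact[contact >= 0]
        if t_med < 0.8 * min_radius and contact.size:
            host = dets[int(np.bincount(contact).argmax())]
            host.rows = np.concatenate([host.rows, lo.rows])
            host.cols = np.concatenate([host.cols, lo.cols])
            host.centroid = (float(host.rows.mean()), float(host.cols.mean()))
        else:
            kept.append(lo)
    return dets + kept


def _tile_seed(seed: int, region_id: int, tile_id: int, salt: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(region_id), int(tile_id), int(salt)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_field(
    image: np.ndarray,
    models: TrainedModels,
    config: PipelineConfig = PipelineConfig(),
    tumor_masks: Optional[Dict[int, np.ndarray]] = None,
    seed: int = 0,
) -> RunResult:
    """Detect nuclei and estimate the ki67-index of every tumor region.

    ``tumor_masks`` maps region id -> binary mask (default: one region
    covering the whole field — tumor identification is a manual input).
    Fully seeded: identical inputs and seed give identical detections.
    """
    if models is None:
        raise ValueError("trained models are required")
    models.validate()
    stats = models.stats
    flags = config.ablation
    pp = config.preprocess
    pre = preprocess(image, pp)
    if tumor_masks is None:
        tumor_masks = {0: np.ones(pre.shape[:2], dtype=bool)}

    ext = config.nucleus_extent_factor
    if flags.no_preproc:
        stress_params = dict(n_iter=1, n_samples=1, radius=1)
    else:
        radius = config.stress_radius or int(math.ceil(ext * max(stats.max_rp, stats.max_rn)))
        stress_params = dict(
            n_iter=config.stress_n_iter, n_samples=config.stress_n_samples, radius=radius
        )
    r_min = config.log_r_min or max(1, int(math.floor(ext * min(stats.min_rp, stats.min_rn))))
    r_max = config.log_r_max or max(r_min, int(math.ceil(ext * max(stats.max_rp, stats.max_rn))))
    log_cfg = LogConfig(
        r_min=r_min, r_max=r_max, keep_frac=config.keep_frac,
        schedule=() if flags.no_log else tuple(config.log_schedule),
    )
    sep_cfg = StressSeparationConfig(
        schedule=() if flags.no_stress else tuple(config.stress_schedule),
        n_iter=stress_params["n_iter"], n_samples=stress_params["n_samples"],
    )
    if config.match_radius is not None:
        match_radius = {"POS": config.match_radius, "NEG": config.match_radius}
    else:
        match_radius = {"POS": stats.med_rp, "NEG": stats.med_rn}
    rules = {
        "POS": EligibilityRules.from_stats(stats, "POS"),
        "NEG": EligibilityRules.from_stats(stats, "NEG"),
    }
    if config.leftover_min_area is None:
        leftover_min_area = int(min(stats.min_ap, stats.min_an) / 2.0)
    else:
        leftover_min_area = config.leftover_min_area
    shape_models = {"POS": models.shape_pos, "NEG": models.shape_neg}

    estimates: Dict[int, Ki67Estimates] = {}
    detections: Dict[int, List[Detection]] = {}
    for region_id, tmask in tumor_masks.items():
        tmask = np.asarray(tmask, dtype=bool)
        region_dets: List[Detection] = []
        for tile_id, (tile, (r0, c0)) in enumerate(
            tile_image(pre, pp.tile_size, pp.tile_overlap)
        ):
            th, tw = tile.shape[:2]
            tile_tumor = tmask[r0 : r0 + th, c0 : c0 + tw]
            if not tile_tumor.any():
                continue
            sp = StressParams(seed=_tile_seed(seed, region_id, tile_id, 0), **stress_params)
            enhanced = stress_enhance(tile, sp)
            cand = rough_candidate_mask(enhanced, pp.candidate_threshold) & tile_tumor
            m_pos, m_neg = split_nuclei_masks(tile, cand, models.color)
            gray = luma(tile)
            for salt, (polarity, mask) in enumerate([("POS", m_pos), ("NEG", m_neg)], start=1):
                if not mask.any():
                    continue
                smodel = shape_models[polarity]
                dets, residual = extract_isolated_nuclei(mask, smodel, tile_id)
                if log_cfg.schedule and residual.any():
                    votes, strength = log_vote(gray, residual, log_cfg, with_strength=True)
                    more, residual = iterative_vote_threshold(
                        votes, residual, smodel, log_cfg.schedule, tile_id, strength=strength
                    )
                    dets.extend(more)
                if sep_cfg.schedule and residual.any():
                    lab, n = ndimage.label(residual, structure=EIGHT)
                    for i in range(1, n + 1):
                        comp = lab == i
                        more, rest = separate_region(
                            gray, comp, rules[polarity], sep_cfg,
                            seed=_tile_seed(seed, region_id, tile_id, salt * 1000 + i),
                            tile_id=tile_id,
                        )
                        dets.extend(more)
                        residual[comp & ~rest] = False
                leftover_dets = admit_leftovers(
                    residual, polarity, leftover_min_area, tile_id
                )
                min_rad = stats.min_rp if polarity == "POS" else stats.min_rn
                dets = _attach_remnants(dets, leftover_dets, tile.shape[:2], min_rad)
                logger.debug(
                    "region %s tile %s %s: %d detections (%s)",
                    region_id, tile_id, polarity, len(dets),
                    {s: sum(1 for d in dets if d.stage == s)
                     for s in ("isolated", "log", "stress", "leftover")},
                )
                for d in dets:
                    d.tumor_region_id = region_id
                region_dets.extend(d.shifted(r0, c0) for d in dets)
        merged = merge_detections(region_dets, match_radius)
        logger.info(
            "tumor region %s: %d detections after merging (%d before)",
            region_id, len(merged), len(region_dets),
        )
        detections[region_id] = merged
        estimates[region_id] = estimate_indices(merged, stats)
    return RunResult(estimates=estimates, detections=detections)
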