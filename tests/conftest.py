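"""Shared fixtures: one trained model set and matching helpers.

Training a model set costs ~15 s (the STRESS enhancement of the training
field dominates), so it is session-scoped and shared by every test that
needs trained classifiers.
"""

from __future__ import annotations

import numpy as np
import pytest

from ki67.pipeline import train_models
from ki67.synthetic import SyntheticConfig, export_training_annotations, generate_field

TRAIN_SEED = 100


@pytest.fixture(scope="session")
def training_field():
    return generate_field(SyntheticConfig(seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def annotations(training_field):
    _, gt = training_field
    return export_training_annotations(gt, 20, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def models(training_field, annotations):
    image, _ = training_field
    return train_models(image, annotations, seed=0)


@pytest.fixture(scope="session")
def stats(models):
    return models.stats


def match_detections(dets, gt, radius):
    """Greedy one-to-one centroid matching of detections to true nuclei.

    Returns (n_matched, n_detections, n_true); polarity must agree and the
    centroid distance must be within ``radius``.
    """
    used = set()
    pol = np.asarray(gt.polarity)
    tp = 0
    for d in dets:
        best, best_d = None, radius
        for i, (cr, cc) in enumerate(gt.centroids):
            if i in used or pol[i] != d.polarity:
                continue
            dist = ((d.centroid[0] - cr) ** 2 + (d.centroid[1] - cc) ** 2) ** 0.5
            if dist <= best_d:
                best_d, best = dist, i
        if best is not None:
            used.add(best)
            tp += 1
    return tp, len(dets), gt.n_nuclei


def detection_f1(dets, gt, radius):
    tp, n_det, n_true = match_detections(dets, gt, radius)
    precision = tp / max(n_det, 1)
    recall = tp / n_true
    return 2 * precision * recall / max(precision + recall, 1e-9)


def per_nucleus_hit(dets, gt, radius):
    """Boolean per true nucleus: some detection centroid within radius."""
    hit = np.zeros(gt.n_nuclei, dtype=bool)
    for i, (cr, cc) in enumerate(gt.centroids):
        for d in dets:
            if ((d.centroid[0] - cr) ** 2 + (d.centroid[1] - cc) ** 2) ** 0.5 <= radius:
                hit[i] = True
                break
    return hit


def naive_stress(image, mask, params):
    """Literal per-pixel STRESS reference sharing the documented RNG stream.

    Row-major pixel scan; every in-mask pixel consumes n_iter * n_samples
    uniforms; candidates are in-disk, in-bounds, in-mask offsets in
    row-major offset order, centre excluded; degenerate envelopes keep the
    original value; output clamped to [0, 255].
    """
    from ki67.stress import disk_offsets

    arr = np.asarray(image, dtype=np.float64)
    gray = arr.ndim == 2
    if gray:
        arr = arr[:, :, None]
    h, w, nch = arr.shape
    out = arr.copy()
    offs = disk_offsets(params.radius)
    rng = np.random.default_rng(params.seed)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            cand = []
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    cand.append((rr, cc))
            if not cand:
                for _ in range(params.n_iter * params.n_samples):
                    rng.random()
                continue
            ncand = len(cand)
            acc = [0.0] * nch
            for _ in range(params.n_iter):
                mn = [1e300] * nch
                mx = [-1e300] * nch
                for _ in range(params.n_samples):
                    idx = int(rng.random() * ncand)
                    if idx >= ncand:
                        idx = ncand - 1
                    rr, cc = cand[idx]
                    for ch in range(nch):
                        v = arr[rr, cc, ch]
                        if v < mn[ch]:
                            mn[ch] = v
                        if v > mx[ch]:
                            mx[ch] = v
                for ch in range(nch):
                    v0 = arr[r, c, ch]
                    if mx[ch] > mn[ch]:
                        s = (v0 - mn[ch]) * 255.0 / (mx[ch] - mn[ch])
                        s = 0.0 if s < 0.0 else (255.0 if s > 255.0 else s)
                    else:
                        s = v0
                    acc[ch] += s
            for ch in range(nch):
                out[r, c, ch] = acc[ch] / params.n_iter
    return out[:, :, 0] if gray else out
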