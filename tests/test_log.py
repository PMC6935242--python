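"""Multiscale LoG voting and the iterative vote-threshold separation."""

import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from ki67.log_multiscale import (
    LogConfig,
    extract_isolated_nuclei,
    iterative_vote_threshold,
    log_vote,
    top_pixels,
)
from ki67.shape import NucleiShapeStats, train_shape_tree

STATS = NucleiShapeStats(
    min_ap=60, med_ap=192, max_ap=400, min_an=40, med_an=115, max_an=300,
    min_rp=4.0, med_rp=7.8, max_rp=11.0, min_rn=3.0, med_rn=6.0, max_rn=9.0,
)


@pytest.fixture(scope="module")
def disk_tree():
    rng = np.random.default_rng(0)
    disks, negatives = [], []
    for k in range(10):
        r = rng.uniform(4.5, 10.5)
        m = np.zeros((40, 40), bool)
        rr, cc = draw_disk((20, 20), r)
        m[rr, cc] = True
        disks.append(m)
        bar = np.zeros((40, 40), bool)
        r0 = int(rng.integers(4, 30))
        bar[r0 : r0 + 3, 2:38] = True
        negatives.append(bar)
        # merged-pair blobs: what the tree must reject inside clusters
        pair = np.zeros((40, 60), bool)
        rp = rng.uniform(5.5, 8.5)
        for centre in ((20.0, 22.0), (20.0, 22.0 + 1.7 * rp)):
            rr, cc = draw_disk(centre, rp, shape=(40, 60))
            pair[rr, cc] = True
        negatives.append(pair)
        speck = np.zeros((40, 40), bool)  # fragments far below nucleus size
        rr, cc = draw_disk((20, 20), rng.uniform(1.2, 2.2))
        speck[rr, cc] = True
        negatives.append(speck)
    return train_shape_tree(disks, negatives, STATS, "POS", seed=0)


def test_config_invariants():
    with pytest.raises(ValueError):
        LogConfig(r_min=5, r_max=3)
    with pytest.raises(ValueError):
        LogConfig(keep_frac=1.0)
    with pytest.raises(ValueError):
        LogConfig(schedule=(30, 45))
    assert LogConfig(schedule=()).schedule == ()


def test_top_pixels_tie_break_is_stable_row_major():
    vals = np.array([5.0, 5.0, 1.0, 5.0, 2.0])
    assert list(top_pixels(vals, 3)) == [0, 1, 3]


def test_vote_bound_and_off_mask_zero():
    rng = np.random.default_rng(1)
    gray = rng.uniform(0, 255, (40, 40))
    mask = np.zeros((40, 40), bool)
    mask[5:30, 5:30] = True
    cfg = LogConfig(r_min=3, r_max=7)
    votes = log_vote(gray, mask, cfg)
    assert votes.max() <= 7 - 3 + 1
    assert votes[~mask].sum() == 0


def test_single_radius_vote_bound():
    gray = np.full((20, 20), 100.0)
    gray[8:12, 8:12] = 20.0
    mask = np.ones((20, 20), bool)
    votes = log_vote(gray, mask, LogConfig(r_min=4, r_max=4))
    assert votes.max() <= 1


def test_uniform_gray_exact_tie_break_count():
    gray = np.full((16, 16), 90.0)
    mask = np.zeros((16, 16), bool)
    mask[2:12, 3:13] = True
    cfg = LogConfig(r_min=3, r_max=5, keep_frac=0.65)
    votes = log_vote(gray, mask, cfg)
    count = math.ceil(0.65 * mask.sum())
    n_scales = 3
    assert votes.sum() == n_scales * count


def test_dark_disk_max_vote_centroid_near_centre():
    gray = np.full((64, 64), 220.0)
    rr, cc = draw_disk((31.0, 33.0), 6)
    gray[rr, cc] = 60.0
    mask = np.zeros((64, 64), bool)
    mask[rr, cc] = True
    votes = log_vote(gray, mask, LogConfig(r_min=3, r_max=12))
    peak = votes == votes.max()
    prow, pcol = np.nonzero(peak)
    assert abs(prow.mean() - 31.0) <= 1.0 and abs(pcol.mean() - 33.0) <= 1.0


def test_keep_frac_sweep_monotone_selected_counts():
    mask = np.zeros((30, 30), bool)
    mask[4:26, 4:26] = True
    n = mask.sum()
    counts = [math.ceil(kf * n) for kf in (0.55, 0.65, 0.75)]
    assert counts == sorted(counts)
    rng = np.random.default_rng(2)
    gray = rng.uniform(0, 255, (30, 30))
    sums = [
        log_vote(gray, mask, LogConfig(r_min=3, r_max=5, keep_frac=kf)).sum()
        for kf in (0.55, 0.65, 0.75)
    ]
    assert sums == sorted(sums)


def test_extract_isolated_empty_mask(disk_tree):
    dets, residual = extract_isolated_nuclei(np.zeros((20, 20), bool), disk_tree)
    assert dets == [] and not residual.any()


def test_extract_isolated_accepts_disk_rejects_dumbbell(disk_tree):
    mask = np.zeros((48, 48), bool)
    rr, cc = draw_disk((12, 12), 7)
    mask[rr, cc] = True
    dets, residual = extract_isolated_nuclei(mask, disk_tree)
    assert len(dets) == 1 and not residual.any()
    assert dets[0].polarity == "POS" and dets[0].stage == "isolated"

    dumbbell = np.zeros((48, 48), bool)
    for centre in ((30, 18), (30, 29)):
        rr, cc = draw_disk(centre, 7)
        dumbbell[rr, cc] = True
    dets, residual = extract_isolated_nuclei(dumbbell, disk_tree)
    assert dets == []
    assert np.array_equal(residual, dumbbell)


def test_partition_into_detections_and_residual(disk_tree):
    rng = np.random.default_rng(3)
    mask = rng.random((40, 40)) < 0.3
    dets, residual = extract_isolated_nuclei(mask, disk_tree)
    covered = residual.copy()
    for d in dets:
        assert not covered[d.rows, d.cols].any()  # disjoint
        covered[d.rows, d.cols] = True
    assert np.array_equal(covered, mask)  # exact partition


def test_empty_schedule_is_identity(disk_tree):
    mask = np.zeros((30, 30), bool)
    rr, cc = draw_disk((15, 15), 8)
    mask[rr, cc] = True
    votes = np.ones_like(mask, dtype=np.int32)
    dets, residual = iterative_vote_threshold(votes, mask, disk_tree, schedule=())
    assert dets == [] and np.array_equal(residual, mask)


def _always_reject_model():
    from ki67._tree import PortableTree
    from ki67.shape import ShapeTreeModel

    tree = PortableTree(
        children_left=np.array([-1]), children_right=np.array([-1]),
        feature=np.array([-2]), threshold=np.array([-2.0]),
        posterior=np.array([[1.0, 0.0]]), classes=["NOT_NUCLEUS", "NUCLEUS"],
    )
    return ShapeTreeModel(tree=tree, polarity="POS", stats=STATS)


def test_no_accept_path_leaves_residual_unchanged():
    bar = np.zeros((30, 30), bool)
    bar[14:17, 2:28] = True
    votes = np.ones_like(bar, dtype=np.int32)
    dets, residual = iterative_vote_threshold(votes, bar, _always_reject_model())
    assert dets == []
    assert np.array_equal(residual, bar)


def test_dumbbell_with_two_vote_peaks_splits(disk_tree):
    mask = np.zeros((60, 60), bool)
    centres = [(30.0, 20.0), (30.0, 37.0)]
    for centre in centres:
        rr, cc = draw_disk(centre, 8.6)
        mask[rr, cc] = True
    votes = np.zeros((60, 60), dtype=np.int32)
    strength = np.zeros((60, 60))
    for centre in centres:  # synthetic centre-peaked votes
        rr, cc = draw_disk(centre, 8.6)
        d = np.sqrt((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2)
        votes[rr, cc] = np.maximum(votes[rr, cc], (9 - d).astype(np.int32))
        strength[rr, cc] = np.maximum(strength[rr, cc], 9.0 - d)
    dets, residual = iterative_vote_threshold(
        votes, mask, disk_tree, strength=strength
    )
    assert len(dets) == 2
    for d, centre in zip(sorted(dets, key=lambda d: d.centroid[1]), centres):
        assert abs(d.centroid[0] - centre[0]) <= 2.0
        assert abs(d.centroid[1] - centre[1]) <= 2.0
    # monotone shrinkage and containment
    assert residual.sum() <= mask.sum()
    for d in dets:
        assert mask[d.rows, d.cols].all()
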