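"""Region descriptors, shape statistics and the nucleus-shape trees."""

import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from ki67.shape import (
    FEATURE_NAMES,
    NucleiShapeStats,
    classify_region,
    compute_nuclei_stats,
    region_features,
    train_shape_tree,
)

STATS = NucleiShapeStats(
    min_ap=110, med_ap=192, max_ap=300, min_an=60, med_an=115, max_an=200,
    min_rp=4.5, med_rp=7.8, max_rp=10.0, min_rn=3.5, med_rn=6.0, max_rn=8.0,
)


def _disk_mask(radius, pad=4):
    size = 2 * (radius + pad) + 1
    mask = np.zeros((size, size), bool)
    rr, cc = draw_disk((size // 2, size // 2), radius + 0.5)
    mask[rr, cc] = True
    return mask


def moments_ellipse_oracle(mask):
    """Axes and eccentricity from raw second central moments."""
    rows, cols = np.nonzero(mask)
    mu_rr = ((rows - rows.mean()) ** 2).mean()
    mu_cc = ((cols - cols.mean()) ** 2).mean()
    mu_rc = ((rows - rows.mean()) * (cols - cols.mean())).mean()
    common = math.sqrt((mu_rr - mu_cc) ** 2 + 4 * mu_rc**2)
    lam1 = (mu_rr + mu_cc + common) / 2
    lam2 = (mu_rr + mu_cc - common) / 2
    major = 4 * math.sqrt(lam1)
    minor = 4 * math.sqrt(max(lam2, 0.0))
    ecc = math.sqrt(1 - lam2 / lam1) if lam1 > 0 else 0.0
    return major, minor, ecc


def test_feature_vector_has_twenty_named_entries():
    feats = region_features(_disk_mask(8), STATS, "POS")
    assert feats.shape == (20,) and len(FEATURE_NAMES) == 20
    assert np.all(np.isfinite(feats))


def test_polarity_codings_differ_only_in_last_seven():
    mask = _disk_mask(7)
    pos = region_features(mask, STATS, "POS")
    neg = region_features(mask, STATS, "NEG")
    assert np.array_equal(pos[:13], neg[:13])
    assert not np.array_equal(pos[13:], neg[13:])


def test_disk_geometry():
    feats = dict(zip(FEATURE_NAMES, region_features(_disk_mask(10), STATS, "POS")))
    assert feats["eccentricity"] <= 0.1
    assert feats["min_rad_over_max_rad"] >= 0.9
    assert abs(feats["compactness"] - 1.0) <= 0.15
    assert feats["area"] <= feats["convex_area"]
    assert feats["area"] <= feats["bbox_area"]


def test_ratio_identity_at_median_area():
    mask = _disk_mask(8)
    area = mask.sum()
    stats = NucleiShapeStats(
        min_ap=area / 2, med_ap=area, max_ap=2 * area, min_an=60, med_an=115,
        max_an=200, min_rp=4, med_rp=8, max_rp=10, min_rn=3, med_rn=6, max_rn=8,
    )
    feats = dict(zip(FEATURE_NAMES, region_features(mask, stats, "POS")))
    assert feats["area_over_med_a"] == pytest.approx(1.0)


def test_rectangle_against_moment_oracle():
    mask = np.zeros((30, 40), bool)
    mask[5:25, 10:20] = True  # 20 x 10 filled rectangle
    feats = dict(zip(FEATURE_NAMES, region_features(mask, STATS, "NEG")))
    assert feats["area"] == 200
    assert feats["bbox_area"] == 200
    assert feats["area_over_bbox"] == pytest.approx(1.0)
    major, minor, ecc = moments_ellipse_oracle(mask)
    assert feats["max_axis"] == pytest.approx(major, abs=1e-6)
    assert feats["min_axis"] == pytest.approx(minor, abs=1e-6)
    assert feats["eccentricity"] == pytest.approx(ecc, abs=1e-6)
    assert feats["max_axis"] / feats["min_axis"] == pytest.approx(2.0, rel=0.05)


def test_scale_coherence_under_doubling():
    def exact_disk(radius):
        size = 2 * int(radius + 4) + 1
        mask = np.zeros((size, size), bool)
        rr, cc = draw_disk((size // 2, size // 2), radius)
        mask[rr, cc] = True
        return mask

    small = exact_disk(6.5)
    big = exact_disk(13.0)
    f_small = dict(zip(FEATURE_NAMES, region_features(small, STATS, "POS")))
    f_big = dict(zip(FEATURE_NAMES, region_features(big, STATS, "POS")))
    for name in ("area", "convex_area", "bbox_area"):
        assert f_big[name] / f_small[name] == pytest.approx(4.0, rel=0.10)
    for name in ("perimeter", "min_axis", "max_axis", "min_rad", "max_rad"):
        assert f_big[name] / f_small[name] == pytest.approx(2.0, rel=0.10)


def test_degenerate_regions_rejected():
    with pytest.raises(ValueError):
        region_features(np.zeros((5, 5), bool), STATS, "POS")
    tiny = np.zeros((5, 5), bool)
    tiny[2, 2] = True
    with pytest.raises(ValueError):
        region_features(tiny, STATS, "POS")
    two = np.zeros((12, 12), bool)
    two[1:4, 1:4] = True
    two[8:11, 8:11] = True
    with pytest.raises(ValueError):
        region_features(two, STATS, "POS")


def test_stats_from_known_areas():
    masks, pols = [], []
    for r, pol in [(6, "POS"), (8, "POS"), (10, "POS"), (4, "NEG"), (5, "NEG")]:
        masks.append(_disk_mask(r))
        pols.append(pol)
    stats = compute_nuclei_stats(masks, pols)
    areas = [m.sum() for m in masks]
    assert stats.min_ap == min(areas[:3])
    assert stats.med_ap == sorted(areas[:3])[1]
    assert stats.max_ap == max(areas[:3])
    assert stats.min_an == min(areas[3:])
    # a rasterized disk's radius statistic recovers its radius
    assert stats.med_rp == pytest.approx(8.0, abs=1.0)
    with pytest.raises(ValueError):
        compute_nuclei_stats(masks[:3], pols[:3])  # no NEG regions


def test_single_region_degenerate_statistics():
    stats = compute_nuclei_stats([_disk_mask(7), _disk_mask(5)], ["POS", "NEG"])
    assert stats.min_ap == stats.med_ap == stats.max_ap


def _bars_and_disks(seed=0):
    rng = np.random.default_rng(seed)
    disks, bars = [], []
    for _ in range(8):
        disks.append(_disk_mask(int(rng.integers(5, 10))))
        bar = np.zeros((40, 40), bool)
        r0 = int(rng.integers(5, 15))
        bar[r0 : r0 + 3, 4:36] = True
        bars.append(bar)
    return disks, bars


def test_shape_tree_separates_disks_from_bars():
    disks, bars = _bars_and_disks()
    model = train_shape_tree(disks, bars, STATS, "POS", seed=0)
    assert model.tree.training_accuracy == 1.0
    held_disks, held_bars = _bars_and_disks(seed=99)
    hits = sum(classify_region(m, model) == "NUCLEUS" for m in held_disks)
    hits += sum(classify_region(m, model) == "NOT_NUCLEUS" for m in held_bars)
    assert hits / 16 >= 0.95


def test_shape_tree_tolerates_label_noise():
    disks, bars = _bars_and_disks()
    # same region in both classes: training cannot be perfect, must not crash
    model = train_shape_tree(disks, bars + [disks[0]], STATS, "POS", seed=0)
    assert model.tree.training_accuracy < 1.0


def test_shape_tree_needs_both_classes():
    disks, bars = _bars_and_disks()
    with pytest.raises(ValueError):
        train_shape_tree(disks, bars[:2], STATS, "POS")


def test_shape_model_json_round_trip(tmp_path):
    from ki67.shape import ShapeTreeModel

    disks, bars = _bars_and_disks()
    model = train_shape_tree(disks, bars, STATS, "NEG", seed=1)
    path = tmp_path / "shape.json"
    model.save(path)
    loaded = ShapeTreeModel.load(path)
    assert loaded.polarity == "NEG"
    assert loaded.stats == model.stats
    for m in disks + bars:
        assert classify_region(m, loaded) == classify_region(m, model)


@pytest.mark.parametrize("trial", range(10))
def test_random_shapes_match_moment_oracle(trial):
    rng = np.random.default_rng(trial)
    mask = np.zeros((48, 48), bool)
    if trial % 2 == 0:
        rr, cc = draw_ellipse(
            24, 24, rng.uniform(5, 14), rng.uniform(5, 14),
            rotation=rng.uniform(0, math.pi), shape=(48, 48),
        )
        mask[rr, cc] = True
    else:
        h, w = int(rng.integers(6, 20)), int(rng.integers(6, 20))
        mask[10 : 10 + h, 10 : 10 + w] = True
    feats = dict(zip(FEATURE_NAMES, region_features(mask, STATS, "POS")))
    major, minor, ecc = moments_ellipse_oracle(mask)
    assert feats["area"] == mask.sum()
    rows, cols = np.nonzero(mask)
    assert feats["bbox_area"] == (np.ptp(rows) + 1) * (np.ptp(cols) + 1)
    assert feats["max_axis"] == pytest.approx(major, abs=1e-6)
    assert feats["min_axis"] == pytest.approx(minor, abs=1e-6)
    assert feats["eccentricity"] == pytest.approx(ecc, abs=1e-6)
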