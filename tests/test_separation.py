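"""Masked-STRESS cluster separation: thickness, eligibility, splitting."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import skeletonize

from ki67.stress_separation import (
    EligibilityRules,
    StressSeparationConfig,
    admit_leftovers,
    eligible_nucleus,
    region_thickness_range,
    separate_region,
)

RULES = EligibilityRules(max_area=300.0, min_area_half=40.0, polarity="POS")


def _disk(radius, shape=(40, 40), centre=None):
    mask = np.zeros(shape, bool)
    rr, cc = draw_disk(centre or (shape[0] // 2, shape[1] // 2), radius)
    mask[rr, cc] = True
    return mask


def test_thickness_of_disk_matches_radius():
    t_min, t_med = region_thickness_range(_disk(10.5))  # inscribed radius 10
    assert abs(t_min - 10) <= 1.5
    assert abs(t_med - 10) <= 1.5


def test_thickness_of_thin_bar():
    bar = np.zeros((20, 30), bool)
    bar[8:11, 2:28] = True  # 3 px wide
    t_min, t_med = region_thickness_range(bar)
    assert 1 <= t_min <= 2 and 1 <= t_med <= 2


def test_dumbbell_thickness_against_distance_transform_oracle():
    shape = (40, 60)
    mask = _disk(6, shape, (20, 18)) | _disk(6, shape, (20, 40))
    mask[18:23, 18:40] = mask[18:23, 18:40] | True  # 5-px bridge region
    bridge = np.zeros(shape, bool)
    bridge[19:22, 22:36] = True  # thin it to ~3 px
    mask = _disk(6, shape, (20, 18)) | _disk(6, shape, (20, 40)) | bridge
    t_min, t_med = region_thickness_range(mask)
    # oracle: EDT sampled on the skeleton
    crop = np.pad(mask, 1)
    edt = ndimage.distance_transform_edt(crop)
    d = edt[skeletonize(crop)]
    assert t_min <= 2
    assert abs(t_med - np.median(d)) <= 2.0


def test_tiny_region_thickness_floor():
    speck = np.zeros((10, 10), bool)
    speck[5, 5] = True
    assert region_thickness_range(speck) == (1, 1)


def test_eligibility_strict_area_window():
    disk = _disk(7)  # area ~150
    area = disk.sum()
    assert eligible_nucleus(disk, RULES)
    assert not eligible_nucleus(disk, EligibilityRules(max_area=float(area), min_area_half=10.0))
    assert not eligible_nucleus(disk, EligibilityRules(max_area=1000.0, min_area_half=float(area)))


def test_eligibility_axis_ratio_threshold():
    stretched = np.zeros((40, 60), bool)
    rr, cc = draw_ellipse(20, 30, 7, 14, shape=(40, 60))  # 2:1, ratio 0.5
    stretched[rr, cc] = True
    assert not eligible_nucleus(stretched, EligibilityRules(max_area=1000.0, min_area_half=10.0))


def test_rules_validation():
    with pytest.raises(ValueError):
        EligibilityRules(max_area=10.0, min_area_half=20.0)
    with pytest.raises(ValueError):
        EligibilityRules(max_area=100.0, min_area_half=10.0, axis_ratio_min=1.5)


def test_uniform_eligible_region_detected_whole():
    # degenerate contrast: masked stress leaves the region flat, so the
    # whole region is the only component at every threshold level
    gray = np.full((40, 40), 120.0)
    region = _disk(7)
    dets, residual = separate_region(gray, region, RULES, seed=0)
    assert len(dets) == 1
    assert not residual.any()
    assert dets[0].stage == "stress"
    assert dets[0].area == region.sum()


def test_uniform_ineligible_region_left_alone():
    gray = np.full((40, 40), 120.0)
    region = _disk(11)  # area ~380 > max_area
    dets, residual = separate_region(gray, region, RULES, seed=0)
    assert dets == []
    assert np.array_equal(residual, region)


def test_empty_schedule_is_identity():
    gray = np.full((40, 40), 120.0)
    region = _disk(7)
    dets, residual = separate_region(
        gray, region, RULES, StressSeparationConfig(schedule=()), seed=0
    )
    assert dets == [] and np.array_equal(residual, region)


def test_touching_pair_with_bright_seam_splits():
    shape = (48, 64)
    gray = np.full(shape, 230.0)
    c1, c2 = (24.0, 23.0), (24.0, 38.0)
    m1, m2 = _disk(8, shape, c1), _disk(8, shape, c2)
    region = m1 | m2
    gray[region] = 90.0
    seam = region & (np.abs(np.arange(shape[1])[None, :] - 30.5) <= 1.0)
    gray[seam] = 130.0  # barely brighter interstice at the waist
    rules = EligibilityRules(max_area=280.0, min_area_half=40.0, polarity="POS")
    dets, residual = separate_region(gray, region, rules, seed=1)
    assert len(dets) == 2
    for d, centre in zip(sorted(dets, key=lambda d: d.centroid[1]), (c1, c2)):
        assert abs(d.centroid[0] - centre[0]) <= 2.0
        assert abs(d.centroid[1] - centre[1]) <= 2.0
    for d in dets:
        assert region[d.rows, d.cols].all()


def test_admit_leftovers_one_detection_per_component():
    residual = np.zeros((30, 30), bool)
    residual[2:5, 2:5] = True
    residual[20:24, 20:25] = True
    dets = admit_leftovers(residual, "NEG")
    assert len(dets) == 2
    assert {d.stage for d in dets} == {"leftover"}
    assert all(d.polarity == "NEG" for d in dets)
    assert admit_leftovers(np.zeros((5, 5), bool), "POS") == []


def test_admit_leftovers_min_area_filter():
    residual = np.zeros((30, 30), bool)
    residual[2:4, 2:4] = True  # 4 px speck
    residual[10:20, 10:20] = True  # 100 px block
    dets = admit_leftovers(residual, "POS", min_area=50)
    assert len(dets) == 1 and dets[0].area == 100
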