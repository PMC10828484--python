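"""Nucleus/fibre segmentation, QC rules, and background statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from myosen import (build_nuclear_mask, classify_myonuclei, erode_nuclear_mask,
                    extract_fibres, fibres_from_polygons, sarcomeric_background)
from myosen.matching import match_points
from myosen.pipeline import fibres_from_truth
from myosen.segmentation import QC_TOUCHING


def _disk_image(centers, radius=6, level=3000.0, shape=(200, 200), noise=0.0,
                seed=0):
    img = np.full(shape, 100.0)
    for cy, cx in centers:
        rr, cc = draw_disk((cy, cx), radius, shape=shape)
        img[rr, cc] = level
    img = ndi.gaussian_filter(img, 1.0)
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, shape)
    return img


def test_two_disjoint_disks_give_two_clean_records():
    img = _disk_image([(60, 60), (140, 140)])
    recs = build_nuclear_mask(img)
    assert len(recs) == 2
    assert not any(r.qc_excluded for r in recs)


def test_overlapping_disks_flagged_touching():
    img = _disk_image([(100, 96), (100, 107)], radius=6)
    recs = build_nuclear_mask(img)
    assert len(recs) == 1
    assert recs[0].qc_reason == QC_TOUCHING and recs[0].qc_excluded


def test_blurred_nucleus_flagged():
    img = _disk_image([(50, 50), (50, 150), (150, 50)], radius=6)
    # one extra nucleus rendered heavily defocused
    soft = np.full((200, 200), 0.0)
    rr, cc = draw_disk((150, 150), 6, shape=(200, 200))
    soft[rr, cc] = 2900.0
    img = img + ndi.gaussian_filter(soft, 4.0)
    recs = build_nuclear_mask(img)
    blurred = [r for r in recs if r.qc_reason == "blurred"]
    assert len(blurred) == 1
    assert abs(blurred[0].centroid[0] - 150) < 6


def test_constant_image_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        assert build_nuclear_mask(np.full((50, 50), 7.0)) == []


def test_planted_field_recovered_with_high_sensitivity():
    """150 well-separated nuclei at SNR ~100: nearly all detected, matched
    one-to-one to the plants within 3 px."""
    rng = np.random.default_rng(4)
    centers = []
    for gy in range(10):
        for gx in range(15):
            centers.append((30 + 40 * gy + rng.uniform(-6, 6),
                            20 + 40 * gx + rng.uniform(-6, 6)))
    img = _disk_image(centers, radius=5, shape=(440, 620), noise=30.0)
    recs = build_nuclear_mask(img)
    good = [r for r in recs if not r.qc_excluded]
    assert len(good) >= 148
    det = np.array([r.centroid for r in good])
    planted = np.array([(cx, cy) for cy, cx in centers])
    pairs = match_points(det, planted, 3.0)
    assert len(pairs) >= 148


def test_raising_blur_threshold_never_unexcludes_touching():
    img = _disk_image([(100, 96), (100, 107), (40, 40), (160, 160), (40, 160)])
    for thr in (0.1, 0.4, 0.9):
        recs = build_nuclear_mask(img, blur_rel_threshold=thr)
        touch = [r for r in recs if r.qc_reason == QC_TOUCHING]
        assert len(touch) == 1 and touch[0].qc_excluded


# --------------------------------------------------------------------------
# erosion / ring
# --------------------------------------------------------------------------

def test_disk_ring_partition_identity():
    img = _disk_image([(100, 100)], radius=10)
    recs = build_nuclear_mask(img)
    erode_nuclear_mask(recs, 2)
    r = recs[0]
    assert not (r.eroded_mask & r.ring_mask).any()
    assert np.array_equal(r.eroded_mask | r.ring_mask, r.mask)
    assert r.ring_mask.sum() > 0 and r.eroded_mask.sum() > 0


def test_zero_depth_erosion_rejected():
    with pytest.raises(ValueError):
        erode_nuclear_mask([], 0)


def test_thin_nucleus_fully_eroded_keeps_full_ring():
    img = _disk_image([(100, 100)], radius=4)
    recs = build_nuclear_mask(img, min_area_px=10)
    erode_nuclear_mask(recs, 6)
    r = recs[0]
    assert r.thin_nucleus
    assert np.array_equal(r.ring_mask, r.mask)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(a=st.floats(4, 12), b=st.floats(3, 10), angle=st.floats(0, 3.1),
       depth=st.integers(1, 3))
def test_erosion_partition_property_on_ellipses(a, b, angle, depth):
    shape = (40, 40)
    rr, cc = draw_ellipse(20, 20, min(a, b), max(a, b), shape=shape,
                          rotation=angle)
    img = np.full(shape, 50.0)
    img[rr, cc] = 3000.0
    recs = build_nuclear_mask(img, min_area_px=5)
    erode_nuclear_mask(recs, depth)
    for r in recs:
        assert not (r.eroded_mask & r.ring_mask).any()
        assert np.array_equal(r.eroded_mask | r.ring_mask, r.mask)


# --------------------------------------------------------------------------
# myonuclear classification, fibre extraction
# --------------------------------------------------------------------------

def test_myonuclear_rule_on_simple_geometry():
    square = np.array([[10., 10.], [90., 10.], [90., 90.], [10., 90.], [10., 10.]])
    fibres = fibres_from_polygons([square])

    class P:
        def __init__(self, x, y):
            self.centroid = (x, y)
            self.nucleus_id = 0
            self.is_myonuclear = False
            self.fibre_id = -1
    inside, outside, on_edge = P(50, 50), P(5, 5), P(10, 50)
    classify_myonuclei([inside, outside, on_edge], fibres)
    assert inside.is_myonuclear and inside.fibre_id == 0
    assert not outside.is_myonuclear
    assert not on_edge.is_myonuclear  # strict interior rule


def test_myonuclear_classes_agree_with_plants(taf_noiseless):
    img, gt = taf_noiseless
    from myosen.synthetic import NUC_INTERSTITIAL
    nuclei = build_nuclear_mask(img.channel("DAPI"))
    fibres = fibres_from_truth(gt)
    classify_myonuclei(nuclei, fibres)
    det = np.array([n.centroid for n in nuclei])
    planted = np.array([n.center for n in gt.nuclei])
    pairs = match_points(det, planted, 3.0)
    assert len(pairs) > 0.9 * len(gt.nuclei)
    agree = sum(nuclei[i].is_myonuclear == (gt.nuclei[j].cls != NUC_INTERSTITIAL)
                for i, j in pairs)
    assert agree / len(pairs) >= 0.98


def test_watershed_fibre_extraction_recovers_tessellation(taf_noiseless):
    img, gt = taf_noiseless
    fibres = extract_fibres(img.channel("WGA"), pixel_size_um=1.0)
    n_det = sum(not f.edge for f in fibres)
    n_true = len(gt.analysed_fibre_ids())
    assert abs(n_det - n_true) <= max(0.02 * n_true, 1)
    # per-fibre area recovery on matched fibres
    from shapely.geometry import Polygon
    det_nonedge = [f for f in fibres if not f.edge]
    tc = np.array([Polygon(gt.fibre_polygons[i]).centroid.coords[0]
                   for i in gt.analysed_fibre_ids()])
    dc = np.array([Polygon(f.polygon).centroid.coords[0] for f in det_nonedge])
    pairs = match_points(dc, tc, 10.0)
    assert len(pairs) >= 0.95 * n_true
    errs = []
    for di, ti in pairs:
        truth_area = Polygon(gt.fibre_polygons[gt.analysed_fibre_ids()[ti]]).area
        errs.append(abs(det_nonedge[di].area_px - truth_area) / truth_area)
    assert np.median(errs) <= 0.05


def test_single_fibre_filling_field_is_edge_flagged():
    img = np.full((120, 120), 50.0)
    img[:3, :] = img[-3:, :] = img[:, :3] = img[:, -3:] = 3000.0
    fibres = extract_fibres(img)
    assert len(fibres) == 1 and fibres[0].edge


# --------------------------------------------------------------------------
# sarcomeric background
# --------------------------------------------------------------------------

def test_background_constant_and_checkerboard():
    region = np.ones((60, 60), dtype=bool)
    bg = sarcomeric_background(np.full((60, 60), 100.0), [], region)
    assert bg.mean == 100.0 and bg.sd == 0.0
    checker = np.indices((60, 60)).sum(axis=0) % 2
    img = np.where(checker == 0, 90.0, 110.0)
    bg = sarcomeric_background(img, [], region)
    assert bg.mean == pytest.approx(100.0) and bg.sd == pytest.approx(10.0)


def test_background_recovers_planted_gaussian():
    rng = np.random.default_rng(9)
    img = rng.normal(100.0, 15.0, size=(120, 120))
    bg = sarcomeric_background(img, [], np.ones((120, 120), dtype=bool))
    assert abs(bg.mean - 100.0) <= 1.0
    assert abs(bg.sd - 15.0) <= 1.0
    assert bg.pixel_count == 120 * 120


def test_background_requires_enough_pixels():
    region = np.zeros((60, 60), dtype=bool)
    region[:5, :5] = True
    with pytest.raises(ValueError):
        sarcomeric_background(np.ones((60, 60)), [], region)


def test_background_excludes_dilated_nuclei(hmgb1_section):
    img, gt = hmgb1_section
    from myosen.pipeline import nuclei_from_truth
    nuclei = nuclei_from_truth(gt)
    bg = sarcomeric_background(img.channel("HMGB1"), nuclei, gt.fibre_labels)
    # positives are planted 6 SD above background, so the background stats
    # must sit near the sarcomeric texture, not the nuclear levels
    assert abs(bg.mean - 500.0) < 25.0
    assert bg.sd < 60.0
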