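"""Marker quantification: positivity rules, focus detection, TAF matching,
p16 scoring and the per-sample summary."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from myosen import (FociSet, SampleSummary, assign_foci, count_taf,
                    detect_foci, hmgb1_positive, laminb1_positive, pct_taf,
                    p16_scores, summarise_sample)
from myosen.pipeline import (fibres_from_truth, foci_from_truth,
                             nuclei_from_truth, summarise_from_truth)
from myosen.segmentation import (NucleusRecord, SarcomericBackground,
                                 erode_nuclear_mask, fibres_from_polygons,
                                 sarcomeric_background)
from myosen.senescence import classify_hmgb1, classify_laminb1, pct_positive


def _bg(mean, sd):
    return SarcomericBackground(mean=mean, sd=sd, channel="m", pixel_count=1000)


# --------------------------------------------------------------------------
# intensity rules
# --------------------------------------------------------------------------

@pytest.mark.parametrize("nucleus_mean,mean,sd,expected", [
    (150.0, 100.0, 20.0, True),     # above mean + 2 SD = 140
    (140.0, 100.0, 20.0, False),    # exactly at the threshold: strict >
    (139.9, 100.0, 20.0, False),
    (100.1, 100.0, 0.0, True),      # zero-SD background
])
def test_hmgb1_positivity_rule(nucleus_mean, mean, sd, expected):
    assert hmgb1_positive(nucleus_mean, _bg(mean, sd)) is expected


def test_laminb1_ring_density_is_a_plain_sum():
    mask = np.zeros((12, 12), dtype=bool)
    mask[2:10, 2:10] = True
    rec = NucleusRecord(0, (0, 0, 12, 12), mask, (6, 6), int(mask.sum()))
    erode_nuclear_mask([rec], 2)
    ring_area = int(rec.ring_mask.sum())
    from myosen.senescence import laminb1_ring_density
    dens = laminb1_ring_density(np.full((12, 12), 50.0), [rec])[0]
    assert dens == 50.0 * ring_area
    assert laminb1_ring_density(np.zeros((12, 12)), [rec])[0] == 0.0
    assert not laminb1_positive(0.0, ring_area, _bg(10, 1))


def test_hmgb1_classification_is_exact_at_6sd(hmgb1_section):
    img, gt = hmgb1_section
    nuclei = nuclei_from_truth(gt)
    bg = sarcomeric_background(img.channel("HMGB1"), nuclei, gt.fibre_labels)
    classify_hmgb1(nuclei, img.channel("HMGB1"), bg)
    for n in nuclei:
        if n.is_myonuclear and not n.qc_excluded:
            truth = gt.nucleus_marker_class[n.nucleus_id] == "positive"
            assert n.hmgb1_positive is truth
    assert pct_positive(nuclei, "hmgb1_positive") == pytest.approx(
        gt.per_sample_truth.pct_hmgb1_pos)


def test_laminb1_classification_is_exact_at_6sd(laminb1_section):
    img, gt = laminb1_section
    nuclei = nuclei_from_truth(gt)
    bg = sarcomeric_background(img.channel("LaminB1"), nuclei, gt.fibre_labels)
    erode_nuclear_mask(nuclei, 2)
    classify_laminb1(nuclei, img.channel("LaminB1"), bg)
    for n in nuclei:
        if n.is_myonuclear and not n.qc_excluded:
            truth = gt.nucleus_marker_class[n.nucleus_id] == "positive"
            assert n.laminb1_positive is truth


# --------------------------------------------------------------------------
# focus detection
# --------------------------------------------------------------------------

def _gauss_spot(img, x, y, amp=500.0, sigma=1.5):
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))


def test_single_noiseless_blob_detected_subpixel():
    img = np.full((64, 64), 100.0)
    _gauss_spot(img, 30.3, 41.7)
    fs = detect_foci(img, scale_px=1.5)
    assert len(fs) == 1
    assert np.hypot(fs.points[0, 0] - 30.3, fs.points[0, 1] - 41.7) < 0.5


def test_two_blobs_six_sigma_apart_resolved():
    img = np.full((64, 64), 100.0)
    _gauss_spot(img, 20, 32, sigma=1.5)
    _gauss_spot(img, 29, 32, sigma=1.5)
    fs = detect_foci(img, scale_px=1.5)
    assert len(fs) == 2


def test_detection_rejects_nonpositive_scale():
    with pytest.raises(ValueError):
        detect_foci(np.zeros((8, 8)), 0.0)


def test_flat_image_yields_no_foci():
    assert len(detect_foci(np.full((32, 32), 9.0), 1.5)) == 0


# --------------------------------------------------------------------------
# TAF colocalisation
# --------------------------------------------------------------------------

def _one_nucleus():
    mask = np.ones((20, 20), dtype=bool)
    rec = NucleusRecord(0, (0, 0, 20, 20), mask, (10, 10), 400)
    rec.is_myonuclear = True
    return [rec]


def _fs(ch, pts):
    pts = np.asarray(pts, dtype=float)
    return FociSet(ch, pts, np.ones(len(pts)),
                   nucleus_assignment=np.zeros(len(pts), dtype=np.int64))


def test_coincident_pair_is_one_taf():
    res = count_taf(_fs("telomere", [[5, 5]]), _fs("gH2AX", [[5, 5]]),
                    _one_nucleus(), coloc_radius_px=1.5)
    assert res.per_nucleus[0] == 1
    assert res.taf_pct_of_gh2ax == 100.0


def test_separated_pair_is_no_taf():
    res = count_taf(_fs("telomere", [[5, 5]]), _fs("gH2AX", [[8, 5]]),
                    _one_nucleus(), coloc_radius_px=1.5)
    assert res.per_nucleus[0] == 0
    assert res.taf_pct_of_gh2ax == 0.0


def test_matching_is_one_to_one_and_symmetric():
    tel = [[5, 5], [5.8, 5], [12, 12]]
    gh = [[5.4, 5], [12.4, 12], [17, 17]]
    nuclei = _one_nucleus()
    a = count_taf(_fs("telomere", tel), _fs("gH2AX", gh), nuclei, 1.5)
    b = count_taf(_fs("telomere", gh), _fs("gH2AX", tel), nuclei, 1.5)
    assert a.per_nucleus[0] == b.per_nucleus[0] == 2
    assert {(t, g) for t, g in a.pairs} == {(g, t) for t, g in b.pairs}


def test_taf_matching_recovers_planted_partners(taf_noiseless):
    _, gt = taf_noiseless
    nuclei = nuclei_from_truth(gt)
    res = count_taf(foci_from_truth(gt, "telomere"), foci_from_truth(gt, "gH2AX"),
                    nuclei, coloc_radius_px=1.5)
    truth = gt.taf_counts_true()
    assert {k: v for k, v in res.per_nucleus.items()} == truth


@pytest.mark.parametrize("counts,k,expected", [
    ([0, 1, 2, 3, 2], 2, 60.0),
    ([0, 1, 2, 3, 2], 3, 20.0),
    ([0, 0, 0, 0], 1, 0.0),
    ([0, 0, 0, 0], 3, 0.0),
])
def test_pct_taf_direct_counts(counts, k, expected):
    res = pct_taf(counts, k)
    assert res.value == expected
    assert res.low_n  # denominator below the 100-nucleus quota


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.integers(0, 6), min_size=1, max_size=120))
def test_three_taf_nuclei_are_subset_of_two_taf(counts):
    assert float(pct_taf(counts, 3)) <= float(pct_taf(counts, 2))


# --------------------------------------------------------------------------
# p16
# --------------------------------------------------------------------------

def _square_fibre_with_nucleus():
    square = np.array([[0., 0.], [40., 0.], [40., 40.], [0., 40.], [0., 0.]])
    fibres = fibres_from_polygons([square])
    mask = np.zeros((8, 8), dtype=bool)
    mask[1:7, 1:7] = True
    rec = NucleusRecord(0, (16, 16, 24, 24), mask, (20, 20), int(mask.sum()))
    rec.is_myonuclear, rec.fibre_id = True, 0
    return fibres, [rec]


def test_p16_two_nuclear_foci():
    fibres, nuclei = _square_fibre_with_nucleus()
    fs = FociSet("p16", [[20, 20], [21, 20]], [1, 1],
                 nucleus_assignment=np.array([0, 0]),
                 fibre_assignment=np.array([0, 0]))
    assert p16_scores(fs, nuclei, fibres) == (100.0, 0.0, 100.0)


def test_p16_two_cytoplasmic_foci():
    fibres, nuclei = _square_fibre_with_nucleus()
    fs = FociSet("p16", [[5, 5], [30, 8]], [1, 1],
                 nucleus_assignment=np.array([-1, -1]),
                 fibre_assignment=np.array([0, 0]))
    assert p16_scores(fs, nuclei, fibres) == (0.0, 100.0, 100.0)


def test_p16_focus_outside_all_fibres_is_excluded():
    fibres, nuclei = _square_fibre_with_nucleus()
    fs = FociSet("p16", [[20, 20], [200, 200]], [1, 1],
                 nucleus_assignment=np.array([0, -1]),
                 fibre_assignment=np.array([0, -1]))
    assert p16_scores(fs, nuclei, fibres) == (0.0, 0.0, 0.0)


def test_p16_truth_assignment_matches_plants(p16_section):
    img, gt = p16_section
    nuclei = nuclei_from_truth(gt)
    fibres = fibres_from_truth(gt)
    fs = foci_from_truth(gt, "p16")
    pn, pf, pa = p16_scores(fs, nuclei, fibres)
    t = gt.per_sample_truth
    assert (pn, pf, pa) == (t.pct_p16_nuclei_2plus, t.pct_p16_fibre_2plus,
                            t.pct_p16_any_2plus)


def test_p16_colour_deconvolution_highlights_planted_foci(p16_section):
    img, gt = p16_section
    from myosen.senescence import p16_chromogen_map
    chrom = p16_chromogen_map(img.pixels)
    foci = gt.foci_true["p16"]
    at_foci = np.median([chrom[int(round(f.y)), int(round(f.x))] for f in foci])
    assert at_foci > 5 * np.median(chrom)


# --------------------------------------------------------------------------
# summary
# --------------------------------------------------------------------------

def test_noiseless_truth_bypass_recovers_every_variable(taf_noiseless):
    _, gt = taf_noiseless
    summ = summarise_from_truth(gt)
    truth = gt.per_sample_truth
    for name in truth.filled_fields():
        assert getattr(summ, name) == getattr(truth, name), name


def test_summary_missing_inputs_stay_missing():
    out = summarise_sample(None, None)
    assert out.pct_taf_2plus is None and out.fibrotic_area_pct is None
    assert "missing:nuclei" in out.flags and "missing:morphology" in out.flags


def test_summary_rejects_inconsistent_taf_percentages():
    with pytest.raises(ValueError):
        SampleSummary(pct_taf_2plus=10.0, pct_taf_3plus=20.0)
    with pytest.raises(ValueError):
        SampleSummary(pct_hmgb1_pos=120.0)
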