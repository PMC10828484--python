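"""End-to-end quantification runs, including ground-truth bypass.

The bypass path mirrors the study's manual steps (fibre outlining, focus
counting) by building nucleus / fibre / foci records directly from a
synthetic section's ground truth and then running the quantification
operations on them.  With detection bypassed and noise off, every
per-sample variable must recover its planted value exactly; the
image-based paths (thresholding, blob detection, watershed) are scored
separately against the same truth.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from . import morphology, senescence
from .segmentation import (FibreRecord, NucleusRecord, fibres_from_polygons,
                           sarcomeric_background)
from .senescence import FociSet, count_taf, summarise_sample
from .summary import SampleSummary
from .synthetic import NUC_CENTRAL, NUC_PERIPHERAL, GroundTruth


def nuclei_from_truth(gt: GroundTruth) -> list:
    """NucleusRecords from planted ellipses.

    Myonuclei inside edge-clipped fibres are flagged ``edge``-excluded:
    partial fibres are not analysed, so neither are their nuclei.
    """
    shape = gt.fibre_labels.shape
    good = set(gt.analysed_fibre_ids())
    records = []
    for nid, nuc in enumerate(gt.nuclei):
        rr, cc = draw_ellipse(nuc.center[1], nuc.center[0],
                              nuc.axes[1], nuc.axes[0],
                              shape=shape, rotation=-nuc.angle)
        if rr.size == 0:
            continue
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        mask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        mask[rr - r0, cc - c0] = True
        rec = NucleusRecord(nucleus_id=nid, bbox=(r0, c0, r1, c1), mask=mask,
                            centroid=(nuc.center[0], nuc.center[1]),
                            area_px=int(mask.sum()))
        rec.is_myonuclear = nuc.cls in (NUC_PERIPHERAL, NUC_CENTRAL)
        rec.fibre_id = nuc.fibre_id
        if rec.is_myonuclear and nuc.fibre_id not in good:
            rec.qc_excluded, rec.qc_reason = True, "edge"
        records.append(rec)
    return records


def fibres_from_truth(gt: GroundTruth, pixel_size_um: float | None = None) -> list:
    fibres = fibres_from_polygons(gt.fibre_polygons, gt.fibre_edge,
                                  pixel_size_um or gt.spec.pixel_size_um)
    for f, central in zip(fibres, gt.fibre_central):
        f.central_nucleus = central
    return fibres


def foci_from_truth(gt: GroundTruth, channel: str) -> FociSet:
    foci = gt.foci_true[channel]
    with_z = any(f.z is not None for f in foci)
    pts = np.array([[f.x, f.y, f.z] if with_z else [f.x, f.y] for f in foci],
                   dtype=float).reshape(len(foci), 3 if with_z else 2)
    fs = FociSet(channel, pts, np.ones(len(foci)),
                 nucleus_assignment=np.array([f.nucleus_id for f in foci],
                                             dtype=np.int64),
                 fibre_assignment=np.array([f.fibre_id for f in foci],
                                           dtype=np.int64))
    return fs


def summarise_from_truth(gt: GroundTruth, image=None,
                         coloc_radius_px: float = 1.5) -> SampleSummary:
    """Run the quantification operations on truth-derived records.

    Foci, outlines and nucleus masks come from the plants (detection
    bypassed); the intensity classifiers (HMGB1 / Lamin B1) run on the
    image when one is provided.  The fibrotic fraction is measured by
    pixel counting on the planted mask.
    """
    spec = gt.spec
    nuclei = nuclei_from_truth(gt)
    fibres = fibres_from_truth(gt)
    panel = spec.marker_panel

    taf = None
    foci_sets = {}
    if panel == "TAF":
        taf = count_taf(foci_from_truth(gt, "telomere"),
                        foci_from_truth(gt, "gH2AX"),
                        nuclei, coloc_radius_px=coloc_radius_px)
    elif panel == "p16":
        foci_sets["p16"] = foci_from_truth(gt, "p16")
    elif panel in ("HMGB1", "LaminB1") and image is not None:
        marker = image.channel(panel)
        bg = sarcomeric_background(marker, nuclei, gt.fibre_labels,
                                   channel_name=panel)
        if panel == "HMGB1":
            senescence.classify_hmgb1(nuclei, marker, bg)
        else:
            from .segmentation import erode_nuclear_mask
            erode_nuclear_mask(nuclei, depth_px=2)
            senescence.classify_laminb1(nuclei, marker, bg)

    analysed = [f for f in fibres if not f.edge]
    scale = spec.pixel_size_um
    morph = morphology.MorphologySummary(
        min_feret_mean=float(np.mean([morphology.min_feret(f.polygon, scale)
                                      for f in analysed])),
        csa_mean_um2=float(np.mean([f.area_px * scale * scale for f in analysed])),
        fibre_number_per_mm2=morphology.fibre_density(
            fibres, gt.fibre_labels.size, scale),
        cnf_pct=morphology.cnf_pct(fibres, nuclei),
        fibrotic_area_pct=100.0 * float(gt.fibrotic_mask.mean()),
        feret_units="um",
        n_fibres_analysed=len(analysed),
    )
    return summarise_sample(nuclei, fibres, foci_sets=foci_sets, taf=taf,
                            morphology=morph, panel=panel)
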