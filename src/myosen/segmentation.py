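"""Nucleus and fibre segmentation with QC exclusions.

Nuclei are segmented from the DAPI channel by global (Otsu) thresholding
and connected components.  Mirroring the analysis protocol, touching or
blurred nuclei are flagged and excluded from every percentage denominator
rather than split.  Myonuclei are separated from interstitial and
satellite-cell nuclei with the WGA-delineated fibre outlines: a nucleus is
myonuclear iff its centroid lies strictly inside a fibre polygon (eroded
by the WGA boundary half-width).  Fibre outlines themselves come either
from ground truth (the stand-in for manual outlining) or from watershed
segmentation of the boundary channel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from shapely.geometry.polygon import orient
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .morphology import min_feret

log = logging.getLogger(__name__)

QC_NONE = "none"
QC_TOUCHING = "touching"
QC_BLURRED = "blurred"
QC_EDGE = "edge"


@dataclass
class NucleusRecord:
    """One segmented nucleus."""

    nucleus_id: int
    bbox: tuple                      # (min_row, min_col, max_row, max_col)
    mask: np.ndarray                 # bool, within bbox
    centroid: tuple                  # (x, y) px, image coordinates
    area_px: int
    is_myonuclear: bool = False
    fibre_id: int = -1
    qc_excluded: bool = False
    qc_reason: str = QC_NONE
    thin_nucleus: bool = False
    mean_intensity: dict = field(default_factory=dict)
    ring_integrated_density: float | None = None
    laminb1_positive: bool | None = None
    hmgb1_positive: bool | None = None
    foci_counts: dict = field(default_factory=dict)
    taf_count: int = 0
    eroded_mask: np.ndarray | None = None
    ring_mask: np.ndarray | None = None

    def full_mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass
class FibreRecord:
    """One myofibre outline with morphometry."""

    fibre_id: int
    polygon: np.ndarray              # closed CCW (n, 2) array, (x, y) px
    area_px: float
    csa_um2: float | None = None
    min_feret_um: float | None = None
    min_feret_au: float | None = None
    nucleus_ids: list = field(default_factory=list)
    central_nucleus: bool = False
    p16_foci_nuclear: int = 0
    p16_foci_extranuclear: int = 0
    edge: bool = False

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class SarcomericBackground:
    """Per-image sarcomeric (fibre-interior, extra-nuclear) intensity."""

    mean: float
    sd: float                        # population SD (complete pixel set)
    channel: str
    pixel_count: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


# --------------------------------------------------------------------------
# nuclei
# --------------------------------------------------------------------------

def build_nuclear_mask(dapi: np.ndarray, min_area_px: int = 30,
                       solidity_threshold: float = 0.9,
                       peak_min_distance: int = 5,
                       blur_rel_threshold: float = 0.4) -> list:
    """Segment nuclei from a DAPI channel.

    Connected components above the Otsu threshold; components below
    ``min_area_px`` are dropped.  QC flags (components stay in the list
    with ``qc_excluded=True``):

    * ``touching`` — solidity below ``solidity_threshold`` or at least two
      regional intensity maxima more than ``peak_min_distance`` px apart;
    * ``blurred`` — Laplacian-variance sharpness score over the padded
      bounding box (normalised by mean intensity) below
      ``blur_rel_threshold`` times the image's median component score;
    * ``edge`` — touching the image border.
    """
    img = np.asarray(dapi, dtype=float)
    if img.size == 0 or np.ptp(img) == 0:
        warnings.warn("empty or constant DAPI channel; no nuclei segmented")
        return []
    thr = threshold_otsu(img)
    lab = label(img > thr)
    h, w = img.shape
    records, scores = [], []
    for rp in regionprops(lab, intensity_image=img):
        if rp.area < min_area_px:
            continue
        r0, c0, r1, c1 = rp.bbox
        mask = rp.image
        sub = rp.image_intensity
        touching = rp.solidity < solidity_threshold
        if not touching:
            smooth = ndi.gaussian_filter(np.where(mask, sub, 0.0), 1.5)
            peaks = peak_local_max(smooth, min_distance=peak_min_distance,
                                   threshold_rel=0.5, exclude_border=False,
                                   labels=mask.astype(int))
            touching = len(peaks) >= 2
        # sharpness: Laplacian variance over the padded bounding box (the
        # pad captures the nucleus rim, where defocus shows most)
        pad = 4
        box = img[max(r0 - pad, 0):min(r1 + pad, h),
                  max(c0 - pad, 0):min(c1 + pad, w)]
        mean_int = sub[mask].mean()
        score = ndi.laplace(box).var() / max(mean_int, 1e-9)
        edge = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        cy, cx = rp.centroid
        rec = NucleusRecord(
            nucleus_id=len(records), bbox=rp.bbox, mask=mask,
            centroid=(cx, cy), area_px=int(rp.area))
        rec.mean_intensity["DAPI"] = float(mean_int)
        if touching:
            rec.qc_excluded, rec.qc_reason = True, QC_TOUCHING
        elif edge:
            rec.qc_excluded, rec.qc_reason = True, QC_EDGE
        records.append(rec)
        scores.append(score)
    if records:
        med = float(np.median(scores))
        for rec, score in zip(records, scores):
            if score < blur_rel_threshold * med and rec.qc_reason == QC_NONE:
                rec.qc_excluded, rec.qc_reason = True, QC_BLURRED
    return records


def measure_channel(nuclei: list, channel: np.ndarray, name: str) -> list:
    """Fill ``mean_intensity[name]`` for every nucleus from a raster."""
    img = np.asarray(channel, dtype=float)
    for rec in nuclei:
        r0, c0, r1, c1 = rec.bbox
        rec.mean_intensity[name] = float(img[r0:r1, c0:c1][rec.mask].mean())
    return nuclei


def erode_nuclear_mask(nuclei: list, depth_px: int) -> list:
    """Erode each nuclear mask by ``depth_px``; store eroded and ring masks.

    The ring (original minus eroded) and the eroded mask partition the
    original mask.  A nucleus whose inradius is at most ``depth_px`` ends
    up fully eroded; its ring is the full mask and it is flagged
    ``thin_nucleus``.
    """
    if depth_px < 1:
        raise ValueError("depth_px must be >= 1")
    selem = disk(depth_px)
    for rec in nuclei:
        eroded = ndi.binary_erosion(rec.mask, structure=selem)
        if not eroded.any():
            rec.thin_nucleus = True
            rec.eroded_mask = np.zeros_like(rec.mask)
            rec.ring_mask = rec.mask.copy()
        else:
            rec.eroded_mask = eroded
            rec.ring_mask = rec.mask & ~eroded
    return nuclei


def ring_mask(nuclei: list, depth_px: int) -> list:
    """Peripheral (ring) masks for each nucleus; see erode_nuclear_mask."""
    erode_nuclear_mask(nuclei, depth_px)
    return [rec.ring_mask for rec in nuclei]


def classify_myonuclei(nuclei: list, fibres: list,
                       boundary_halfwidth_px: float = 0.0) -> list:
    """Set ``is_myonuclear`` and the containing fibre for each nucleus.

    A nucleus is myonuclear iff its centroid lies strictly inside a fibre
    polygon eroded by the WGA boundary half-width (a centroid on the
    polygon edge or in the boundary band is not myonuclear).  Fibre
    ``nucleus_ids`` are updated symmetrically.
    """
    polys = []
    for f in fibres:
        p = f.shapely() if isinstance(f, FibreRecord) else Polygon(f)
        if boundary_halfwidth_px > 0:
            p = p.buffer(-boundary_halfwidth_px)
        polys.append(p)
    for f in fibres:
        if isinstance(f, FibreRecord):
            f.nucleus_ids = []
    for rec in nuclei:
        pt = Point(rec.centroid[0], rec.centroid[1])
        rec.is_myonuclear, rec.fibre_id = False, -1
        for fi, p in enumerate(polys):
            if not p.is_empty and p.contains(pt):
                rec.is_myonuclear = True
                fid = fibres[fi].fibre_id if isinstance(fibres[fi], FibreRecord) else fi
                rec.fibre_id = fid
                if isinstance(fibres[fi], FibreRecord):
                    fibres[fi].nucleus_ids.append(rec.nucleus_id)
                break
    return nuclei


# --------------------------------------------------------------------------
# fibres
# --------------------------------------------------------------------------

def extract_fibres(boundary: np.ndarray, pixel_size_um: float | None = None,
                   boundary_bright: bool = True, min_area_px: int = 150,
                   simplify_tol: float = 0.5, edge_margin_px: int = 3) -> list:
    """Segment fibre regions from a boundary channel (bright WGA borders,
    or pass ``boundary_bright=False`` for dark borders).

    Watershed on the inverted-boundary distance map, seeded at the
    regional maximum of each interior component; regions are vectorised to
    simplified polygons and border-touching regions flagged ``edge``.
    """
    img = np.asarray(boundary, dtype=float)
    if img.size == 0 or np.ptp(img) == 0:
        warnings.warn("constant boundary channel; no fibres found")
        return []
    thr = threshold_otsu(img)
    interior = img < thr if boundary_bright else img > thr
    if not interior.any():
        warnings.warn("no interior regions found")
        return []
    dist = ndi.distance_transform_edt(interior)
    comp = label(interior)
    seeds = peak_local_max(dist, labels=comp, num_peaks_per_label=1,
                           exclude_border=False)
    markers = np.zeros_like(comp)
    for i, (r, c) in enumerate(seeds, start=1):
        markers[r, c] = i
    regions = watershed(-dist, markers, mask=interior)

    h, w = img.shape
    fibres = []
    for rp in regionprops(regions):
        if rp.area < min_area_px:
            continue
        r0, c0, r1, c1 = rp.bbox
        # the boundary band is clipped off at the field border, so regions of
        # edge-clipped fibres stop a band half-width short of it
        m = edge_margin_px
        edge = r0 <= m or c0 <= m or r1 >= h - m or c1 >= w - m
        padded = np.pad(rp.image, 1)
        contours = find_contours(padded.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        # (row, col) in padded bbox frame -> (x, y) image frame
        xy = np.stack([contour[:, 1] - 1 + c0, contour[:, 0] - 1 + r0], axis=1)
        poly = Polygon(xy).simplify(simplify_tol)
        if poly.is_empty or poly.geom_type != "Polygon" or len(poly.exterior.coords) < 4:
            continue
        poly = orient(poly.buffer(0), 1.0)
        verts = np.asarray(poly.exterior.coords)
        rec = FibreRecord(fibre_id=len(fibres), polygon=verts,
                          area_px=float(rp.area), edge=edge)
        try:
            feret = min_feret(verts)
        except ValueError:
            continue
        if pixel_size_um is not None:
            rec.csa_um2 = rp.area * pixel_size_um ** 2
            rec.min_feret_um = feret * pixel_size_um
        rec.min_feret_au = feret
        fibres.append(rec)
    return fibres


def fibres_from_polygons(polygons, edge_flags=None,
                         pixel_size_um: float | None = None) -> list:
    """Build FibreRecords directly from known outlines (the manual-outline
    stand-in used when quantification is scored against ground truth)."""
    fibres = []
    for i, verts in enumerate(polygons):
        verts = np.asarray(verts, dtype=float)
        poly = Polygon(verts)
        rec = FibreRecord(fibre_id=i, polygon=verts, area_px=float(poly.area),
                          edge=bool(edge_flags[i]) if edge_flags is not None else False)
        feret = min_feret(verts)
        rec.min_feret_au = feret
        if pixel_size_um is not None:
            rec.csa_um2 = poly.area * pixel_size_um ** 2
            rec.min_feret_um = feret * pixel_size_um
        fibres.append(rec)
    return fibres


def rasterise_fibres(fibres: list, shape) -> np.ndarray:
    """Label raster of fibre polygons (ids are fibre_id + 1)."""
    labels = np.zeros(shape, dtype=np.int32)
    for f in fibres:
        rr, cc = draw_polygon(f.polygon[:, 1], f.polygon[:, 0], shape=shape)
        labels[rr, cc] = f.fibre_id + 1
    return labels


# --------------------------------------------------------------------------
# sarcomeric background
# --------------------------------------------------------------------------

def sarcomeric_background(marker: np.ndarray, nuclei: list, fibres,
                          channel_name: str = "marker",
                          dilate_px: int = 2,
                          min_pixels: int = 100) -> SarcomericBackground:
    """Mean and population SD of marker intensity over fibre-interior
    pixels, excluding nuclear masks dilated by ``dilate_px``.

    ``fibres`` may be a boolean fibre-interior raster, a label raster, or
    a list of FibreRecords (rasterised here).  Computed per image.
    """
    img = np.asarray(marker, dtype=float)
    if isinstance(fibres, np.ndarray):
        region = fibres > 0
    else:
        region = rasterise_fibres(fibres, img.shape) > 0
    nmask = np.zeros(img.shape, dtype=bool)
    for rec in nuclei:
        r0, c0, r1, c1 = rec.bbox
        nmask[r0:r1, c0:c1] |= rec.mask
    if dilate_px > 0:
        nmask = ndi.binary_dilation(nmask, structure=disk(dilate_px))
    eligible = region & ~nmask
    n = int(eligible.sum())
    if n < min_pixels:
        raise ValueError(
            f"only {n} sarcomeric pixels (< {min_pixels}); image unusable")
    vals = img[eligible]
    return SarcomericBackground(mean=float(vals.mean()),
                                sd=float(vals.std(ddof=0)),
                                channel=channel_name, pixel_count=n)
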