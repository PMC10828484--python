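"""Senescence-marker quantification.

Implements the four marker readouts reported per biopsy:

* **HMGB1** — a nucleus is positive iff its mean nuclear fluorescence
  exceeds the sarcomeric background mean plus twice the sarcomeric SD
  (strict inequality; a nucleus exactly at the threshold is negative).
* **Lamin B1** — integrated density over the peripheral nuclear ring
  (original minus eroded DAPI mask); positivity uses the area-normalised
  ring density against the same mean + 2·SD background rule.
* **TAF** — telomere-associated DNA-damage foci: γH2A.X foci whose
  centroid colocalises with a telomere focus in the same nucleus, under
  one-to-one closest-pairs-first matching; reported as the percentage of
  nuclei with ≥2 (and ≥3) TAF and as TAF as a percentage of all γH2A.X
  foci.
* **p16** — RNA-ISH foci per myofibre, split into nuclear and
  extranuclear, with the three ≥2-focus percentages (nuclei, fibres, any).

Foci are detected with scale-selective Laplacian-of-Gaussian blob
detection (2-D or 3-D) with a robust local-prominence cut and
centre-of-mass sub-pixel refinement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import blob_log

from .segmentation import FibreRecord, NucleusRecord, SarcomericBackground, rasterise_fibres
from .summary import SampleSummary

log = logging.getLogger(__name__)


@dataclass
class FociSet:
    """Detected or planted foci of one channel."""

    channel: str                     # "telomere" | "gH2AX" | "p16"
    points: np.ndarray               # (n, 2) [x, y] or (n, 3) [x, y, z]
    intensities: np.ndarray
    nucleus_assignment: np.ndarray | None = None   # nucleus_id or -1
    fibre_assignment: np.ndarray | None = None     # fibre_id or -1

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, self.ndim or 2)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.intensities) != len(self.points):
            raise ValueError("points and intensities length mismatch")

    @property
    def ndim(self):
        p = np.asarray(self.points)
        return p.shape[1] if p.ndim == 2 and p.size else (p.shape[-1] if p.size else None)

    def __len__(self):
        return len(self.points)


# --------------------------------------------------------------------------
# intensity-rule classifiers
# --------------------------------------------------------------------------

def hmgb1_positive(nucleus_mean: float, background: SarcomericBackground) -> bool:
    """True iff mean nuclear intensity strictly exceeds background mean
    plus twice the background SD."""
    return nucleus_mean > background.mean + 2.0 * background.sd


def laminb1_ring_density(channel: np.ndarray, nuclei: list) -> list:
    """Integrated density (sum of intensities) over each nucleus's ring
    mask; requires erode_nuclear_mask to have been run.  A fully eroded
    (thin) nucleus falls back to its full mask and keeps its flag."""
    img = np.asarray(channel, dtype=float)
    out = []
    for rec in nuclei:
        ring = rec.ring_mask if rec.ring_mask is not None else rec.mask
        r0, c0, r1, c1 = rec.bbox
        dens = float(img[r0:r1, c0:c1][ring].sum())
        rec.ring_integrated_density = dens
        out.append(dens)
    return out


def laminb1_positive(density: float, ring_area: int,
                     background: SarcomericBackground) -> bool:
    """Area-normalised ring density against the mean + 2·SD rule (the ring
    measurement is defined by the protocol; the positivity cut mirrors the
    HMGB1 rule for internal consistency)."""
    if ring_area <= 0:
        return False
    return density / ring_area > background.mean + 2.0 * background.sd


def classify_hmgb1(nuclei: list, marker: np.ndarray,
                   background: SarcomericBackground,
                   channel_name: str = "HMGB1") -> None:
    from .segmentation import measure_channel
    measure_channel(nuclei, marker, channel_name)
    for rec in nuclei:
        rec.hmgb1_positive = hmgb1_positive(rec.mean_intensity[channel_name],
                                            background)


def classify_laminb1(nuclei: list, marker: np.ndarray,
                     background: SarcomericBackground) -> None:
    laminb1_ring_density(marker, nuclei)
    for rec in nuclei:
        ring = rec.ring_mask if rec.ring_mask is not None else rec.mask
        rec.laminb1_positive = laminb1_positive(rec.ring_integrated_density,
                                                int(ring.sum()), background)


def analysed_nuclei(nuclei: list) -> list:
    """Non-excluded myonuclei: the denominator of every nuclear percentage."""
    return [n for n in nuclei if n.is_myonuclear and not n.qc_excluded]


def pct_positive(nuclei: list, attr: str) -> float:
    pool = analysed_nuclei(nuclei)
    if not pool:
        raise ValueError("no analysed nuclei")
    return 100.0 * sum(bool(getattr(n, attr)) for n in pool) / len(pool)


# --------------------------------------------------------------------------
# focus detection
# --------------------------------------------------------------------------

def detect_foci(channel: np.ndarray, scale_px: float,
                min_prominence: float = 4.0,
                z_scale: float = 0.8) -> FociSet:
    """Laplacian-of-Gaussian blob detection at the given spot scale.

    Candidate blobs come from scale-selective LoG filtering; each is kept
    only if its response in the scale-matched smoothed image exceeds
    ``min_prominence`` robust (MAD-based) noise SDs of that smoothed
    image — the matched filter concentrates focus signal while averaging
    noise down, so this is the natural domain for a prominence cut.
    Surviving foci get centre-of-mass sub-pixel centroids and
    deterministic (y, x) / (z, y, x) ordering.  Accepts 2-D images or
    (Z, H, W) stacks.
    """
    if scale_px <= 0:
        raise ValueError("scale_px must be positive")
    img = np.asarray(channel, dtype=float)
    is3d = img.ndim == 3
    bg = float(np.median(img))
    if img.max() - bg <= 0:
        return FociSet("unknown", np.empty((0, 3 if is3d else 2)), np.empty(0))
    sub = img - bg
    sigma = (z_scale * scale_px, scale_px, scale_px) if is3d else scale_px
    sm = ndi.gaussian_filter(sub, sigma)
    sm_med = float(np.median(sm))
    mad = float(np.median(np.abs(sm - sm_med))) * 1.4826
    robust_sd = max(mad, 1e-3 * float(sm.max() - sm_med), 1e-12)
    cut = sm_med + min_prominence * robust_sd
    if is3d:
        blobs = blob_log(sub, min_sigma=(z_scale * 0.8 * scale_px,) + (0.8 * scale_px,) * 2,
                         max_sigma=(z_scale * 1.6 * scale_px,) + (1.6 * scale_px,) * 2,
                         num_sigma=4, threshold=0.3 * min_prominence * robust_sd)
    else:
        blobs = blob_log(sub, min_sigma=0.8 * scale_px, max_sigma=1.6 * scale_px,
                         num_sigma=5, threshold=0.3 * min_prominence * robust_sd)
    pts, amps = [], []
    r = max(int(round(scale_px)), 2)
    for b in blobs:
        if is3d:
            z0, y0, x0 = int(round(b[0])), int(round(b[1])), int(round(b[2]))
            if sm[z0, y0, x0] < cut:
                continue
            zs = slice(max(z0 - 1, 0), min(z0 + 2, img.shape[0]))
            ys = slice(max(y0 - r, 0), min(y0 + r + 1, img.shape[1]))
            xs = slice(max(x0 - r, 0), min(x0 + r + 1, img.shape[2]))
            w = np.clip(sub[zs, ys, xs], 0.0, None)
            tot = w.sum()
            if tot <= 0:
                continue
            zz, yy, xx = np.mgrid[zs, ys, xs]
            pts.append((float((xx * w).sum() / tot), float((yy * w).sum() / tot),
                        float((zz * w).sum() / tot)))
            amps.append(float(sub[zs, ys, xs].max()))
        else:
            y0, x0 = int(round(b[0])), int(round(b[1]))
            if sm[y0, x0] < cut:
                continue
            ys = slice(max(y0 - r, 0), min(y0 + r + 1, img.shape[0]))
            xs = slice(max(x0 - r, 0), min(x0 + r + 1, img.shape[1]))
            w = np.clip(sub[ys, xs], 0.0, None)
            tot = w.sum()
            if tot <= 0:
                continue
            yy, xx = np.mgrid[ys, xs]
            pts.append((float((xx * w).sum() / tot), float((yy * w).sum() / tot)))
            amps.append(float(sub[ys, xs].max()))
    if not pts:
        return FociSet("unknown", np.empty((0, 3 if is3d else 2)), np.empty(0))
    pts = np.asarray(pts)
    amps = np.asarray(amps)
    # deduplicate near-coincident detections across scales
    keep = []
    for i in range(len(pts)):
        dup = False
        for j in keep:
            if np.linalg.norm(pts[i, :2] - pts[j, :2]) < 0.75 * scale_px and (
                    not is3d or abs(pts[i, 2] - pts[j, 2]) <= 1.0):
                dup = True
                break
        if not dup:
            keep.append(i)
    pts, amps = pts[keep], amps[keep]
    order = np.lexsort((pts[:, 0], pts[:, 1]) if not is3d
                       else (pts[:, 0], pts[:, 1], pts[:, 2]))
    return FociSet("unknown", pts[order], amps[order])


def assign_foci(fs: FociSet, nuclei: list | None, fibres: list | None,
                shape) -> FociSet:
    """Assign each focus to a nucleus (point-in-nuclear-mask) and a fibre
    (point-in-polygon via label raster); -1 where unassigned."""
    n = len(fs)
    if nuclei is not None:
        lab = np.full(shape, -1, dtype=np.int64)
        for rec in nuclei:
            r0, c0, r1, c1 = rec.bbox
            sub = lab[r0:r1, c0:c1]
            sub[rec.mask] = rec.nucleus_id
        fs.nucleus_assignment = np.array(
            [_lookup(lab, fs.points[i]) for i in range(n)], dtype=np.int64)
    if fibres is not None:
        flab = rasterise_fibres(fibres, shape)
        fs.fibre_assignment = np.array(
            [_lookup(flab, fs.points[i]) - 1 for i in range(n)], dtype=np.int64)
        fs.fibre_assignment[fs.fibre_assignment < 0] = -1
    return fs


def _lookup(raster: np.ndarray, pt) -> int:
    x, y = int(round(pt[0])), int(round(pt[1]))
    h, w = raster.shape
    if 0 <= y < h and 0 <= x < w:
        return int(raster[y, x])
    return -1


# --------------------------------------------------------------------------
# TAF
# --------------------------------------------------------------------------

@dataclass
class TafResult:
    per_nucleus: dict                # nucleus_id -> matched-pair count
    pairs: list                      # (telomere index, gH2AX index) matches
    taf_pct_of_gh2ax: float | None
    n_gh2ax: int


def count_taf(telomere: FociSet, gh2ax: FociSet, nuclei: list,
              coloc_radius_px: float = 1.5, z_tol: float = 1.0) -> TafResult:
    """One-to-one greedy nearest-pair telomere-γH2A.X matching per nucleus.

    A TAF is a γH2A.X focus whose centroid lies within
    ``coloc_radius_px`` (in-plane; within ``z_tol`` slices in z) of a
    telomere focus of the same nucleus.  Closest pairs match first and
    each focus is used at most once, so the pair set is symmetric in the
    argument order.  ``taf_pct_of_gh2ax`` is matched γH2A.X foci as a
    percentage of all γH2A.X foci over analysed myonuclei.
    """
    if coloc_radius_px <= 0:
        raise ValueError("coloc_radius_px must be positive")
    if telomere.nucleus_assignment is None or gh2ax.nucleus_assignment is None:
        raise ValueError("foci must be assigned to nuclei first")
    pool = {n.nucleus_id for n in analysed_nuclei(nuclei)}
    by_nuc_t, by_nuc_g = {}, {}
    for i, nid in enumerate(telomere.nucleus_assignment):
        by_nuc_t.setdefault(int(nid), []).append(i)
    for j, nid in enumerate(gh2ax.nucleus_assignment):
        by_nuc_g.setdefault(int(nid), []).append(j)
    per_nucleus = {nid: 0 for nid in pool}
    pairs = []
    n_gh = 0
    for nid in sorted(pool):
        tis, gjs = by_nuc_t.get(nid, []), by_nuc_g.get(nid, [])
        n_gh += len(gjs)
        cands = []
        for ti in tis:
            for gj in gjs:
                dx = telomere.points[ti, 0] - gh2ax.points[gj, 0]
                dy = telomere.points[ti, 1] - gh2ax.points[gj, 1]
                d = math.hypot(dx, dy)
                if d > coloc_radius_px:
                    continue
                if telomere.ndim == 3 and gh2ax.ndim == 3:
                    if abs(telomere.points[ti, 2] - gh2ax.points[gj, 2]) > z_tol:
                        continue
                cands.append((d, ti, gj))
        used_t, used_g = set(), set()
        for d, ti, gj in sorted(cands):
            if ti in used_t or gj in used_g:
                continue
            used_t.add(ti)
            used_g.add(gj)
            pairs.append((ti, gj))
            per_nucleus[nid] += 1
    for rec in nuclei:
        if rec.nucleus_id in per_nucleus:
            rec.taf_count = per_nucleus[rec.nucleus_id]
    pct = 100.0 * len(pairs) / n_gh if n_gh else None
    return TafResult(per_nucleus, pairs, pct, n_gh)


@dataclass
class PctResult:
    value: float
    n: int
    low_n: bool = False

    def __float__(self):
        return float(self.value)


def pct_taf(nuclei, k: int, min_denominator: int = 100) -> PctResult:
    """Percentage of analysed myonuclei with at least ``k`` TAF.

    ``nuclei`` may be NucleusRecords (non-excluded myonuclei counted) or a
    bare list of per-nucleus TAF counts.  A denominator below
    ``min_denominator`` (the per-sample analysis quota) still yields a
    value but is flagged ``low_n``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if nuclei and isinstance(nuclei[0], NucleusRecord):
        counts = [n.taf_count for n in analysed_nuclei(nuclei)]
    else:
        counts = [int(c) for c in nuclei]
    if not counts:
        raise ValueError("no analysed nuclei")
    value = 100.0 * sum(c >= k for c in counts) / len(counts)
    return PctResult(value, len(counts), low_n=len(counts) < min_denominator)


# --------------------------------------------------------------------------
# p16
# --------------------------------------------------------------------------

# transmitted-light stain colours for unmixing the RNAscope RED chromogen
# from the haematoxylin counterstain (rows: stains, columns: RGB OD)
_P16_STAINS = np.array([
    [0.35, 0.45, 0.85],   # haematoxylin
    [0.85, 0.15, 0.20],   # red chromogen
])


def p16_chromogen_map(rgb: np.ndarray) -> np.ndarray:
    """Red-chromogen absorbance map from a brightfield RGB image by colour
    deconvolution (least-squares unmixing of optical densities)."""
    img = np.asarray(rgb, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB raster")
    white = 255.0 if img.max() > 1.5 else 1.0
    od = -np.log10(np.clip(img / white, 1e-3, 1.0))
    basis = -np.log10(_P16_STAINS).T          # (3 rgb, 2 stains)
    coef, *_ = np.linalg.lstsq(basis, od.reshape(-1, 3).T, rcond=None)
    return np.clip(coef[1].reshape(img.shape[:2]), 0.0, None)


def p16_scores(p16_foci: FociSet, nuclei: list, fibres: list):
    """The three ≥2-focus p16 percentages.

    Denominators: analysed nuclei are non-excluded myonuclei inside
    analysed (non-edge) fibres; fibre percentages are over analysed
    fibres.  The "any" percentage pools nuclear and extranuclear foci per
    fibre.  Foci outside every fibre are excluded and logged.
    """
    if p16_foci.nucleus_assignment is None or p16_foci.fibre_assignment is None:
        raise ValueError("p16 foci must be assigned to nuclei and fibres first")
    good_fibres = [f for f in fibres if not f.edge]
    good_ids = {f.fibre_id for f in good_fibres}
    nuc_pool = [n for n in analysed_nuclei(nuclei) if n.fibre_id in good_ids]
    if not nuc_pool or not good_fibres:
        raise ValueError("no analysed nuclei or fibres")
    nuc_counts = {n.nucleus_id: 0 for n in nuclei}
    extra = {f.fibre_id: 0 for f in fibres}
    n_orphan = 0
    for i in range(len(p16_foci)):
        nid = int(p16_foci.nucleus_assignment[i])
        fid = int(p16_foci.fibre_assignment[i])
        if fid < 0:
            n_orphan += 1
            continue
        if nid >= 0 and nid in nuc_counts:
            nuc_counts[nid] += 1
        else:
            extra[fid] = extra.get(fid, 0) + 1
    if n_orphan:
        log.info("%d p16 foci outside every fibre were excluded", n_orphan)
    nuc_by_fibre = {f.fibre_id: 0 for f in fibres}
    for n in nuc_pool:
        nuc_by_fibre[n.fibre_id] += nuc_counts[n.nucleus_id]
    for f in fibres:
        f.p16_foci_nuclear = nuc_by_fibre.get(f.fibre_id, 0)
        f.p16_foci_extranuclear = extra.get(f.fibre_id, 0)
    pct_nuc = 100.0 * sum(nuc_counts[n.nucleus_id] >= 2 for n in nuc_pool) / len(nuc_pool)
    pct_fib = 100.0 * sum(extra.get(f.fibre_id, 0) >= 2 for f in good_fibres) / len(good_fibres)
    pct_any = 100.0 * sum(
        extra.get(f.fibre_id, 0) + nuc_by_fibre.get(f.fibre_id, 0) >= 2
        for f in good_fibres) / len(good_fibres)
    return pct_nuc, pct_fib, pct_any


# --------------------------------------------------------------------------
# summary
# --------------------------------------------------------------------------

def summarise_sample(nuclei: list | None, fibres: list | None,
                     foci_sets: dict | None = None,
                     taf: TafResult | None = None,
                     morphology=None, panel: str | None = None,
                     nuclei_window=(100, 250),
                     fibre_window=(75, 125)) -> SampleSummary:
    """Assemble the per-biopsy variable set from whatever quantifiers ran.

    Missing upstream outputs leave fields missing (``None``), never zero,
    and add a flag.  Deterministic given its inputs.
    """
    out = SampleSummary()
    flags = out.flags
    pool = analysed_nuclei(nuclei) if nuclei else []
    good_fibres = [f for f in fibres if not f.edge] if fibres else []
    out.n_nuclei_analysed = len(pool) if nuclei else None
    out.n_fibres_analysed = len(good_fibres) if fibres else None
    if nuclei is None:
        flags.append("missing:nuclei")
    elif not (nuclei_window[0] <= len(pool) <= nuclei_window[1]):
        flags.append("low_n" if len(pool) < nuclei_window[0] else "high_n")
    if fibres is None:
        flags.append("missing:fibres")

    if pool and panel == "HMGB1":
        if all(n.hmgb1_positive is None for n in pool):
            flags.append("missing:hmgb1")
        else:
            out.pct_hmgb1_pos = pct_positive(nuclei, "hmgb1_positive")
    if pool and panel == "LaminB1":
        if all(n.laminb1_positive is None for n in pool):
            flags.append("missing:laminb1")
        else:
            out.pct_laminb1_pos = pct_positive(nuclei, "laminb1_positive")
    if taf is not None and pool:
        r2 = pct_taf(nuclei, 2)
        r3 = pct_taf(nuclei, 3)
        out.pct_taf_2plus, out.pct_taf_3plus = r2.value, r3.value
        out.taf_pct_of_gh2ax = taf.taf_pct_of_gh2ax
        if r2.low_n:
            flags.append("low_n:taf")
    if foci_sets and "p16" in foci_sets and pool and good_fibres:
        pn, pf, pa = p16_scores(foci_sets["p16"], nuclei, fibres)
        out.pct_p16_nuclei_2plus = pn
        out.pct_p16_fibre_2plus = pf
        out.pct_p16_any_2plus = pa
        if not (fibre_window[0] <= len(good_fibres) <= fibre_window[1]):
            flags.append("fibre_n_outside_window")

    if morphology is not None:
        out.min_feret_mean = morphology.min_feret_mean
        out.feret_units = morphology.feret_units
        out.fibre_number = len(good_fibres) if fibres else None
        out.fibrotic_area_pct = morphology.fibrotic_area_pct
        out.cnf_pct = morphology.cnf_pct
    else:
        flags.append("missing:morphology")
    return out
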