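"""Synthetic muscle cross-section generator with complete ground truth.

Emulates transverse cryosections of human skeletal muscle as imaged for
senescence quantification: a near-hexagonal tessellation of myofibres
bounded by a WGA-stained extracellular band, peripheral / central /
interstitial nuclei, planted marker signal (p16 RNA-ISH foci, telomere and
γH2A.X foci with a controlled colocalisation fraction, HMGB1 and Lamin B1
nuclear intensity classes over sarcomeric background), fibrotic
interstitial regions, and H&E / picrosirius-red brightfield renderings.

Every planted object is recorded in a :class:`GroundTruth`, and the
per-sample summary implied by the plants is computed by direct counting of
the planted lists, so each quantification stage can be scored against a
known answer.

Geometry conventions: pixel-centred 0-based coordinates, x rightward,
y downward; polygons are closed, counter-clockwise; all µm↔px conversion
goes through ``pixel_size_um``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon, box
from shapely.geometry.polygon import orient
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .summary import SampleSummary

PANELS = ("p16", "TAF", "HMGB1", "LaminB1", "HE", "PR")

NUC_PERIPHERAL = "myonuclear-peripheral"
NUC_CENTRAL = "myonuclear-central"
NUC_INTERSTITIAL = "interstitial"

# planted separations (px, in-plane).  EXCLUSION keeps every non-colocalised
# γH2A.X focus clear of all telomere spots so colocalisation matching is
# unambiguous; the same-channel spacings keep planted foci resolvable as
# distinct spots at the rendered PSF, as countable foci must be
EXCLUSION_RADIUS_PX = 3.0
GH_MIN_SEP_PX = 5.0
TEL_MIN_SEP_PX = 7.0

# background (sarcomeric) intensity model for fluorescence marker channels
_BG_MEAN = 500.0
_BG_SD = 50.0
_DAPI_LEVEL = 3000.0
_WGA_LEVEL = 2000.0
_FOCUS_AMPLITUDE = 1200.0
_FOCUS_SIGMA_PX = 1.2


@dataclass
class SectionSpec:
    """Parameters of one synthetic section.

    Defaults emulate the study conditions: ~1 µm pixels, fibres of ~50 µm
    mean diameter so a 512² field holds on the order of a hundred fibres
    (75-125 analysed per section for p16, 100-250 nuclei per sample), a
    fibrotic area fraction near the reported medians (~13%), and a
    telomere-γH2A.X colocalisation fraction near the reported TAF%γH2A.X
    (~35%).
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    n_fibres_target: int | None = None
    fibre_diameter_um_mean: float = 50.0
    fibre_diameter_um_sd: float = 6.0
    boundary_width_um: float = 4.0
    fibrosis_fraction_target: float = 0.13
    cnf_fraction: float = 0.0
    nuclei_per_fibre_mean: float = 1.8
    interstitial_nucleus_rate: float = 0.4
    marker_panel: str = "TAF"
    foci_per_nucleus_distribution: dict = field(default_factory=lambda: {"poisson": 1.0})
    coloc_fraction: float = 0.35
    coloc_jitter_px: float = 1.0
    positive_fraction: float = 0.26
    intensity_contrast_sd: float = 6.0
    noise_model: dict | None = field(default_factory=lambda: {"gaussian_sd": 8.0})
    psf_sigma_px: float = 1.0
    seed: int = 0
    # auxiliary plants (not varied by the study conditions)
    telomere_per_nucleus_mean: float = 8.0
    p16_extranuclear_per_fibre_mean: float = 0.8
    focus_amplitude: float = 1200.0

    def __post_init__(self):
        for name in ("fibrosis_fraction_target", "cnf_fraction",
                     "coloc_fraction", "positive_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.marker_panel not in PANELS:
            raise ValueError(f"marker_panel must be one of {PANELS}")
        if self.psf_sigma_px < 0:
            raise ValueError("psf_sigma_px must be nonnegative")
        h, w = self.field_size_px
        if self.fibre_diameter_um_mean / self.pixel_size_um > min(h, w):
            raise ValueError(
                "infeasible geometry: fibre diameter "
                f"({self.fibre_diameter_um_mean} um) exceeds the field")


@dataclass
class SectionImage:
    """Multi-channel raster with channel roles and calibration."""

    pixels: np.ndarray          # (C, H, W), (Z, C, H, W) fluorescence; (H, W, 3) RGB
    channels: tuple             # channel names, or ("RGB",)
    modality: str               # "fluorescence" | "brightfield"
    pixel_size_um: float
    z_step_um: float | None = None

    @property
    def n_slices(self) -> int | None:
        return self.pixels.shape[0] if self.pixels.ndim == 4 else None

    def channel(self, name: str, z: int | None = None) -> np.ndarray:
        i = self.channels.index(name)
        if self.pixels.ndim == 4:
            return self.pixels[:, i] if z is None else self.pixels[z, i]
        return self.pixels[i]


@dataclass
class Nucleus:
    center: tuple               # (x, y) px
    axes: tuple                 # (semi-major, semi-minor) px
    angle: float                # radians, CCW from +x
    cls: str                    # NUC_* class
    fibre_id: int               # containing fibre id or -1
    z_center: float | None = None
    z_sigma: float | None = None


@dataclass
class Focus:
    x: float
    y: float
    z: float | None
    nucleus_id: int
    partner_id: int | None = None   # index of the colocalised telomere focus
    fibre_id: int = -1              # containing fibre (set for all planted foci)


@dataclass
class GroundTruth:
    """Everything planted in one section, plus the implied summary."""

    fibre_polygons: list            # closed CCW (n,2) arrays, px, interior side of WGA
    fibre_edge: list                # bool per fibre
    fibre_labels: np.ndarray        # int32 raster, 0 = interstitium/boundary
    fibre_central: list             # planted CNF flag per fibre
    nuclei: list                    # Nucleus
    nucleus_marker_class: list      # "positive" | "negative" | None
    foci_true: dict                 # channel -> list[Focus]
    p16_extranuclear: dict          # fibre index -> planted extranuclear count
    fibrotic_mask: np.ndarray       # bool raster
    per_sample_truth: SampleSummary = None
    spec: SectionSpec = None

    # ---- truth-side accounting (direct counts over the planted lists) ----

    def analysed_fibre_ids(self) -> list[int]:
        return [i for i, e in enumerate(self.fibre_edge) if not e]

    def analysed_nucleus_ids(self) -> list[int]:
        """Myonuclei inside non-edge fibres: the analysis denominator."""
        good = set(self.analysed_fibre_ids())
        return [i for i, n in enumerate(self.nuclei)
                if n.cls in (NUC_PERIPHERAL, NUC_CENTRAL) and n.fibre_id in good]

    def taf_counts_true(self) -> dict:
        counts = {i: 0 for i in self.analysed_nucleus_ids()}
        for f in self.foci_true.get("gH2AX", []):
            if f.partner_id is not None and f.nucleus_id in counts:
                counts[f.nucleus_id] += 1
        return counts

    def recompute_summary(self) -> SampleSummary:
        """Recompute the per-sample summary from the planted lists."""
        spec = self.spec
        nuc_ids = self.analysed_nucleus_ids()
        fib_ids = self.analysed_fibre_ids()
        n_nuc, n_fib = len(nuc_ids), len(fib_ids)
        out = SampleSummary()
        out.n_nuclei_analysed = n_nuc
        out.n_fibres_analysed = n_fib

        panel = spec.marker_panel
        if panel in ("HMGB1", "LaminB1") and n_nuc:
            pos = sum(self.nucleus_marker_class[i] == "positive" for i in nuc_ids)
            if panel == "HMGB1":
                out.pct_hmgb1_pos = 100.0 * pos / n_nuc
            else:
                out.pct_laminb1_pos = 100.0 * pos / n_nuc
        if panel == "TAF" and n_nuc:
            counts = self.taf_counts_true()
            gh = [f for f in self.foci_true.get("gH2AX", [])
                  if f.nucleus_id in set(nuc_ids)]
            out.pct_taf_2plus = 100.0 * sum(c >= 2 for c in counts.values()) / n_nuc
            out.pct_taf_3plus = 100.0 * sum(c >= 3 for c in counts.values()) / n_nuc
            matched = sum(f.partner_id is not None for f in gh)
            out.taf_pct_of_gh2ax = 100.0 * matched / len(gh) if gh else None
        if panel == "p16" and n_nuc and n_fib:
            nuc_counts = {i: 0 for i in range(len(self.nuclei))}
            for f in self.foci_true.get("p16", []):
                if f.nucleus_id >= 0:
                    nuc_counts[f.nucleus_id] += 1
            out.pct_p16_nuclei_2plus = (
                100.0 * sum(nuc_counts[i] >= 2 for i in nuc_ids) / n_nuc)
            per_fibre_nuclear = {i: 0 for i in fib_ids}
            for i in nuc_ids:
                per_fibre_nuclear[self.nuclei[i].fibre_id] += nuc_counts[i]
            extra = {i: self.p16_extranuclear.get(i, 0) for i in fib_ids}
            out.pct_p16_fibre_2plus = (
                100.0 * sum(extra[i] >= 2 for i in fib_ids) / n_fib)
            out.pct_p16_any_2plus = (
                100.0 * sum(extra[i] + per_fibre_nuclear[i] >= 2 for i in fib_ids)
                / n_fib)

        # morphology truth (always available from the geometry)
        from .morphology import min_feret  # local import avoids cycles at import time
        if n_fib:
            ferets = [min_feret(self.fibre_polygons[i], spec.pixel_size_um)
                      for i in fib_ids]
            out.min_feret_mean = float(np.mean(ferets))
            out.feret_units = "um"
            out.fibre_number = n_fib
            central = sum(self.fibre_central[i] for i in fib_ids)
            out.cnf_pct = 100.0 * central / n_fib
        out.fibrotic_area_pct = 100.0 * float(self.fibrotic_mask.mean())
        return out


# --------------------------------------------------------------------------
# tessellation
# --------------------------------------------------------------------------

def _tessellate(spec: SectionSpec, rng: np.random.Generator):
    h, w = spec.field_size_px
    if spec.n_fibres_target:
        # area per hexagonal cell = spacing^2 * sqrt(3)/2
        spacing = math.sqrt(2.0 * h * w / (math.sqrt(3.0) * spec.n_fibres_target))
    else:
        spacing = spec.fibre_diameter_um_mean / spec.pixel_size_um
    jitter = 0.6 * spec.fibre_diameter_um_sd / spec.pixel_size_um

    dy = spacing * math.sqrt(3.0) / 2.0
    pts = []
    row = 0
    y = -spacing
    while y < h + spacing:
        x0 = -spacing + (spacing / 2.0 if row % 2 else 0.0)
        x = x0
        while x < w + spacing:
            pts.append((x, y))
            x += spacing
        y += dy
        row += 1
    pts = np.asarray(pts, dtype=float)
    pts = pts + rng.normal(0.0, jitter, size=pts.shape)

    # sentinels keep all interior Voronoi regions bounded
    m = 4 * spacing
    sent = np.array([[-m, -m], [w + m, -m], [-m, h + m], [w + m, h + m],
                     [w / 2, -m], [w / 2, h + m], [-m, h / 2], [w + m, h / 2]])
    vor = Voronoi(np.vstack([pts, sent]))

    field_rect = box(-0.5, -0.5, w - 0.5, h - 0.5)
    cells = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid or poly.is_empty:
            continue
        clipped = poly.intersection(field_rect)
        if clipped.is_empty or clipped.geom_type != "Polygon" or clipped.area < 4.0:
            continue
        edge = clipped.area < poly.area - 1e-6
        cells.append((orient(clipped, 1.0), edge))
    # deterministic id order: scan order of centroids
    cells.sort(key=lambda ce: (round(ce[0].centroid.y, 3), round(ce[0].centroid.x, 3)))
    return cells


def _rasterise_interiors(interiors, shape) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    for i, poly in enumerate(interiors):
        xy = np.asarray(poly.exterior.coords)
        rr, cc = draw_polygon(xy[:, 1], xy[:, 0], shape=shape)
        labels[rr, cc] = i + 1
    return labels


def _paint_fibrosis(labels: np.ndarray, target: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Fibrotic mask hitting ``target`` area fraction within ±0.01.

    Fibrosis lives in (and widens) the interstitium: below the interstitial
    fraction it fills the deepest interstitial pixels first; above it, it
    grows into the fibres from the boundary by distance ordering.
    """
    n_px = labels.size
    want = int(round(target * n_px))
    interstitial = labels == 0
    d_into_fibre = ndi.distance_transform_edt(labels > 0)   # 0 on interstitium
    d_into_inter = ndi.distance_transform_edt(interstitial)  # 0 on fibres
    # single ordering: interstitial pixels deepest-first, then fibre pixels
    # shallowest-first; random jitter breaks ties reproducibly
    score = np.where(interstitial, -d_into_inter, d_into_fibre)
    score = score + rng.uniform(0.0, 1e-3, size=score.shape)
    order = np.argsort(score, axis=None)
    mask = np.zeros(n_px, dtype=bool)
    mask[order[:want]] = True
    mask = mask.reshape(labels.shape)
    got = mask.mean()
    if abs(got - target) > 0.01:
        raise RuntimeError(
            f"fibrosis target {target} unreachable (achieved {got:.3f})")
    return mask


# --------------------------------------------------------------------------
# nuclei
# --------------------------------------------------------------------------

def _sample_in_polygon(poly: Polygon, rng: np.random.Generator, tries: int = 60):
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(tries):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if poly.contains(p):
            return p.x, p.y
    c = poly.representative_point()
    return c.x, c.y


def _place_nuclei(spec: SectionSpec, interiors, edges, rng: np.random.Generator):
    nuclei: list[Nucleus] = []
    central_flags = [False] * len(interiors)
    placed_xy: list[tuple] = []
    min_sep = 13.0 / spec.pixel_size_um

    def ok(x, y):
        return all((x - px) ** 2 + (y - py) ** 2 >= min_sep ** 2
                   for px, py in placed_xy)

    def axes():
        # nominal myonucleus ~11 x 7.5 um; axes are stored in px
        a = float(np.clip(rng.normal(5.5, 0.5), 4.5, 7.0)) / spec.pixel_size_um
        b = float(np.clip(rng.normal(3.8, 0.4), 3.0, 7.0)) / spec.pixel_size_um
        return a, min(b, a - 0.3)

    for fid, poly in enumerate(interiors):
        n = int(rng.poisson(spec.nuclei_per_fibre_mean))
        is_cnf = bool(rng.random() < spec.cnf_fraction)
        if is_cnf and n == 0:
            n = 1
        r_eq = math.sqrt(poly.area / math.pi)
        core = poly.buffer(-0.5 * r_eq)
        # peripheral band: inset below the CNF core margin (0.25 * r_eq)
        inset = min(4.5, max(0.18 * r_eq, 1.6))
        ring = poly.buffer(-inset)
        for k in range(n):
            central = is_cnf and k == 0
            placed = False
            for _ in range(30):
                if central:
                    if core.is_empty:
                        break
                    x, y = _sample_in_polygon(core, rng)
                else:
                    if ring.is_empty or ring.exterior is None:
                        break
                    t = rng.uniform(0.0, ring.exterior.length)
                    p = ring.exterior.interpolate(t)
                    x, y = p.x, p.y
                    if not core.is_empty and core.contains(Point(x, y)):
                        continue
                if ok(x, y):
                    a, b = axes()
                    nuclei.append(Nucleus((x, y), (a, b), rng.uniform(0, math.pi),
                                          NUC_CENTRAL if central else NUC_PERIPHERAL,
                                          fid))
                    placed_xy.append((x, y))
                    placed = True
                    break
            if central and placed:
                central_flags[fid] = True

    # interstitial / satellite nuclei
    n_inter = int(rng.poisson(spec.interstitial_nucleus_rate * max(len(interiors), 1)))
    inter_mask_needed = n_inter > 0
    if inter_mask_needed:
        h, w = spec.field_size_px
        for _ in range(n_inter):
            for _ in range(60):
                x = rng.uniform(2.0, w - 3.0)
                y = rng.uniform(2.0, h - 3.0)
                p = Point(x, y)
                if any(poly.contains(p) for poly in interiors):
                    continue
                if ok(x, y):
                    a, b = axes()
                    nuclei.append(Nucleus((x, y), (a, b), rng.uniform(0, math.pi),
                                          NUC_INTERSTITIAL, -1))
                    placed_xy.append((x, y))
                    break
    return nuclei, central_flags


def _sample_in_ellipse(nuc: Nucleus, rng: np.random.Generator, shrink: float = 0.8):
    r = math.sqrt(rng.uniform())
    th = rng.uniform(0.0, 2.0 * math.pi)
    ex = shrink * nuc.axes[0] * r * math.cos(th)
    ey = shrink * nuc.axes[1] * r * math.sin(th)
    ca, sa = math.cos(nuc.angle), math.sin(nuc.angle)
    return (nuc.center[0] + ca * ex - sa * ey,
            nuc.center[1] + sa * ex + ca * ey)


def _plant_taf_foci(spec: SectionSpec, nuclei, rng: np.random.Generator,
                    with_z: bool = False):
    telomere: list[Focus] = []
    gh2ax: list[Focus] = []
    dropped_noncoloc = 0
    dropped_coloc = 0
    for nid, nuc in enumerate(nuclei):
        if nuc.cls == NUC_INTERSTITIAL:
            continue
        n_tel = int(rng.poisson(spec.telomere_per_nucleus_mean))
        tel_idx = []
        for _ in range(n_tel):
            # telomere spots stay TEL_MIN_SEP apart so that a colocalised
            # γH2A.X focus is unambiguously nearest to its own partner and
            # adjacent foci stay resolvable
            for _try in range(40):
                x, y = _sample_in_ellipse(nuc, rng)
                if all(math.hypot(x - telomere[j].x, y - telomere[j].y) >= TEL_MIN_SEP_PX
                       for j in tel_idx):
                    break
            else:
                continue
            z = _focus_z(nuc, rng) if with_z else None
            tel_idx.append(len(telomere))
            telomere.append(Focus(x, y, z, nid, fibre_id=nuc.fibre_id))
        n_gh = _draw_count(spec.foci_per_nucleus_distribution, rng)
        want_coloc = [bool(rng.random() < spec.coloc_fraction) for _ in range(n_gh)]
        free = list(tel_idx)
        own = []    # gH2A.X positions already planted in this nucleus
        # colocalised foci go down first (on telomeres, which are mutually
        # spaced); non-colocalised foci then keep clear of telomeres and of
        # every existing gH2A.X focus, so all planted foci stay resolvable
        for coloc in sorted(want_coloc, reverse=True):
            if coloc:
                if free:
                    j = free.pop(int(rng.integers(len(free))))
                else:
                    # plant a fresh telomere to pair with, keeping the
                    # planted colocalisation fraction at its nominal value
                    j = None
                    for _ in range(80):
                        x, y = _sample_in_ellipse(nuc, rng)
                        d_tel = min((math.hypot(x - telomere[k].x,
                                                y - telomere[k].y)
                                     for k in tel_idx), default=math.inf)
                        d_own = min((math.hypot(x - ox, y - oy)
                                     for ox, oy in own), default=math.inf)
                        if d_tel >= TEL_MIN_SEP_PX and d_own > GH_MIN_SEP_PX:
                            j = len(telomere)
                            tel_idx.append(j)
                            telomere.append(Focus(
                                x, y, _focus_z(nuc, rng) if with_z else None,
                                nid, fibre_id=nuc.fibre_id))
                            break
                    if j is None:
                        dropped_coloc += 1
                        continue
                t = telomere[j]
                ang = rng.uniform(0.0, 2.0 * math.pi)
                rad = rng.uniform(0.0, spec.coloc_jitter_px)
                x, y = t.x + rad * math.cos(ang), t.y + rad * math.sin(ang)
                own.append((x, y))
                gh2ax.append(Focus(x, y, t.z, nid, partner_id=j,
                                   fibre_id=nuc.fibre_id))
            else:
                placed = None
                for _ in range(150):
                    x, y = _sample_in_ellipse(nuc, rng)
                    d_tel = min((math.hypot(x - telomere[j].x, y - telomere[j].y)
                                 for j in tel_idx), default=math.inf)
                    d_own = min((math.hypot(x - ox, y - oy) for ox, oy in own),
                                default=math.inf)
                    if d_tel > EXCLUSION_RADIUS_PX and d_own > GH_MIN_SEP_PX:
                        placed = (x, y)
                        break
                if placed is None:
                    # nucleus too crowded to respect the exclusion zones
                    dropped_noncoloc += 1
                    continue
                z = _focus_z(nuc, rng) if with_z else None
                own.append(placed)
                gh2ax.append(Focus(placed[0], placed[1], z, nid,
                                   fibre_id=nuc.fibre_id))
    # placement failures hit the two classes unevenly and would bias the
    # realised colocalised fraction; remove foci from the other class in
    # proportion so the planted fraction stays binomial around nominal
    p = spec.coloc_fraction
    if 0.0 < p < 1.0 and (dropped_noncoloc or dropped_coloc):
        excess_coloc = dropped_noncoloc * p / (1.0 - p) - dropped_coloc
        if excess_coloc > 0:
            idx = [i for i, f in enumerate(gh2ax) if f.partner_id is not None]
            k = min(int(round(excess_coloc)), len(idx))
        else:
            idx = [i for i, f in enumerate(gh2ax) if f.partner_id is None]
            k = min(int(round(-excess_coloc * (1.0 - p) / p)), len(idx))
        if k > 0 and idx:
            drop = set(rng.choice(idx, size=k, replace=False).tolist())
            gh2ax = [f for i, f in enumerate(gh2ax) if i not in drop]
    return telomere, gh2ax


def _focus_z(nuc: Nucleus, rng: np.random.Generator) -> float:
    return float(np.clip(rng.normal(nuc.z_center, 0.6 * nuc.z_sigma),
                         nuc.z_center - nuc.z_sigma, nuc.z_center + nuc.z_sigma))


def _draw_count(dist_spec: dict, rng: np.random.Generator) -> int:
    if "poisson" in dist_spec:
        return int(rng.poisson(dist_spec["poisson"]))
    if "fixed" in dist_spec:
        return int(dist_spec["fixed"])
    if "pmf" in dist_spec:
        pmf = np.asarray(dist_spec["pmf"], dtype=float)
        return int(rng.choice(len(pmf), p=pmf / pmf.sum()))
    raise ValueError(f"unknown count distribution {dist_spec!r}")


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _nucleus_raster(nuclei, shape, level_fn) -> np.ndarray:
    """Paint each nucleus ellipse at the per-nucleus level given by level_fn."""
    img = np.zeros(shape, dtype=float)
    for nid, nuc in enumerate(nuclei):
        rr, cc = draw_ellipse(nuc.center[1], nuc.center[0],
                              nuc.axes[1], nuc.axes[0],
                              shape=shape, rotation=-nuc.angle)
        img[rr, cc] = level_fn(nid, nuc)
    return img


def _nucleus_mask(nuclei, shape) -> np.ndarray:
    return _nucleus_raster(nuclei, shape, lambda *_: 1.0) > 0


def _add_foci(img: np.ndarray, foci, amplitude: float = _FOCUS_AMPLITUDE,
              sigma: float = _FOCUS_SIGMA_PX) -> None:
    h, w = img.shape
    r = int(math.ceil(4 * sigma))
    for f in foci:
        x0, y0 = int(round(f.x)), int(round(f.y))
        ys = slice(max(y0 - r, 0), min(y0 + r + 1, h))
        xs = slice(max(x0 - r, 0), min(x0 + r + 1, w))
        yy, xx = np.mgrid[ys, xs]
        img[ys, xs] += amplitude * np.exp(
            -((xx - f.x) ** 2 + (yy - f.y) ** 2) / (2.0 * sigma ** 2))


def _finish_fluorescence(chans: list, spec: SectionSpec,
                         rng: np.random.Generator) -> np.ndarray:
    out = []
    for c in chans:
        img = c.astype(float)
        if spec.psf_sigma_px > 0:
            img = ndi.gaussian_filter(img, spec.psf_sigma_px)
        if spec.noise_model:
            if spec.noise_model.get("poisson_on"):
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            sd = spec.noise_model.get("gaussian_sd", 0.0)
            if sd:
                img = img + rng.normal(0.0, sd, size=img.shape)
        out.append(np.clip(np.rint(img), 0, 65535).astype(np.uint16))
    return np.stack(out)


def _render_fluorescence(spec, labels, nuclei, marker_class, foci, rng):
    h, w = spec.field_size_px
    shape = (h, w)
    dapi = np.full(shape, 100.0)
    dapi += _nucleus_raster(nuclei, shape, lambda *_: _DAPI_LEVEL - 100.0)
    wga = np.full(shape, 100.0)
    wga[labels == 0] = _WGA_LEVEL

    texture = rng.normal(_BG_MEAN, _BG_SD, size=shape)

    def class_level(nid, nuc):
        pos = marker_class[nid] == "positive"
        return (_BG_MEAN + spec.intensity_contrast_sd * _BG_SD) if pos else _BG_MEAN

    panel = spec.marker_panel
    if panel == "HMGB1":
        marker = np.where(labels > 0, texture, 120.0)
        nuc_lvl = _nucleus_raster(nuclei, shape, class_level)
        marker = np.where(nuc_lvl > 0, nuc_lvl, marker)
        chans = [dapi, wga, marker]
        names = ("DAPI", "WGA", "HMGB1")
    elif panel == "LaminB1":
        marker = np.where(labels > 0, texture, 120.0)
        # nuclear interior dimmer than sarcoplasm; positive nuclei get a
        # bright peripheral ring, negative nuclei a background-level ring
        interior = _nucleus_raster(nuclei, shape, lambda *_: 0.5 * _BG_MEAN)
        marker = np.where(interior > 0, interior, marker)
        ring_img = np.zeros(shape)
        for nid, nuc in enumerate(nuclei):
            lvl = class_level(nid, nuc)
            rr, cc = draw_ellipse(nuc.center[1], nuc.center[0],
                                  nuc.axes[1], nuc.axes[0],
                                  shape=shape, rotation=-nuc.angle)
            outer = np.zeros(shape, dtype=bool)
            outer[rr, cc] = True
            rr, cc = draw_ellipse(nuc.center[1], nuc.center[0],
                                  max(nuc.axes[1] - 2.0, 0.5),
                                  max(nuc.axes[0] - 2.0, 0.5),
                                  shape=shape, rotation=-nuc.angle)
            inner = np.zeros(shape, dtype=bool)
            inner[rr, cc] = True
            ring_img[outer & ~inner] = lvl
        marker = np.where(ring_img > 0, ring_img, marker)
        chans = [dapi, wga, marker]
        names = ("DAPI", "WGA", "LaminB1")
    elif panel == "TAF":
        tel = np.full(shape, 100.0)
        gh = np.full(shape, 100.0)
        _add_foci(tel, foci["telomere"], amplitude=spec.focus_amplitude)
        _add_foci(gh, foci["gH2AX"], amplitude=spec.focus_amplitude)
        chans = [dapi, wga, tel, gh]
        names = ("DAPI", "WGA", "telomere", "gH2AX")
    else:
        raise ValueError(f"panel {panel} is not a fluorescence panel")
    return SectionImage(_finish_fluorescence(chans, spec, rng), names,
                        "fluorescence", spec.pixel_size_um)


# brightfield stain colours (transmitted RGB of pure stain at unit density)
_STAIN_HAEM = np.array([0.35, 0.45, 0.85])      # haematoxylin blue-purple
_STAIN_RED = np.array([0.85, 0.15, 0.20])       # RNAscope RED chromogen
_STAIN_EOSIN = np.array([0.95, 0.55, 0.65])     # eosin pink
_STAIN_PR_FIB = np.array([0.80, 0.15, 0.18])    # picrosirius red collagen
_STAIN_PR_TIS = np.array([0.92, 0.80, 0.58])    # pale counterstained muscle


def _absorb(base: np.ndarray, mask: np.ndarray, colour: np.ndarray,
            density: float = 1.0) -> None:
    """Beer-Lambert style multiplicative attenuation on an RGB float image."""
    for k in range(3):
        base[:, :, k][mask] *= colour[k] ** density


def _render_brightfield(spec, labels, nuclei, foci, fibrotic, rng):
    h, w = spec.field_size_px
    img = np.full((h, w, 3), 0.97)
    tissue = np.ones((h, w), dtype=bool)
    panel = spec.marker_panel
    if panel == "PR":
        _absorb(img, tissue & ~fibrotic, _STAIN_PR_TIS)
        _absorb(img, fibrotic, _STAIN_PR_FIB)
    elif panel in ("HE", "p16"):
        base = _STAIN_EOSIN if panel == "HE" else np.array([0.93, 0.90, 0.88])
        _absorb(img, labels > 0, base)
        _absorb(img, labels == 0, base, density=1.8)
        nmask = _nucleus_mask(nuclei, (h, w))
        _absorb(img, nmask, _STAIN_HAEM)
        if panel == "p16":
            dots = np.zeros((h, w))
            _add_foci(dots, foci.get("p16", []), amplitude=1.0, sigma=1.2)
            dens = np.clip(dots, 0.0, 1.6)
            for k in range(3):
                img[:, :, k] *= _STAIN_RED[k] ** dens
    else:
        raise ValueError(f"panel {panel} is not a brightfield panel")
    if spec.psf_sigma_px > 0:
        for k in range(3):
            img[:, :, k] = ndi.gaussian_filter(img[:, :, k], 0.6 * spec.psf_sigma_px)
    img = img * 255.0
    if spec.noise_model:
        sd = spec.noise_model.get("gaussian_sd", 0.0)
        if sd:
            img = img + rng.normal(0.0, 0.5 * sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SectionImage(pixels, ("RGB",), "brightfield", spec.pixel_size_um)


# --------------------------------------------------------------------------
# top-level generators
# --------------------------------------------------------------------------

def _build_truth(spec, cells, rng, with_z=False, n_slices=None):
    h, w = spec.field_size_px
    half_bw = 0.5 * spec.boundary_width_um / spec.pixel_size_um
    interiors, edges = [], []
    for poly, edge in cells:
        inner = poly.buffer(-half_bw)
        if inner.is_empty or inner.geom_type != "Polygon" or inner.area < 150.0:
            continue
        interiors.append(orient(inner, 1.0))
        edges.append(edge)
    if not interiors:
        raise RuntimeError("tessellation produced no usable fibres")
    labels = _rasterise_interiors(interiors, (h, w))
    fibrotic = _paint_fibrosis(labels, spec.fibrosis_fraction_target, rng)
    nuclei, central = _place_nuclei(spec, interiors, edges, rng)

    if with_z:
        for nuc in nuclei:
            nuc.z_center = float(rng.uniform(0.35, 0.65) * (n_slices - 1))
            nuc.z_sigma = float(rng.uniform(1.0, 1.8))

    marker_class = [None] * len(nuclei)
    if spec.marker_panel in ("HMGB1", "LaminB1"):
        marker_class = ["positive" if rng.random() < spec.positive_fraction
                        else "negative" for _ in nuclei]

    foci = {}
    p16_extra = {}
    if spec.marker_panel == "TAF":
        tel, gh = _plant_taf_foci(spec, nuclei, rng, with_z=with_z)
        foci = {"telomere": tel, "gH2AX": gh}
    elif spec.marker_panel == "p16":
        pts = []
        for nid, nuc in enumerate(nuclei):
            if nuc.cls == NUC_INTERSTITIAL:
                continue
            for _ in range(_draw_count(spec.foci_per_nucleus_distribution, rng)):
                x, y = _sample_in_ellipse(nuc, rng)
                pts.append(Focus(x, y, None, nid, fibre_id=nuc.fibre_id))
        for fid, poly in enumerate(interiors):
            n_extra = int(rng.poisson(spec.p16_extranuclear_per_fibre_mean))
            placed = 0
            nmask_polys = [n for n in nuclei if n.fibre_id == fid]
            for _ in range(n_extra * 40):
                if placed == n_extra:
                    break
                x, y = _sample_in_polygon(poly.buffer(-2.0) if poly.area > 200 else poly, rng)
                if any(math.hypot(x - n.center[0], y - n.center[1])
                       < max(n.axes) + 2.0 for n in nmask_polys):
                    continue
                pts.append(Focus(x, y, None, -1, fibre_id=fid))
                placed += 1
            p16_extra[fid] = placed
        foci = {"p16": pts}

    polys = [np.vstack([np.asarray(p.exterior.coords)]) for p in interiors]
    gt = GroundTruth(
        fibre_polygons=polys, fibre_edge=edges, fibre_labels=labels,
        fibre_central=central, nuclei=nuclei,
        nucleus_marker_class=marker_class, foci_true=foci,
        p16_extranuclear=p16_extra, fibrotic_mask=fibrotic, spec=spec)
    gt.per_sample_truth = gt.recompute_summary()
    return gt, interiors


def generate_section(spec: SectionSpec):
    """Generate one synthetic section and its ground truth.

    Returns ``(SectionImage, GroundTruth)``.  Fluorescence panels produce
    channels DAPI, WGA and the marker channel(s); HE/PR/p16 panels produce
    an RGB brightfield raster.  A fixed seed gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _tessellate(spec, rng)
    gt, interiors = _build_truth(spec, cells, rng)
    if spec.marker_panel in ("HMGB1", "LaminB1", "TAF"):
        img = _render_fluorescence(spec, gt.fibre_labels, gt.nuclei,
                                   gt.nucleus_marker_class, gt.foci_true, rng)
    else:
        img = _render_brightfield(spec, gt.fibre_labels, gt.nuclei,
                                  gt.foci_true, gt.fibrotic_mask, rng)
    return img, gt


def generate_zstack(spec: SectionSpec, n_slices: int):
    """Generate a TAF z-stack: foci are 3-D Gaussians spanning adjacent
    optical slices, with the planted colocalisation fraction of γH2A.X foci
    sharing centroids (≤1 px in-plane jitter) with telomere foci.
    """
    if n_slices < 3:
        raise ValueError("n_slices must be >= 3")
    if spec.marker_panel != "TAF":
        spec = replace(spec, marker_panel="TAF")
    rng = np.random.default_rng(spec.seed)
    cells = _tessellate(spec, rng)
    gt, interiors = _build_truth(spec, cells, rng, with_z=True, n_slices=n_slices)
    h, w = spec.field_size_px
    shape = (h, w)
    wga2d = np.full(shape, 100.0)
    wga2d[gt.fibre_labels == 0] = _WGA_LEVEL
    sigma_z = 0.8  # slices
    slices = []
    for z in range(n_slices):
        dapi = np.full(shape, 100.0)
        for nuc in gt.nuclei:
            wz = math.exp(-((z - nuc.z_center) ** 2) / (2.0 * nuc.z_sigma ** 2))
            if wz < 0.02:
                continue
            rr, cc = draw_ellipse(nuc.center[1], nuc.center[0],
                                  nuc.axes[1], nuc.axes[0],
                                  shape=shape, rotation=-nuc.angle)
            dapi[rr, cc] = 100.0 + (_DAPI_LEVEL - 100.0) * wz
        tel = np.full(shape, 100.0)
        gh = np.full(shape, 100.0)
        for img2d, key in ((tel, "telomere"), (gh, "gH2AX")):
            zfoci = [Focus(f.x, f.y, f.z, f.nucleus_id) for f in gt.foci_true[key]
                     if abs(z - f.z) < 3.0 * sigma_z]
            amps = [spec.focus_amplitude
                    * math.exp(-((z - f.z) ** 2) / (2 * sigma_z ** 2))
                    for f in zfoci]
            for f, a in zip(zfoci, amps):
                _add_foci(img2d, [f], amplitude=a)
        stack = _finish_fluorescence([dapi, wga2d.copy(), tel, gh], spec, rng)
        slices.append(stack)
    pixels = np.stack(slices)  # (Z, C, H, W)
    img = SectionImage(pixels, ("DAPI", "WGA", "telomere", "gH2AX"),
                       "fluorescence", spec.pixel_size_um, z_step_um=0.5)
    return img, gt
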