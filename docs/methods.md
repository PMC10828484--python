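# Methods

This note documents the models, rules and numerical choices behind
`myosen`: what the synthetic sections emulate, exactly how each
senescence and morphology variable is computed, how the statistical layer
is defined, and what the passing tests do and do not establish about real
microscopy data.

## Synthetic muscle sections

### Geometry

A transverse muscle cross-section is modelled as a Voronoi tessellation
of a hexagonal lattice with i.i.d. Gaussian jitter, clipped to the field.
This gives near-convex, size-controllable polygons resembling myofibre
cross-sections.  Lattice spacing is the target fibre diameter
(`fibre_diameter_um_mean`, default 50 µm — adult vastus lateralis scale);
jitter is 0.6 × `fibre_diameter_um_sd` (default 6 µm).  When
`n_fibres_target` is set it overrides the spacing.  Cells clipped by the
field border are marked `edge` and excluded from every per-sample
summary, mirroring the exclusion of partial fibres from manual outlining;
nuclei inside edge fibres are likewise excluded from nuclear
denominators.

The extracellular WGA band has width `boundary_width_um` (default 4 µm);
the polygons recorded as ground truth (and used by all quantifiers) are
the fibre interiors on the sarcolemmal side of that band — the outline a
manual annotator would trace.  Interiors below 150 px² are dropped as
unusable slivers.

Coordinates are pixel-centred, 0-based, x rightward, y downward;
polygons closed and counter-clockwise; all µm↔px conversion goes through
`pixel_size_um`.

### Fibrosis

Fibrotic collagen lives in (and widens) the interstitium.  Pixels are
ranked by a single score — interstitial pixels deepest-first, then fibre
pixels by distance from the boundary — and the top fraction is painted
fibrotic, which reaches any target fraction in [0, 1] to well within the
contractual ±1 % absolute.  Default target 0.13, the scale of reported
fibrotic-area medians (~13 %).

### Nuclei

Nuclei are ellipses with semi-axes ≈ 5.5 × 3.8 µm (≈ 11 × 7.5 µm
diameter), mutually separated by ≥ 13 µm, placed per fibre with
Poisson(`nuclei_per_fibre_mean`, default 1.8) counts:

* *peripheral myonuclei* on an inset ring just inside the fibre boundary
  (inset min(4.5 px, max(0.18 r_eq, 1.6 px)), always strictly outside the
  central-nucleation core, see below);
* *central myonuclei* (one per fibre with probability `cnf_fraction`)
  placed inside the polygon eroded by 0.5 r_eq, safely within the CNF
  call margin;
* *interstitial nuclei* at rate `interstitial_nucleus_rate` per fibre
  (default 0.4) in the space between fibres.

With the defaults a 512² px field at 1 µm/px holds ≈ 100 analysed fibres
and 150–200 analysed myonuclei, matching the per-sample analysis windows
of the protocol being emulated (75–125 fibres for p16, 100–250 nuclei for
the intensity markers, ≥ 100 myonuclei for TAF).

### Marker signal

Fluorescence channels carry a sarcomeric background texture of
N(500, 50²) A.U. inside fibres.  Marker-positive nuclei (probability
`positive_fraction`) are painted at background mean +
`intensity_contrast_sd` × background SD — as the whole-nucleus level for
HMGB1, or as a 2-px peripheral ring for Lamin B1 (negative nuclei get a
background-level ring over a dimmed interior).  The PSF blur
(`psf_sigma_px`, default 1) is applied before noise (Gaussian SD and/or
Poisson); rendering is deterministic in `seed` and byte-identical across
runs.

TAF panels plant telomere spots (Poisson mean `telomere_per_nucleus_mean`
per myonucleus) and γH2A.X foci (`foci_per_nucleus_distribution`).  A
planted fraction `coloc_fraction` of γH2A.X foci sits on a telomere spot
(jitter ≤ `coloc_jitter_px`, default 1 px); the rest keep > 3 px from
every telomere spot so colocalisation is unambiguous.  Same-channel spots
keep ≥ 5–7 px apart: foci that are counted as distinct must be resolvable
as distinct at the rendered PSF, as in manual counting.  When crowding
makes a placement impossible the focus is dropped, and a proportional
number of foci of the other class is removed so the realised
colocalisation fraction stays binomial around the nominal value (verified
to track the target within ±0.03 in the mean).  In z-stacks, foci are 3-D
Gaussians (σ_z ≈ 0.8 slices) spanning adjacent optical slices, and nuclei
get Gaussian z-profiles.

Brightfield panels (H&E, RNA-ISH with haematoxylin counterstain,
picrosirius red) are rendered as Beer–Lambert absorbance in distinct RGB
stain hues, so colour unmixing can be exercised on known truth.

### What the generator does not emulate

Optical aberrations, uneven illumination, stain batch variation,
longitudinal-section geometry, fibre typing, touching-nucleus clumps of
realistic shape, autofluorescence and tissue folds.  Passing tests
demonstrate the correctness and calibration of the measurement operations
under controlled conditions; they do not certify segmentation performance
on real slides.

## Quantification

* **Nuclear segmentation** — per-image Otsu threshold on DAPI, connected
  components, minimum area 30 px².  QC mirrors the protocol's exclusions:
  *touching* (solidity < 0.9 or ≥ 2 regional maxima > 5 px apart —
  excluded, never split), *blurred* (Laplacian-variance sharpness over
  the padded bounding box, normalised by mean intensity, below 0.4 × the
  image's median component score; the protocol gives no operational blur
  rule, and a pure quantile cut would mechanically exclude a fixed share
  of every image), *edge* (touching the border).  Excluded nuclei stay in
  the record list but leave every denominator.
* **Sarcomeric background** — mean and *population* SD (complete pixel
  set, divide by n) over fibre-interior pixels outside the 2-px-dilated
  nuclear mask, per image ("in the respective image"); at least 100
  eligible pixels required.  The protocol's "total sum of the sarcomeric
  fluorescence intensity" is read as the mean — a literal sum over ~10⁵
  pixels would make the threshold vacuous.
* **HMGB1** — positive iff mean nuclear intensity > background mean +
  2 SD, strictly; a nucleus exactly at the threshold is negative.
* **Lamin B1** — ring = DAPI mask minus its erosion by `depth_px`
  (default 2 px; the protocol does not state the depth); integrated
  density is the plain sum over ring pixels.  The protocol defines the
  measurement but not a positivity cut; the cut used is area-normalised
  density > mean + 2 SD, mirroring the HMGB1 rule for internal
  consistency, and is configurable.  Fully eroded (thin) nuclei fall back
  to the full mask and are flagged.
* **Focus detection** — scale-selective LoG blob detection (2-D or 3-D);
  a candidate survives only if its response in the scale-matched
  Gaussian-smoothed image exceeds `min_prominence` (default 4) robust
  MAD-based noise SDs of that smoothed image.  The matched filter
  concentrates a focus of pre-blur peak SNR 5 to ≈ 10 noise SDs, which is
  what makes ≥ 95 % sensitivity at ≤ 5 % FDR attainable.  Centroids are
  centre-of-mass refined; ordering is deterministic (y, x) / (z, y, x).
* **TAF** — per nucleus, candidate telomere–γH2A.X pairs within
  `coloc_radius_px` in-plane (and ≤ 1 slice in z) are matched greedily,
  closest first, each focus used once; the pair set is symmetric in the
  argument order.  Radius 1.5 px suits ideal (truth-bypass) coordinates;
  the detection-based pipeline uses 2.5 px to absorb two centroid
  localisation errors.  `TAF% γH2A.X` is matched γH2A.X foci as a
  percentage of all γH2A.X foci over analysed myonuclei — the direction
  forced by the reported 33–40 % magnitudes, since TAF-positive nuclei
  are by construction γH2A.X-positive.
* **p16** — foci assigned to nuclei by point-in-mask and fibres by
  point-in-polygon; three percentages with ≥ 2-focus cuts.  Nuclear
  percentage over non-excluded myonuclei within analysed fibres; fibre
  and "any" percentages over analysed (non-edge) fibres, with nuclear and
  extranuclear counts pooled per fibre for "any".  Foci outside every
  fibre are excluded and logged.  Brightfield input is unmixed by
  least-squares colour deconvolution of optical densities into
  haematoxylin and red-chromogen maps before detection.
* **Minimum Feret** — rotating calipers on the convex hull: minimum over
  hull edges of the farthest vertex distance to the edge's supporting
  line.  The independent oracle sweeps caliper width over a 0.01° grid
  and then golden-section-refines within the best grid cell (the width
  function is piecewise-sinusoidal and unimodal there); a bare grid has
  O(step) error at a kink minimum, so refinement is what makes 1e−9
  agreement a meaningful check.  Units are µm when a pixel size is known,
  arbitrary units otherwise.
* **Fibre density** — non-edge fibres divided by analysed tissue area
  (field minus edge-fibre area) in mm².
* **CNF** — a fibre is centrally nucleated iff a contained, non-excluded
  nucleus centroid lies inside the polygon eroded by `margin_fraction`
  (default 0.25) of the equivalent radius; the protocol's centrality call
  was manual, so the margin is a documented operationalisation.
* **Fibrosis** — tissue = pixels below 0.9 × white luminance; within
  tissue, red dominance R − (G+B)/2 thresholded by Otsu (fixed-value
  override available); fibrotic, non-fibrotic tissue and background
  partition the image exactly.
* **Analysed-fibre cap** — sections with more than 300 analysable fibres
  are subsampled uniformly with a seed, mirroring a fixed manual
  outlining quota.

## Statistics

* Quartiles: linear interpolation between order statistics (type 7), the
  default of the mainstream statistics environments this analysis family
  uses; medians and IQRs are reported, so the convention matters.
* Sex comparisons: Pearson chi-squared with Yates continuity correction
  iff the table is 2×2 — the combination that reproduces all five
  published contingency-table p-values to two decimals (0.46, 0.83, 0.35,
  0.87, 0.33, and incidentally 1.00 for the screening-questionnaire
  table).  Wilcoxon rank-sum is exact when both groups have ≤ 25
  observations and no ties (verified against full enumeration for all
  rank configurations with n₁+n₂ ≤ 10), otherwise normal approximation
  with tie and continuity correction.  P-values print as two decimals,
  "< 0.01" below.
* Correlations: Spearman with average ranks and pairwise deletion;
  effect classes per Cohen (|ρ| < 0.1 negligible, < 0.3 small, < 0.5
  medium, ≥ 0.5 large).  Significance is deliberately not asserted for
  correlations — only ρ and its class are emitted.
* Synthetic cohorts: Gaussian copula.  Target Spearman ρ_s converts to
  the latent Pearson correlation r = 2 sin(πρ_s/6); the matrix must be
  positive semi-definite after conversion (nearest-PSD repair by
  eigenvalue clipping is opt-in).  Marginals are fitted from (median, Q1,
  Q3): normal (scale = IQR/1.349) or lognormal (same on the log scale),
  with optional clipping bounds for percentages.  Derived fields —
  probable sarcopenia from the sex-specific grip cut-offs (< 16 kg women,
  < 27 kg men) and BMI category from the < 25 / 25–30 / > 30 bands — are
  computed from the sampled values, never sampled.  The preset marginals
  and correlation targets in `myosen.presets` are parameterised from the
  published per-sex medians/IQRs and reported correlation coefficients;
  unreported pairs default to 0 and the matrix is repaired and, if
  needed, shrunk slightly toward independence to stay PSD.
* Calibration measured by the test suite: type-I error of the sex
  comparison 3.5–6.5 % at n = 24 vs 16 over 2000 null replicates; copula
  recovery of each pairwise target in {−0.7, −0.3, 0, 0.3, 0.7} within
  ±0.03 (mean over 500 cohorts of n = 40).

## Problem sizes

The test suite and acceptance script run on 512² px sections (768² at
0.5 µm/px for TAF, 1024² for the central-nucleation benchmark, 256² for
the 20-section fibrosis sweep and round-trip tests), ~100 analysed fibres
and 150–200 analysed myonuclei per section, 500–900 planted foci per TAF
field, 2000 null replicates for test calibration and 500 cohorts per
copula target — sizes chosen so every benchmark retains its statistical
meaning while a full run stays in the tens of seconds.

## Known limitations

* The watershed fibre extractor is tuned for clean boundary channels; on
  real, broken WGA staining it will merge fibres and should be treated as
  a starting point for manual correction, as in the emulated protocol.
* Touching nuclei are excluded, not split; samples with heavy nuclear
  clumping lose denominators.
* The Lamin B1 positivity cut and the CNF margin are package choices at
  points the emulated protocol left operational details unstated; both
  are configurable and echoed in output provenance.
* Published per-biopsy medians and figure correlations derive from
  unreleased data and are not reproduction targets; the package's claims
  are property-based (exact recovery, calibration, oracle agreement) plus
  the exactly reproducible contingency-table statistics.
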