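# myosen

Quantification of cellular senescence markers and muscle morphology in
transverse cryosections of human skeletal muscle, with a synthetic-section
benchmark and the sex-stratified cohort statistics used in feasibility
studies of muscle ageing.

## What it does

Senescent cells accumulate in ageing tissue, but no single marker
identifies them; muscle studies therefore score a panel of markers per
biopsy and relate them to morphology and physical function.  This package
implements that analysis end to end:

**Per-nucleus / per-fibre senescence scoring**

* *p16 (CDKN2A) RNA-ISH* — chromogenic foci per myofibre, split into
  nuclear and extranuclear, reported as the percentage of nuclei (fibres,
  or either) carrying ≥ 2 foci.
* *TAF (telomere-associated DNA-damage foci)* — γH2A.X foci whose
  centroids colocalise with telomere-FISH spots in the same nucleus under
  one-to-one closest-pairs-first matching; reported as %nuclei with ≥ 2
  (and ≥ 3) TAF and as TAF as a percentage of all γH2A.X foci.
* *HMGB1* — a nucleus is positive iff its mean nuclear intensity exceeds
  the sarcomeric background mean plus twice the background SD
  (strict inequality):  `I̅_nuc > μ_sarc + 2σ_sarc`.
* *Lamin B1* — integrated density over the peripheral nuclear ring
  (DAPI mask minus its erosion), with the same `μ + 2σ` positivity rule on
  the area-normalised density.

**Morphometry** — minimum Feret diameter by rotating calipers on the
convex hull (cross-checked against a dense angle-sweep oracle), fibre
number per mm², centrally nucleated fibres (nucleus centroid inside the
polygon eroded by 0.25 of the equivalent radius), and picrosirius-red
fibrotic area fraction by red-dominance thresholding.

**Cohort statistics** — median/IQR descriptives, sex comparisons
(chi-squared with Yates correction on 2×2 tables only; Wilcoxon rank-sum,
exact when both groups have ≤ 25 observations and no ties), Spearman rank
correlations with Cohen's effect-size benchmarks (|ρ| ≥ 0.1 / 0.3 / 0.5 =
small / medium / large), correlation heatmaps, and a Gaussian-copula
generator that draws synthetic cohorts with specified marginals
(median, Q1, Q3, family) and Spearman correlation structure.

Because biopsy image data of this kind are typically available only on
request, the package includes a first-class synthetic-section generator
(`myosen.synthetic`): a jittered-hexagonal Voronoi tessellation of
myofibres with a WGA boundary band, peripheral/central/interstitial
nuclei, planted foci with a controlled colocalisation fraction, nucleus
intensity classes over sarcomeric background, fibrotic interstitium and
brightfield (H&E, RNA-ISH, picrosirius red) renderings — all with
complete ground truth, so every quantification stage is scored against a
known answer.

## Worked example

```python
from myosen import SectionSpec, generate_section
from myosen.segmentation import (build_nuclear_mask, classify_myonuclei,
                                 sarcomeric_background)
from myosen.senescence import classify_hmgb1, pct_positive
from myosen.pipeline import fibres_from_truth
from myosen.cohort import chi2_test, spearman

# synthetic HMGB1 section: 26% of nuclei planted positive at 6-SD contrast
spec = SectionSpec(seed=42, marker_panel="HMGB1", positive_fraction=0.26)
image, truth = generate_section(spec)

nuclei = build_nuclear_mask(image.channel("DAPI"))
fibres = fibres_from_truth(truth)           # manual-outline stand-in
classify_myonuclei(nuclei, fibres)
bg = sarcomeric_background(image.channel("HMGB1"), nuclei,
                           truth.fibre_labels, channel_name="HMGB1")
classify_hmgb1(nuclei, image.channel("HMGB1"), bg)

print(f"sarcomeric background: mean={bg.mean:.1f}, SD={bg.sd:.1f} "
      f"(threshold {bg.mean + 2*bg.sd:.1f})")
print(f"%HMGB1+ = {pct_positive(nuclei, 'hmgb1_positive'):.1f}% "
      f"(planted: {truth.per_sample_truth.pct_hmgb1_pos:.1f}%)")

smoking = [[14, 10, 0], [9, 6, 1]]   # men vs women: never/previous/current
chi2, p, dof = chi2_test(smoking)
print(f"smoking chi2={chi2:.3f}, p={p:.2f}")

r = spearman([69, 61, 75, 58, 52, 63], [38, 44, 33, 49, 45, 40],
             "age", "grip", "M")
print(f"Spearman rho(age, grip) = {r.rho:.2f} ({r.effect_class})")
```

Output:

```
sarcomeric background: mean=487.3, SD=38.7 (threshold 564.7)
%HMGB1+ = 21.5% (planted: 21.2%)
smoking chi2=1.549, p=0.46
Spearman rho(age, grip) = -0.94 (large)
```

The measured HMGB1 percentage (21.5%) sits next to the planted 21.2%: the
detected-nucleus path and the ground-truth bookkeeping use slightly
different denominators (segmentation QC versus planted lists), which is
the point of the benchmark.  The chi-squared p of 0.46 is the published
men-versus-women smoking comparison recomputed from its printed counts.

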