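# Methods

This note documents the models, algorithms and numerical choices behind
`fibertension`: a pipeline that quantifies the tensional state of fibronectin
fibers in multiplexed immunofluorescence images of breast tissue and relates
untensed-fiber regions to collagen organization and cell phenotypes.

## Background and measurement model

Fibronectin (FN) fibers in tissue are held under cell-generated tension.
The bacterial-adhesin-derived peptide probe FnBPA5 binds FN's N-terminal
type-I modules with nanomolar affinity only while the fiber is relaxed;
stretching destroys its multivalent binding motif. Co-staining a cryosection
with a Cy5-labelled FnBPA5 probe and a polyclonal FN antibody (which reports
all fibers regardless of tension) therefore yields a per-pixel tension
read-out: the fraction of FN-positive pixels that are also FnBPA5-positive
summarizes how much of the fiber network has lost tension. Tenascin-C (TNC)
marks fibrotic remodeling, second-harmonic generation (SHG) reports fibrillar
collagen label-free, and nuclear/membrane markers (DAPI, panCK, GATA3, Ki67,
α-SMA, CD34, CD8, CD45, CD4, FoxP3) support cell phenotyping.

## Pixel quantification

* **Thresholding.** Positivity is strict (`intensity > threshold`). The
  default policy is Otsu's method computed per channel and per field over a
  fixed 256-bin histogram of in-region intensities, regardless of bit depth;
  ties break toward the smallest maximizing threshold. Per-field (rather than
  per-slide) thresholds were chosen because fields are acquired independently;
  a fixed-threshold policy is available as an override.
* **Pixel ratio** (FnBPA5 relative to FN) is
  `100 · |FnBPA5⁺ ∩ FN⁺| / |FN⁺|`. The intersection excludes FnBPA5⁺ pixels
  that fall off FN⁺ pixels (noise), since the quantity is defined relative to
  the reference stain. **Pixel density** (TNC, CD34, FN) is relative to the
  analysis-region area instead.
* **Ratiometric tension maps** divide FnBPA5 by FN intensity on the joint
  mask where both channels pass threshold; values are undefined (NaN), not
  zero, elsewhere. Ratios are relative (a.u.): two fluorophores do not allow
  absolute molecular ratios.
* An optional **linear pixel classifier** (least-squares weights over
  multi-scale Gaussian-smoothed intensity and gradient-magnitude features,
  score cut at 0.5) stands in for interactively trained pixel classification
  when manual annotations exist. A linear-probability model places its 0.5
  crossing at the class boundary only when the two intensity classes are
  well separated (bimodal), which is the regime stained-tissue channels
  occupy; it is not a general-purpose segmenter.

## Fiber orientation and coherency

* **Frangi vesselness** scores bright curvilinear ridges from the Hessian
  eigenvalues |λ₁| ≤ |λ₂| per scale σ ∈ {1, 2, 3, 4} px:
  `exp(−(λ₁/λ₂)²/(2β²)) · (1 − exp(−(λ₁²+λ₂²)/(2c²)))` where λ₂ < 0, else 0,
  maximized over scales, with β = 0.5 and c defaulting to half the maximum
  Hessian norm over the image. Gaussian derivatives use nearest-neighbor
  boundary handling (zero padding would manufacture border ridges on any
  non-zero background), and eigenvalues below 10⁻¹² of the image magnitude
  are treated as zero so a flat image scores exactly 0.
* **Structure tensor.** Gradients by centered differences; tensor components
  windowed with a Gaussian of σ = 4 px (the window of the original
  orientation tool is not published; 4 px matches the fiber widths drawn by
  the generator). Orientation θ ∈ [0°, 180°) is the fiber (minor-eigenvector)
  direction, 0° along image rows measured toward columns, so vertical fibers
  map to 90°. Coherency C = (λmax − λmin)/(λmax + λmin) ∈ [0, 1], defined as 0
  where the tensor trace vanishes.
* **Mean coherency** is averaged over fiber pixels — the default fiber mask
  is `vesselness > Otsu(vesselness)` — so the statistic describes collagen
  fibers, not background. A whole-image average remains available by passing
  an all-true mask.

## Cell detection and phenotyping

Nuclei are detected from DAPI: Gaussian smoothing (σ = 1 px), Otsu
foreground, then a watershed split on the smoothed distance transform with
markers at local maxima separated by at least twice the minimum nucleus
radius; components outside [12, 400] µm² are discarded. Centroids and areas
are reported in µm via the isotropic pixel size. Marker intensities are
averaged over the nucleus plus a 1.5 µm expansion ring (configurable),
with contested ring pixels assigned to the nearest nucleus. Composite
phenotypes (e.g. Ki67⁺ & panCK⁺ carcinoma cells, CD4⁺ & FoxP3⁺ Tregs) are
conjunctions of per-marker thresholds; thresholds default to Otsu over the
per-cell mean-intensity distribution, with a minimum-contrast guard (50 a.u.
between the two classes) so a marker with no positive cells is not split
mid-noise. Percentages are normalized to the total DAPI-detected cell count.

## Proximity statistics

Distances use the exact Euclidean distance transform of the positive-pixel
mask complement, scaled to µm, sampled at the pixel containing the nucleus
centroid (a centroid on a positive pixel scores exactly 0; this matches a
brute-force nearest-positive-pixel search at pixel resolution). Profiles bin
flagged-cell distances into half-open 1 µm intervals up to 20 µm plus an
explicit overflow bin; fractions are percentages of the flagged-cell count
and sum to 100. The within-radius summary uses an inclusive 10 µm boundary.
The two-stage statistic selects cells within 10 µm of the FnBPA5 mask and
reports their mean distance to the CD34 (vessel) mask, separating
vessel-lining smooth-muscle cells from CAFs.

## Cohort statistics

One value per patient enters every test (a patient's fields are averaged
first; fields are never treated as independent samples). Normality is
assessed by four tests — D'Agostino-Pearson (n ≥ 8), Anderson-Darling,
Shapiro-Wilk, and Lilliefors' Kolmogorov-Smirnov — at α = 0.05; a sample is
parametric iff at least three fail to reject. Samples too small for three
tests to apply are treated as nonparametric; this reproduces the convention
that tiny groups are compared by rank tests. Two parametric groups get a
two-tailed unpaired t test (Welch by default, pooled switchable); two
nonparametric groups get the Mann-Whitney test (asymptotic, two-sided,
without continuity correction so that perfectly tied identical samples give
p = 1); three or more groups get one-way ANOVA with Tukey's HSD or
Kruskal-Wallis with Dunn's rank-based post-hoc under Bonferroni adjustment
(the most conservative of the common choices). Proximity profiles are
compared by a two-way ANOVA over group × distance-bin with Tukey's HSD on
group marginal means; declining profiles by a linear-contrast test for trend
(centered bin ranks as coefficients, contrast F on (1, df_error)); and
pixel-fraction co-occurrence by Pearson's r with the two-sided t-transform
p-value.

## Synthetic tissue generator

No patient images are distributed with the study, so the generator emulates
the statistical structure the analysis assumes, with exhaustive ground truth
captured *before* the point-spread blur and noise are applied:

* **Fibers** are smooth curves 2–6 px wide. The healthy preset draws
  sinusoidal undulations (amplitude 5 µm, wavelength 30 µm) with orientations
  uniform in [0°, 180°); invasive presets draw near-straight curves
  concentrated about a random common axis (axial von Mises, κ = 20). A
  contiguous subset of fibers (plus one partial fiber) is copied into the
  FnBPA5 channel until the target fraction of FN⁺ pixels is met: 0.08
  (healthy, DCIS), 0.35 (invasive grade 2), 0.45 (grade 3) — the healthy and
  tumor anchors follow the reported ≈8% vs ≈40% contrast, with the grade
  split chosen so grade 3 clearly exceeds grade 2. TNC is a 3 px dilated halo
  around FnBPA5⁺ fibers plus sparse background (this coupling produces the
  positive FnBPA5–TNC correlation across samples); SHG mirrors fiber
  geometry. Halo width and fiber widths are free parameters of the generator
  (no published values exist) and are surfaced in `truth_meta.json`.
* **Cells** are non-overlapping ellipses (area ≈ π r², r = 3.0–4.0 µm by
  preset, grade 3 largest, ±15% jitter). Phenotypes draw from a preset mix;
  coupled phenotypes (cancer cells, epithelial cells, CAFs and T cells in
  invasive presets) are placed so their centroid distance to the nearest true
  FnBPA5⁺ pixel follows an exponential law with scale 4 µm, implemented by
  rejection sampling on the FnBPA5 distance transform. An overlap rejection
  retries the *same* target distance at other candidate pixels before a new
  distance is drawn — otherwise local crowding near fibers would bias the
  distance law outward. CAFs additionally reject positions within 25 µm of
  CD34⁺ vessel tracks; healthy/DCIS presets arrange epithelial cells inside
  myoepithelial (α-SMA⁺) duct/lobule rings placed near untensed-fiber
  patches, with a vessel track adjacent to each healthy ring. This
  construction makes the two-stage statistic discriminate by design:
  α-SMA⁺ cells near untensed fibers sit close to vessels in healthy tissue
  and far from them in invasive tissue.
* **Rendering.** Signal amplitudes are drawn from U(150, 220) a.u. over a
  background of 10 a.u.; channels are blurred with a Gaussian PSF (σ =
  0.7 px) and receive Poisson shot noise plus Gaussian read noise (σ = 3).
  This reflects the high signal-to-noise of confocal imaging of bright
  stains.
* **Scale.** The reference frame is 1024 × 1024 px at 0.5 µm/px
  (512 × 512 µm, desk-scale); preset fiber and cell counts refer to that
  frame and scale with frame size. Cell counts (450–800 per frame by preset)
  and the phenotype mixes are generator choices anchored to the reported
  cohort patterns (e.g. ≈1.3% Ki67⁺&panCK⁺ and ≈5% GATA3⁺&panCK⁺ in healthy
  tissue, ≈45–50% GATA3⁺&panCK⁺ in neoplastic tissue, α-SMA⁺ percentage
  higher in healthy than invasive), not claims about patient values.
* **Determinism.** One NumPy `default_rng` stream per sample, seeded
  explicitly; every stochastic step draws from it in documented order, so
  regeneration with the same preset and seed is bit-identical.

### What the generator does not emulate

Real cryosections have spatially varying autofluorescence, spectral
bleed-through, tissue folds and detachment artifacts, touching and
overlapping nuclei, partial-volume effects, and biological correlation
structure far richer than an exponential placement law. Passing the
recovery tests therefore demonstrates that the *algorithms* are correct and
unbiased under the stated imaging model — not that the pipeline is validated
on clinical material. The per-field Otsu policy in particular would need
revisiting on images with strong shading.

## Verification strategy

* Pixel primitives (Otsu, ratio/density counting, distance transform) are
  checked for exact agreement against brute-force oracles on seeded random
  instances; near-ties in the Otsu objective are compared by attained
  between-class variance, since two algebraically equal formulations can
  differ by one ULP.
* Fiber operators are checked against closed-form limits: stripe patterns
  (coherency ≥ 0.95, orientation 90°), isotropic noise (coherency ≤ 0.2),
  30° rotation equivariance within ±2°, zero response on constant images,
  and ridge-centerline dominance ≥ 5× background.
* Parameter recovery runs the full pipeline on cohorts of seeds 0–9 at the
  reference frame and compares against generator truth: the FnBPA5 pixel
  ratio and phenotype percentages recover within ±5 percentage points per
  sample, nucleus detection precision and recall reach ≥ 0.95, and the
  coupled-placement law matches the exponential CDF within 3 binomial σ at
  n = 1000 cells.
* Inference recovery verifies that the healthy-vs-invasive comparison is
  significant at p < 0.01 under the gated test, the FnBPA5–TNC correlation is
  positive, the trend test rejects on a declining profile, and both the
  trend test and the full gated two-group procedure control type-I error
  near the nominal 0.05 over 1000 null replicates.
* Determinism is asserted byte-for-byte on repeated cohort runs.

## Known limitations

* The pixel classifier is linear and intended for separable (bimodal)
  channels only.
* Proximity distances are sampled at the centroid's containing pixel rather
  than interpolated; the discretization error is bounded by one pixel.
* Coherency windows and Frangi scales are tuned to fibers a few pixels wide;
  images at very different magnifications need rescaled parameters.
* The two-way profile ANOVA treats per-sample bin fractions as homoscedastic
  across bins, which is approximate for percentages near 0 or 100.
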