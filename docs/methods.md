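# Methods

## The quantity being measured

The TIL proportion of a tumor section is

π = 100 · L / (C + L + S)

where C, L, S are the counts of cancer cells, lymphocytes and stromal
cells detected on the section. Counts are summed over all tiles of the
section before dividing (not averaged per tile), so π is exactly
"lymphocyte count over total cell count". For survival analysis a cohort
is dichotomised at the sample median of π (midpoint convention for even
n; values equal to the cutoff go to the low group).

## Image pipeline

**Grayscale.** Each RGB tile is converted to CIELAB (D65). Two
nucleus-signal channels are derived:

* a *slide-normalised* channel for thresholding — lightness standardised
  by its per-channel mean/SD, negated (haematoxylin-dark nuclei score
  high), min–max rescaled to [0, 1];
* an *absolute* channel for per-cell intensity features — (100 − L*)/100.

The split matters: thresholding only needs the within-slide ranking, but
intensity features must be comparable across sections. A min–max-anchored
scale stretches the darkest nuclei of any section to full signal, so on a
section with no truly basophilic nuclei the darkest cancer nuclei would
imitate lymphocytes. Anchoring features to the lightness axis removes
that composition dependence.

**Otsu threshold.** 256 equal right-open bins over [min, max];
the threshold is the bin boundary maximising the between-class variance
σ²_B(t) = w₀w₁(μ₀ − μ₁)²; ties break to the lowest boundary. A constant
image raises a degenerate-image error. The implementation is checked
against an exhaustive scan that evaluates σ²_B directly at every
boundary, and against scikit-image's estimator on bimodal data.

**Opening and watershed.** The foreground mask (gray > t*) is opened
with a disk (radius 1 px by default), removing single-pixel speckle.
Touching nuclei are split by watershed on the negated Euclidean distance
transform; seeds are the h-maxima (h = 2 px) of the distance transform
*after* Gaussian smoothing with σ = 1 px. The smoothing is load-bearing:
the radially perturbed boundaries of cancer-like nuclei put several
spurious maxima inside one nucleus, and raw-EDT seeding over-segments
(~12% spurious objects on the 200-nucleus benchmark). Components the
seeds do not reach are labelled as a fallback, so small low-prominence
nuclei are never lost. Regions under 9 px are discarded (sub-lymphocyte
debris at this pixel scale); labels are renumbered contiguously.

**Tiling.** Whole sections are processed as a row-major 10×10 grid
(floor-divided tile sizes; remainder pixels appended to the last
row/column), with two practical amendments. First, the grayscale and the
Otsu threshold are computed once per section: a background-only tile has
no bimodal histogram, and a per-tile threshold would slice noise into
foreground. Second, the grid is clamped so no tile falls under 100 px per
side — tiling exists for memory efficiency on large sections, and tiles
comparable in size to a nucleus would put most nuclei on a seam. Nuclei
straddling a seam yield one fragment per tile; when two fragments touch
across the seam (within a 3-px band, since the opening erodes tile
edges), the smaller fragment is suppressed and the larger keeps the
label. At IoU ≥ 0.5 the retained larger fragment still matches its
nucleus, which is what keeps object-level precision/recall ≥ 0.95.

Segmentation contains no randomness; identical input gives an identical
label map.

## Features (43, fixed order, registry version 1.0)

| group | count | members |
|---|---|---|
| shape | 12 | area, Crofton perimeter, major/minor axis, eccentricity, solidity, extent, circularity, convex area, orientation, equivalent diameter, boundary roughness |
| intensity | 12 | mean, SD, min, max, median, MAD, skewness, kurtosis, q10, q90, integrated intensity, contrast vs. a 2-px dilated ring |
| texture | 13 | GLCM (32 grey levels, distance 1, four directions averaged, symmetric): contrast, dissimilarity, homogeneity, energy, correlation, ASM, entropy, max probability, cluster shade, cluster prominence, sum average, sum variance, difference variance |
| neighbourhood | 3 | neighbour count within 50 px, nearest-neighbour distance, inverse mean 3-NN distance |
| gradient | 3 | mean/SD/max Sobel gradient magnitude on the region boundary |

Texture patches are the region bounding box with background masked to
the region median. The Crofton perimeter estimator is validated against
a polygon-boundary oracle with a 10% tolerance. All 43 features are
invariant to translation, and all but orientation to 90° rotation.
Solidity of small rasterised disks is ≈0.93, not 1: the pixelated convex
hull overshoots the disk; this is a property of the estimator, not a
defect.

## Classifier

RBF-kernel SVM (C = 1, γ = 1/43) over features standardised with
training-set statistics, one classifier per cancer type. Training sets
are built the way they are in practice: the segmentation circles cells,
an annotator labels the circled cells, and the features of the *circled*
regions become the records. In the synthetic setting the generator's
ground truth plays the annotator (nearest true centroid within 6 px).
Training on idealised true masks instead creates a train/test
distribution shift (watershed artefacts, seam fragments) that costs
~15 points of per-cell accuracy.

Validation: stratified 10-fold cross-validation (folds assigned after a
canonical lexicographic ordering of records, so accuracy depends only on
the record multiset); Pearson concordance of per-sample class proportions
with manual counts (switchable to Spearman); and a Jonckheere–Terpstra
test of TIL proportion across ordered manual grades.

**Jonckheere–Terpstra.** JT = Σ_{i<j} U_ij over ordered group pairs
(ties count ½). For pooled n ≤ 12 the p-value is exact by full
enumeration of group assignments; otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction (JT moves in
half-integer steps). Without the correction the approximation misses the
exact p by up to 0.04 at n = 12; with it, ≤ 0.02. Two-sided by default.
Kruskal–Wallis similarly switches to an exact enumeration below pooled
n = 12, where the χ² approximation is unreliable.

## Cohort statistics and survival

Rank tests, chi-square and Spearman are scipy-backed with fixed
conventions: tie-corrected H with χ²(g−1) p; rank-sum exact for the
smaller sample ≤ 8 without ties; Pearson chi-square without Yates
correction; Bonferroni as min(1, m·p). The linear model is OLS with
dummy coding against stated reference levels, complete-case rows, normal
95% CIs (B ± 1.96·SE), and standardised coefficients
Beta = B·SD(x)/SD(y).

Survival uses lifelines: product-limit Kaplan–Meier (median = earliest t
with S(t) ≤ 0.5), the standard log-rank χ² with df = groups − 1, and Cox
partial likelihood with Efron ties and Wald CIs exp(β ± 1.96·SE). TIL %
enters untransformed, so its HR is per percentage point. Monotone
likelihood (perfect separation) raises a convergence error rather than
returning a silent non-converged fit.

## Synthetic data: what it emulates, what it does not

**Slides.** Eosin-pink background (RGB ≈ (235, 200, 215)) with mottle;
haematoxylin-dark nuclei of three morphologies — cancer: radius 8–16 px
with 4-harmonic radial boundary noise and strong chromatin speckle
(SD 28); lymphocyte: radius 3–5 px, near-circular, darkest palette;
stroma: ellipse with axis ratio 3–5. Placement is rejection sampling
(cap 1000 tries/nucleus, then a placement error) with a configurable
fraction deliberately placed touching a neighbour to exercise watershed
splitting. Global Gaussian blur (σ = 1 px) and additive noise (SD 3)
finish the render. Geometry is calibrated in pixels, not µm, since the
magnification-to-pixel scale of real sections is scanner-dependent.

Not emulated: staining variability between labs, tissue folds, necrosis,
out-of-focus regions, overlapping nuclei in 3D, mitotic figures, and the
long-tailed cellularity of real sections. Passing the synthetic
benchmark therefore demonstrates the pipeline's internal consistency —
segmentation, features, classifier and statistics compose correctly and
recover known truth — not clinical-grade accuracy on real H&E material.
The per-cancer "cytomorphology presets" only reseed the generator; real
cancer-type differences are larger and systematic.

**Cohorts.** TIL % is log-normal (default median 3%, σ_log = 1),
matching the heavy right skew of real TIL distributions; covariates are
Bernoulli(½); survival is exponential with hazard
h·exp(β_til·TIL% + Σβ_c·x_c) and independent exponential censoring
(defaults h = 0.15/yr, c = 0.10/yr → ≈ 2/3 events), optional
administrative cutoff. The default β_til = ln(0.965) per TIL point, the
effect size at which hazard-ratio recovery is demonstrated.

## Problem sizes and tolerances

The benchmark slide is 1000×1000 px with 200 nuclei; training sets use
60–80 cells per class; Cox recovery pools 50 replicates of n = 2000;
trend-test calibration uses 1000 null replicates of 3×25 observations.
These sizes make the full suite run in about two minutes on one CPU
while leaving Monte-Carlo error well inside the asserted bands
(segmentation precision/recall ≥ 0.95, per-cell accuracy ≥ 95%,
|π̂ − π| ≤ 2 points, pooled HR in [0.96, 0.97], type-I error 5% ± 2
points). Newton/partial-likelihood tolerances are lifelines defaults;
OLS is checked against the normal equations at 1e-8.

## Known limitations

* The 43-feature registry is a documented, versioned set; external
  training tables with different feature definitions can be ingested via
  the column-mapping shim but are only meaningful if their features
  measure the same quantities.
* Fragment suppression at tile seams discards the smaller fragment's
  area, slightly biasing per-nucleus shape features near seams; the
  minimum tile size keeps the affected fraction small.
* The median-split convention (ties to low) and the exact-test size
  cutoffs (n ≤ 12) are conventions, stated here so results are
  reproducible, not claims of optimality.
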