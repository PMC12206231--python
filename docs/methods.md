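# Methods

## Coordinate and tiling conventions

Slides live in 0-based pixel coordinates at working magnification
(default 0.5 µm/px ≙ ×20; the magnification is the primary statement,
the µm/px value is a configurable convention). Patches are half-open
256×256 px rectangles on a row-major grid; partial patches on the
right/bottom margins are dropped, so tiling is an exact partition of
the floor-aligned area and every cell centroid inside that area belongs
to exactly one patch. A patch is retained when its area-weighted tissue
fraction is **≥ 0.5** — "less than 50% tissue discarded" implies a
strict-less discard, so the boundary case is kept. Region masks are
binary grids at an integer downsample (default 8); patch/mask overlap is
computed area-weighted at the mask resolution, never by resampling
images.

## Spatial statistics

**ANNR.** For the cells of one type in a patch, the observed mean
nearest-neighbor distance is divided by the expectation under complete
spatial randomness, `D̄_E = 0.5/√(n/A)` with `A` the full patch area
(256² px²). No edge-effect correction is applied — the ratio is the
plain Clark–Evans form. Consequences worth knowing:

* under CSR the uncorrected estimator is biased slightly upward
  (unobserved neighbors outside the window): at n ≈ 100 in a 256² patch
  the mean ANNR is ≈ 1.04, which is why the CSR calibration band is
  [0.95, 1.05] rather than symmetric around 1;
* when a type's cells occupy only part of a patch (e.g. a tumor border),
  `A` overstates their available area and the ANNR drops — a real
  property of the protocol, not an artifact of this implementation.
* fewer than two cells leave the ratio missing.

**Join counts.** The patch is tessellated by the Voronoi diagram of all
nuclei centroids; two cells are neighbors iff their regions share a
boundary, computed as the Delaunay dual with no edge-length cutoff and
no clipping of infinite regions. For each focal type, cells are labeled
black/white and the BB/BW/WW joins counted over the edges;
autocorrelation is `(J_BB − J_BW)/J_T`. Degenerate inputs: coincident
duplicate points are merged onto their first occurrence (logged);
fully collinear configurations get a fixed-seed 1e-6 px jitter
(logged); a patch with no joins yields a missing autocorrelation, and
all-coincident points are a degenerate-input error.

**Cross-type distances** are symmetric nearest-cross-neighbor
distances (a→nearest b pooled with b→nearest a). All-pairs distances
were rejected: they grow quadratically and make the median depend on
patch occupancy rather than spacing.

**Descriptive statistics** are population-moment conventions: variance
with ddof 0, biased skewness, biased *excess* kurtosis. Fewer than 2
values → variance missing; fewer than 3 values or zero variance →
skewness/kurtosis missing.

## The 524-entry feature vector

The featurizer always emits exactly 524 named entries in a frozen
order, generated by `slidescape.manifest` (code, not a data file, so
the names cannot drift from the implementation;
`write_manifest_yaml` exports it). The core categories — composition
(13), per-type morphology 6×4×7 (168), cross-type distances 15×7
(105), per-type NN distances 6×7 (42), ANNR (6), join autocorrelation
(6), join fractions (18), in-tumor fractions (6) — account for 364
entries. **The remaining 160 are documented extras of the same
families** (ordered count ratios, pooled all-cell variants, Delaunay
degree summaries, densities per mm², in-tumor counts and area, distance
quartiles): the original per-feature listing is not available in full,
so the enumeration beyond the stated categories is this package's own
reconstruction, fixed here once and flagged as such. Missing values are
emitted as NaN and never imputed at featurization time: comparisons
drop them per feature and the tree classifier routes them natively.

## Attribution and selection

Integrated gradients uses a midpoint Riemann sum (default 64 steps;
512 in the completeness checks) along the straight path from the
baseline (default zero vector). Gradients come from an analytic
callable when supplied, otherwise central finite differences (exact
for polynomials up to degree 2). The completeness gap
`|Σ attr − (f(x) − f(baseline))|` is reported with every result.

Selection operates on **raw** scores — slide min-max normalization
(constant maps → 0.5) is display-only. Candidates are tissue-retained
patches whose center lies in the tumor ∪ stripe region and whose score
toward the slide's true class is positive; the top
`ceil(0.10 · candidates)` are kept, truncated to 200 per slide, ties
broken by (row, col) for determinism. Two deliberate interpretations
of the protocol: the 10% is taken over region-restricted candidates
(the region restriction precedes the analysis), and all slides
participate in group formation regardless of the classifier's verdict
(an option on `form_groups` excludes misclassified slides given a
prediction table). The stripe is a Euclidean-disk dilation of the
tumor mask by `round(stripe_µm/(mpp·downsample))` cells, implemented
via the exact Euclidean distance transform (identical to a disk
structuring element, O(grid) cost). Patient-level scores aggregate as
the maximum over the patient's slides.

## Comparison

CLES is computed by exhaustive pairwise comparison with 0.5 credit for
ties; the tie convention preserves `cles(x,y) + cles(y,x) = 1` and the
exact identity with the Mann–Whitney U (`U = CLES·|x|·|y|`) and with
the rank-statistic AUROC. Reported CLES is oriented toward the
larger-mean group. The U test is exact (enumeration) when
`|x|·|y| ≤ 400` without ties, else the normal approximation with tie
and continuity corrections; fully tied inputs return p = 1 with a
warning. Raw p-values are reported for protocol fidelity;
Benjamini–Hochberg adjusted values are added because 524 simultaneous
tests demand them. "Effect size bigger than random" is operationalized
as `|CLES − 0.5| > 0.05` (configurable); the threshold is a convention.
Patches within a slide are correlated but treated as independent units,
as in the source protocol — p-values are therefore optimistic, a known
limitation.

## Classification

XGBoost (`hist`, single-thread for determinism) over a small frozen
grid (depth {3,5} × learning rate {0.1,0.3} × 100 trees), selected by
mean 3-fold cross-validated AUROC with folds stratified by class and
grouped by patient; degenerate single-class folds trigger a reshuffle
with a warning. The 80–20 split is likewise patient-grouped and
class-stratified — stricter than a plain patch split, which would leak
slide-correlated patches across the boundary (`group_by_patient=False`
restores the literal behavior). AUROC uses the rank statistic; its 95%
CI is a class-stratified percentile bootstrap (2000 resamples by
default), widened if needed to cover the point estimate. The Youden
threshold maximizes sensitivity + specificity − 1 over midpoints of
consecutive unique scores, returning the lowest maximizer.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the statistical structure the analysis
assumes, at desk scale. Default geometry is 2048×2048 px per slide
(8×8 patches) — far smaller than a clinical WSI but large enough for a
tumor with a distinct interior and border; cohort sizes in tests are
20–80 slides. Per slide: an elliptical tissue region (~70% of the
slide); one smooth tumor blob constrained to 20–60% of the tissue;
tumor cells from a Thomas cluster process (5 parents per 256² patch of
tumor area; offspring σ 45 px progressors / 46 px non-progressors;
within-tumor density 120 cells/patch); background types by homogeneous
Poisson over the tissue (stroma 40, lymphocyte 25, epithelial 20,
granulocyte 8, plasma 8 per patch), thinned to 40% inside the tumor
(tumor nests displace surrounding tissue — without this, interior
patches are so diluted that BB joins cannot dominate and the join-count
contrast inverts); intermixing flips tumor-process cells inside the
mask to a random other type with probability 0.32 (progressors) vs
0.06 (non-progressors). Morphology is Gamma (area) / Beta (shape
measures) per type — supports on the right ranges; the families are
conventions since no distributions are published. Attribution is a
step-plus-noise surrogate (bonus 1.0, Gaussian noise σ 0.6) focused on
the eroded tumor interior (non-progressors) or the border stripe
(progressors); stripe width 128 µm at this slide scale.

Effect sizes are conventions: the published group contrasts are given
only as figure-level effect sizes, so the defaults were calibrated once
so that the patch-level CLES on tumor-cell ANNR between selected groups
is ≈ 0.6–0.7 and all four headline contrasts (ANNR, join-count
autocorrelation, nuclear area higher in non-progressors; eccentricity
higher in progressors) recover at p < 0.01 on 40 slides/arm. Most of
the ANNR separation comes from the *location* structure — border
patches of progressors contain partial cluster spills confined to a
fraction of the patch area — rather than from the small σ contrast;
this mirrors how the real analysis couples attribution location with
spatial statistics.

The generator does **not** render pixel data, simulate staining or
scanner variation, cross-center domain shift, multi-scale tumor
architecture (nests, keratin pearls), or cell-shape/orientation
coupling. Passing tests therefore demonstrate that the *pipeline*
recovers known structure from nuclei records — not that the biological
findings would replicate on real tissue.

## Determinism

Every stochastic component takes an explicit seed; cohort generation
spawns per-slide streams with `numpy.random.SeedSequence`, so output
files are byte-identical across runs for a fixed (seed, config).
XGBoost runs single-threaded with a fixed `random_state`. The pipeline
writes its resolved configuration and package version beside all
artifacts.
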