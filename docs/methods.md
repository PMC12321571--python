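# Methods

This note documents the models and procedures implemented in `arcquant`,
the assumptions behind them, the defaults chosen where a choice was open,
and what the synthetic benchmarks do and do not demonstrate.

## Pixel-percentage smFISH quantification

Multiplexed smFISH probe channels are quantified per cell, not per spot:
a cell's expression of gene *g* is the percentage of its ROI pixels that
carry probe signal after thresholding. This is appropriate when probe
density saturates individual nuclei (dense perinatal tissue) and absolute
spot counts are unreliable.

**Rényi-entropy threshold.** For a 256-bin intensity histogram with
normalised bin masses `p_i`, a candidate threshold `t` splits the histogram
into `[0, t]` and `(t, 255]`; each side is renormalised and its Rényi
entropy of order α taken,

    H_α = log(Σ q_i^α) / (1 − α),      H_1 = −Σ q_i log q_i  (Shannon limit),

and the per-α threshold maximises the sum of the two entropies (first
maximiser on ties, candidates restricted to splits with mass on both
sides). The default `alpha_set = (0.5, 1, 2)` follows the widely
distributed automatic-threshold dialect, which combines the three
candidates by an ordering-and-weighting rule: candidates are sorted,
weighted (1, 2, 1) when they agree within 5 bins of each other (or all
disagree) and (0, 1, 3) / (3, 1, 0) when only the upper / lower pair
agrees, then blended with the cumulative masses at the extreme candidates.
Implementation details that matter:

- Float images are binned to 256 equal-width levels between the image min
  and max; the returned threshold is the midpoint between the largest
  sub-threshold and smallest supra-threshold pixel value, so "strictly
  above threshold" coincides exactly with "in a foreground bin" and the
  foreground mask is invariant to adding a constant to the image.
- A constant image has no separable classes and raises; inside the matrix
  builder a constant (signal-free) channel is instead treated as
  all-background, since an empty channel is an expected outcome there.
- Foreground components smaller than `min_object_px` pixels
  (8-connectivity) are removed. This replaces manual speck curation with a
  reproducible rule; `min_object_px = 0` disables it.

**Median zeroing.** Per gene, the median is computed over all cells of the
dataset (zeros included, images pooled — a per-image option exists);
entries at or below the median are set to 0, strictly greater entries are
kept. Ties at the median are zeroed. The operation is a single pass:
re-applying it would recompute medians on the zeroed matrix and zero
further entries, which is deliberately not done.

**Clustering.** The standard single-cell workflow is applied to the
median-zeroed matrix via scanpy: `log(1 + x)` on the 0–100 percent scale
(no additional scale factor — the values are already normalised per-cell
fractions), per-gene standardisation (zero-variance genes map to 0), PCA
retaining *all* available components (`min(n_cells − 1, n_genes)`), a kNN
graph (default `k = 20`), Leiden at resolution 1.0 and UMAP, all seeded.
`k` and the resolution are configuration with stated defaults; the planted
benchmark is insensitive to over-clustering because subtype assignment
operates per cluster.

**Subtype assignment.** Expression is z-scored per gene across all cells;
a cluster's score for a subtype is the mean z-score of the subtype's
required markers over the cluster's cells. The best subtype is assigned
when it beats the runner-up by `margin` (default 0.1 z-units), otherwise
the cluster is `unassigned`. The default rules are the six inhibitory
subtypes plus the SATB2⁺ excitatory type listed in the README.

## Neighborhood interaction analysis

Within one image, cells are nodes; an undirected edge joins two cells with
centroid distance **strictly** below the threshold (default 4 px; a pair
at exactly 4.0 px is not joined). Distances are raw pixel units on
centroids; no physical-unit conversion.

The interaction score of an ordered pair (A, B) is the mean number of
B-neighbors per A-cell (the histoCAT convention; both directions are
reported, homotypic pairs count same-type contacts). Significance comes
from permuting the label vector over the fixed node positions (fixed
composition — the standard exchangeable null) and the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n_permutations)`, which is valid
under exchangeability and never zero; ties between null and observed
count as extreme, making the test conservative rather than anti-
conservative. The default tail is enrichment; avoidance (`null ≤ obs`) is
behind a flag. A pair is "present" in an image when both types occur
there; pairs with an absent type are reported `present=False` and left
untested. Across images, a pair is kept iff significant (P < α, default
0.05) in ≥ 30% of images and present in ≥ 90%, both compared with ≥ so
the boundaries are attainable.

**Calibration conditions.** The CSR calibration uses 100 cells at 50/50
type proportions in 40 × 40 px images (0.0625 cells/px², mean neighbor
degree ≈ 3 under the 4-px rule — comparable to the dense migratory-stream
fields the analysis targets) with 1000 permutations over 400 images.
Density matters: in much sparser images the neighbor graph is nearly
edgeless, the statistic collapses onto a few atoms, and the tie-inclusive
permutation p-value becomes markedly super-uniform — a degenerate regime
in which the test is valid but uninformative. Even at the chosen density
the empirical type-I error at α = 0.05 sits slightly below nominal
(≈ 0.040 measured over 2000 images), the irreducible cost of a discrete
null; this is within the 0.05 ± 0.02 tolerance asserted by the tests.

**Stream mapping.** Cells are projected to the nearest point of a
migratory-stream polyline; the normalised position is the cumulative arc
length at the projection divided by the total length (0 = stream origin at
the Arc, 1 = cortical end), and the signed perpendicular offset is
reported in pixels. Ties between segments resolve to the earliest segment.

## Morphometry

- **Area ratio**: region pixels / brain pixels × 100; the physical pixel
  area cancels. Tier 1 is measured directly; tiers 2–3 are Arc minus
  tier 1 (containment enforced).
- **Gyrification index**: closed-polyline length of the full contour
  divided by that of the outer envelope. When no envelope is supplied the
  convex hull of the full contour is used — a reproducible surrogate for
  the manually drawn "line connecting the cortical surface" (a
  rolling-closing envelope would be an alternative; the hull is exact for
  the synthetic contours used here). GI is invariant to rigid motion and
  uniform scaling and equals 1 for convex outlines.
- **Serial-section volume**: the conical-frustum sum
  `Σ (A_{k−1} + A_k + √(A_{k−1} A_k)) h_k / 3`, with optionally per-gap
  spacing (the study design this emulates used fixed 750 µm intervals).
  The sum is *exact* (relative error < 1e−12 in tests) for any solid whose
  radius is piecewise linear between sections — cylinders, cones, frustum
  stacks — and converges for smooth solids: a sphere cut into 21 sections
  across its diameter is recovered within 1%.
- **Tier intensity profiles**: mean intensity of pixels strictly above a
  positivity threshold, per tier band of a wall-anchored rectangular box;
  an empty band yields `NaN` (missing), not an error. Tier boundaries are
  explicit inputs — in the emulated workflow they were drawn manually from
  DAPI, which is not reproducible from code.
- **Correlation**: standard Pearson product-moment r with the two-sided
  t-test p-value, reported with n.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their arguments including the seed
(seeds are explicit, never global state). Coordinates are 0-based pixel
indices, origin top-left, y downward.

- **Probe images**: ROIs are disks at centroids (radius configurable,
  default 3 px); overlapping disks are partitioned by nearest centroid
  (lowest id on exact ties) so pixel-count oracles are unambiguous. Each
  ROI pixel is probe-positive with the cell's (type, gene) probability;
  background pixels are positive at the speckle rate; the realised
  positive fraction per cell is stored as ground truth. Channels are
  binary (0 / 255) — no point-spread function, no registration error
  across rounds, no intensity gradients. Passing the exact-recovery test
  therefore shows the thresholding/counting machinery is correct, not that
  the pipeline is robust to microscope noise.
- **Cell maps**: CSR (uniform, independent multinomial labels) or planted
  structure. Homotypic attraction is a Neyman–Scott process: uniform
  parents (count = Poisson(rate × area) when a rate is given, else
  `n_type / mean_offspring`, at least 1), offspring assigned uniformly to
  parents with isotropic Gaussian scatter (default σ = 2 px), wrapped onto
  the image torus to preserve stationarity. Heterotypic attraction
  scatters the second type around the first; avoidance rejection-resamples
  points inside an exclusion radius. The real streams' spatial intensity
  and clump scale are not reported in any source; these defaults are
  stated, not fitted.
- **Solids and contours**: cross-sections are analytic closed forms;
  folded contours are `r(θ) = R + a·sin(kθ)` with `a < R` (which
  guarantees a simple curve), their true lengths attached from adaptive
  quadrature of `√(r² + r′²)` and the envelope being the circle through
  the gyral crests.
- **Region masks**: exact-pixel-count rectangles stacked row-wise; a
  request with no feasible rectangle factorisation (e.g. a prime wider
  than the image) is rejected rather than approximated.
- **Subtype benchmark**: 700 cells, 384 × 384 px, the 32-gene panel, the
  six inhibitory subtypes at 13% each (78% combined) plus SATB2⁺ cells;
  defining markers at probe-pixel probability 0.6, lineage co-markers
  0.25–0.45, background 0.05, speckle 10⁻³ per pixel, ROI radius 3 px
  (≈ 29 px per ROI, so one pixel ≈ 3.4 percentage points of expression
  noise). At these settings the end-to-end pipeline recovers planted
  labels for ≥ 90% of cells with ARI > 0.8; smaller ROIs, weaker markers
  or heavier speckle degrade this gracefully but are not part of the
  asserted contract.

## Numerical choices and degenerate inputs

- Strict inequalities throughout where the underlying rule is strict:
  neighbor distance, median zeroing, positivity thresholds, foreground
  ("strictly above threshold").
- Threshold candidates, argmaxes and stream-segment ties resolve to the
  first (lowest) option deterministically.
- Empty ROI, empty brain mask, constant image (at the public threshold
  API), zero-variance correlate inputs, degenerate paths and infeasible
  packings raise `ValueError`; empty tier bands and absent types in an
  image are flagged missing/not-present instead, because they occur in
  routine batch analysis.
- Permutation null comparisons use a 1e−9 tolerance so that identical
  statistics computed through the vectorised engine compare as ties.
- Monte-Carlo sizes in tests and the acceptance script (400 calibration
  images, 20-image experiments, 10⁴ permutations on the enumerable
  fixture, 700-cell benchmark) were sized to give comfortable statistical
  resolution for the asserted tolerances on a single CPU.

## Known limitations

- No registration of sequential smFISH rounds, nucleus segmentation or
  spot counting; ROIs and tier boundaries are inputs, not inferred.
- The permutation test assumes exchangeable labels within an image;
  gradients in cell density do not violate the null, but make the
  enrichment interpretation local to the image.
- The Rényi dialect's ordering-and-weighting rule is defined for exactly
  three α values; other `alpha_set` sizes fall back to the median
  candidate.
- Aggregation requires every image to contribute a result per pair;
  "present" means both types occur in the image (an observed-contact
  reading of presence is a stricter alternative not implemented).
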