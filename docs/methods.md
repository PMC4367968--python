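# Methods

## Overview

`eyereg` quantifies the spatial regularity of the Drosophila
compound-eye surface from reflected-light photographs. Each ommatidial
lens reflects incident light as a bright spot, so a healthy eye shows a
near-hexagonal lattice of reflections while retinal degeneration (the
rough-eye phenotype) scrambles and thins it. The pipeline is:

1. **Normalization** — 8-bit grayscale conversion, rolling-ball
   background subtraction, and a surface-like contrast filter.
2. **Detection** — ommatidial reflections as local intensity maxima
   with a prominence (noise-tolerance) criterion, inside a
   user-defined region of interest (ROI).
3. **Features** — 18 spatial-regularity variables: four grid-cell
   occupancy percentages; mean/variance/skewness of maxima-per-cell
   plus the total count (TOTMAX); mean/variance/skewness across cells
   of the centroid-to-mass-center distance (DISTM/DISTVAR/DISTSKEW);
   the same aggregates of within-cell kurtosis and skewness; and the
   log variance of nearest-neighbor distances (LOGNNVAR).
4. **Classification** — a five-class multinomial logit on
   (DISTM, DISTSKEW, LOGNNVAR) with the fully degenerate class 4 as
   reference, shipped as a versioned JSON coefficient asset; the class
   probabilities are collapsed to the regularity index
   `IREG = (4·PP₀ + 3·PP₁ + 2·PP₂ + PP₃)/4 ∈ [0, 1]`.

The package also ships the full model-(re)building pipeline
(correlation pruning, per-variable ANOVA screening, PC1 clustering into
five ordered classes, forward-stepwise variable selection, multinomial
fitting with train/test splits and a split-robustness check), the group
statistics (Kruskal–Wallis plus Dunn's post-hoc z tests), and a
synthetic image generator so every stage is testable without image
downloads.

## Coordinate and intensity conventions

Pixel coordinates are 0-based `(x, y)` = (column, row), origin top-left.
Images are floats on the 8-bit scale [0, 255] throughout; rounding to
integers happens only on export, so feature values never suffer double
rounding. 16-bit inputs are linearly rescaled to [0, 255]; RGB is
collapsed with BT.709 luminance weights (0.2125, 0.7154, 0.0721).

ROI polygons are rasterized by even-odd ray casting evaluated at pixel
centers with a half-open crossing rule (`(y1 > y) != (y2 > y)`, strict
`x < x_crossing`): pixel centers exactly on a left/bottom edge are
inside, on a right/top edge outside. This makes ROI areas exactly
reproducible — a rectangle with vertices (0,0)–(W,0)–(W,H)–(0,H)
rasterizes to exactly W×H pixels.

## Background subtraction

The background is the ball-apex surface: for a ball of radius `r`
(pixels, same units on the intensity axis),

    bg(p) = min over |d| <= r of  img(p + d) + r − sqrt(r² − |d|²),

i.e. the apex height of the ball positioned under pixel `p` with its
surface kept under the image (scikit-image's `rolling_ball`). This is
the erosion half of a grayscale opening with a ball-shaped structuring
element; the full opening (the envelope over all ball positions) is
bounded below by it, and the two differ at most by the sag of the ball
across a feature — a conservative background that never clips isolated
narrow peaks. A 1-pixel spike loses at most `r − sqrt(r² − 1)`
(≈ 0.05 gray levels at r = 10). Frame edges use only in-frame pixels.

Note that any convex ball wider than the inter-spot gap rides across
the tips of a dense reflection lattice, so the residual spot contrast
after subtraction is much smaller than the raw spot amplitude. This is
inherent to rolling-ball subtraction, not an artifact; the detection
tolerance must be calibrated to the residual contrast (see below).
Default radius: 50 px, the common default of the lineage
implementation; the calibration loop tunes it per dataset.

## Surface-like filter

`out(x,y) = (img(x,y) + shifted(255 − img)(x,y)) / 2`, where the
inverted copy is displaced horizontally by `displacement` pixels
(default 1) with edge replication so no column is undefined. Flat
regions map to exactly 127.5 regardless of their level, which
normalizes uneven illumination; intensity edges become symmetric
bright/dark ridges that sharpen spot contrast. The displacement is a
free parameter and reported with results.

## Maxima detection

A maximum is reported when its prominence — height above the highest
saddle connecting it to a higher maximum — strictly exceeds the noise
tolerance. Prominence is computed exactly by a union-find sweep over
pixels in descending intensity order (the persistence construction)
with 8-connectivity; intensity ties break by raster order. The global
maximum has no higher maximum, hence unbounded prominence: it is always
reported unless the image is constant. Equal-valued plateaus yield a
single point at the plateau centroid rounded to the nearest pixel
(Python banker's rounding at exact .5). Prominence is evaluated on the
full image; points are then filtered by the ROI mask. Prominence is
invariant to global intensity offsets, which the test suite checks.

The default tolerance (12 gray levels) separates well-resolved
reflections (residual prominence roughly 10–30 after preprocessing at
the generator's reference conditions) from sensor noise. The
calibration operation reproduces a user's manual count: for each
candidate rolling-ball radius it scans the tolerance on a logarithmic
ladder over [1, 255] (the count is non-increasing in tolerance) and
stops at the first pair within ±5% of the manual count, returning the
best pair flagged unconverged otherwise. The procedure is fully
deterministic.

## Feature scale

All distances (nearest-neighbor, centroid-to-mass-center) are converted
to micrometers via the image's pixel size and divided by the reference
pitch 1.85 um — the resolution at which the built-in coefficients were
developed — so images at any resolution feed the classifier on its
development scale. The grid-cell default of 50 px at reference
resolution (~92.5 um, several ommatidia across) scales inversely with
pixel size to preserve the physical cell extent.

The grid is anchored at the top-left corner of the ROI bounding box;
only cells lying entirely inside the ROI mask are kept, so regions near
the ROI edge are discarded. TOTMAX counts all maxima in the ROI, not
only those inside complete cells. The cell "centroid" is the mean of
its pixel centers, `(x0 + (c−1)/2, y0 + (c−1)/2)` for cell size `c`;
on the single-pixel maxima image all points carry equal weight, so the
brightness-weighted center of mass equals the plain mean position.

Moment estimators: variance uses denominator n−1 (zero for n < 2);
skewness and kurtosis are the biased population standardized moments,
kurtosis non-excess. Within-cell skewness/kurtosis are computed on the
distribution of point-to-centroid distances and require ≥ 3 / ≥ 4
points; sparser cells are excluded from the across-cell aggregation,
and empty cells contribute only to the occupancy and count statistics.
The within-cell "skewness"/"kurtosis" variables admit more than one
reading (per-cell moments of what, exactly); since none of them enters
the final three-variable classifier, the choice made here affects only
the exploratory variable set, never IREG.

If all nearest-neighbor distances are identical (a perfect lattice),
their variance is zero and LOGNNVAR is floored at
`log(eps) ≈ −36` (double-precision machine epsilon), with a flag
carried through to the output tables.

## The classifier

Linear predictors for classes i = 0..3 relative to reference class 4:

    a_i = independent_i + distm_i·DISTM + distskew_i·DISTSKEW
          + lognnvar_i·LOGNNVAR

    PP_i = exp(a_i) / (Σ_j exp(a_j) + 1),   PP_4 = 1 / (Σ_j exp(a_j) + 1)

computed with max-subtraction so extreme predictors cannot overflow.
The shipped coefficient matrix has exactly 16 free values (4 classes ×
4 columns); class 4 carries the implicit zero row. IREG weights the
ordinal classes 4,3,2,1,0 and divides by 4, so IREG = 1 is a fully
regular (wild-type-like) surface and IREG = 0 full degeneration. IREG
is a convex combination, hence always in [0, 1], and moving probability
mass to a less-degenerate class never decreases it.

A quirk of the shipped coefficients worth knowing: the class-3 DISTSKEW
coefficient is strongly negative, so extremely disordered patterns with
negative distance skewness can score as class 3 (IREG ≈ 0.25) rather
than class 4. The monotone IREG response to increasing disorder still
holds across the tested gradient.

## Model rebuilding

`RegularityModel` wraps a feature table and exposes the pipeline in
statsmodels style; `fit()` returns a `RegularityResults` with the
coefficient matrix in the published layout, standard errors,
log-likelihood, held-out accuracy and a `summary()` table.

* **Correlation pruning** (default |r| > 0.9): greedy elimination —
  repeatedly drop, from the worst pair, the variable with the larger
  mean absolute correlation to the remaining set; ties break by column
  order. Constant columns are dropped first with a warning.
* **ANOVA screen**: per-variable one-way ANOVA in the classic layout
  (between/within sums of squares, df k−1 and N−k, mean squares, F,
  upper-tail p). Zero within-variance with distinct means reports an
  infinite F.
* **Class assignment**: PCA on z-scored variables (correlation-matrix
  PCA — the variables' scales differ wildly); k-means (k = 5, fixed
  seed, k-means++) on the PC1 scores; clusters ordered along PC1 and
  oriented so class 0 sits at the low-DISTM (regular) end. Undefined
  moment entries are neutralized at the column mean before the PCA.
* **Stepwise selection**: forward entry by likelihood-ratio p < 0.05,
  backward removal at p > 0.10, deterministic.
* **Multinomial fit**: statsmodels MNLogit, Newton with an L-BFGS
  fallback when Newton degenerates on (quasi-)separated data.
  Separation is flagged heuristically (non-finite or runaway
  coefficients/standard errors, or non-convergence) and the
  coefficients still reported with a warning.
* **Robustness check**: refits across random train/test divisions and
  reports each group's mean IREG per split plus the maximum across-split
  difference; with a single split the dispersion is undefined.

Group comparison uses scipy's Kruskal–Wallis (tie-corrected) and a
hand-computed Dunn's z for each pair (rank-sum difference over the
tie-corrected standard error), unadjusted by default with Bonferroni
and Holm options; pairs are flagged at p < 0.05.

## Synthetic data

The generator renders Gaussian spots on a hexagonal lattice (ommatidia
pack hexagonally) clipped to an elliptical footprint mimicking the
in-focus region of a curved eye. Degeneration is emulated by positional
jitter (isotropic Gaussian, px), spot dropout (independent deletion
probability) and spot broadening, over a linear illumination gradient
with additive Gaussian noise. Reference conditions: 256×256 frame,
22 px pitch (≈ 40 um at the 1.85 um reference pixel), spot σ = 3 px,
amplitude 180, gradient span 30, noise σ = 4. All randomness flows from
one integer seed through `numpy.random.default_rng`.

What the generator does *not* emulate: lens glare, specular highlights,
bristles, curvature-dependent defocus, or correlated texture; passing
tests therefore demonstrate the correctness and monotone behavior of
the algorithms on idealized reflection patterns, not performance on any
particular microscope's images — real deployments should recalibrate
detection parameters against manual counts.

For training-path validation there is also a feature-space simulator:
triples drawn from a stratified five-component Gaussian mixture (one
component per class-dominant region of feature space, spreads
(2.5, 0.7, 3.0), weights 0.15/0.10/0.15/0.30/0.30) with class labels
sampled from the built-in model's probabilities. The stratification
keeps every between-class boundary populated so that even the
near-zero coefficients of the class-3 equation are sign-identifiable
at n = 2000.

## Problem sizes and numerical choices

The validation suite runs at desk scale by design: detection is checked
against exhaustive prominence enumeration on 200 random fields up to
64×64; the degeneration-gradient check uses 20 seeds × 3 conditions of
256×256 images; coefficient recovery uses n = 2000 simulated feature
triples; the split-robustness check uses 3 divisions of 450 rows.
Feature-level property tests use the generator's ground-truth points
directly where image rendering adds nothing to the property under test.
One property test pins the lattice pitch to 12.5 px (cell size an exact
multiple) so the zero-jitter distance baseline reflects regularity
rather than the arbitrary phase between lattice and grid.

Known limitations: no sub-pixel localization or spot-shape fitting; no
support for z-stacks or color channels; the exact class boundaries of
the original five-class clustering are not recoverable from the
published material, so the PC1/k-means assignment is this package's own
(documented) construction; reproducing the original study's fitted
numbers would require its image dataset.
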