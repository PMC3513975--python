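# Methods

This note records what each stage of `regionbow` computes, the modelling
assumptions behind it, the defaults and why they were chosen, and what
the synthetic phantoms do and do not establish about real data.

## Synthetic phantoms

Each phantom is a 160×160 image with one star-convex lesion: an
ellipse-like base radius (18–28 px, uniform) modulated by harmonics 2–4
with total relative amplitude ≤ 0.12, guaranteeing a simply-connected
mask with well-defined outward normals and at least 18 px of clearance
between the lesion and every border (enough for 15-px profiles plus a
3-px patch radius). Around the lesion, a 20-px annulus (by Euclidean
distance from the mask) carries its own intensity distribution — the
stand-in for category-specific surrounding tissue.

The three default classes separate along both cues the method uses:

| class | interior mean/sd | texture (sd, blur scale) | ring mean/sd |
|---|---|---|---|
| bright-smooth | 180 / 8 | 20, 3 px | 70 / 8 |
| dark-plain | 80 / 8 | — | 150 / 8 |
| mid-coarse | 130 / 8 | 30, 6 px | 110 / 12 |

Background level is 40 and global pixel noise sd is 5, so interior means
sit ≥ 10 noise-sd apart — a regime in which a nearest-centroid
classifier on masked mean intensity is already perfect, which the tests
use as a sanity ceiling. The interior texture is a Gaussian random field
(white noise blurred at the stated scale) recentred to zero mean within
the mask, so texture adds grain without shifting a class's mean level.
Per-patch normalization removes local level and contrast, so what the
interior BoW actually discriminates here is texture *pattern* (grain
scale), while the margin BoW sees the sign and steepness of the
boundary step — the analogue of enhancing rim vs dark halo in contrast
images.

What the phantoms deliberately lack: anatomy and MRI physics (bias
fields, partial voluming, acquisition-dependent histograms), multi-organ
background structure, inter-observer mask variability, multiple lesions,
and correlated patients across images (every phantom is its own
patient). Passing the end-to-end test therefore shows that the pipeline
recovers class structure *when the assumed cues are present and the mask
is right*; it does not certify clinical performance.

## Intensity standardization

Two-step landmark standardization. Foreground = pixels strictly above
the image median (an order statistic; the common above-the-mean rule is
available via `foreground_rule="above-mean"`). Landmarks are the 1st
percentile, median and 99th percentile of the foreground, computed as
order statistics (`numpy` method `"lower"`). Training fixes
`s_low = 0`, `s_high = 4095` (a 12-bit-like range that avoids
quantization of 8- or 16-bit inputs) and sets `s_mid` to the mean of the
training images' medians after mapping each image's (low, high) linearly
onto the scale ends. Transformation is the continuous two-segment linear
map through the three landmark pairs; beyond the outer landmarks the
adjacent segment is extended (slopes are positive, so the full map is
strictly increasing).

The median-based foreground rule is what makes the transform *exactly*
idempotent: a strictly increasing map commutes with order statistics, so
a standardized image reselects the same foreground pixels and its
landmarks land exactly on `(s_low, s_mid, s_high)`; the second
application is then the identity, bit for bit. With a mean-based rule
the reselected foreground can differ slightly and idempotence holds only
approximately. Degenerate images (landmarks not strictly increasing,
e.g. constant images) are excluded from training with a warning and
passed through unchanged at transform time.

## Boundary geometry and the margin region

The mask boundary is traced by Moore contour following (clockwise in
array coordinates, i.e. counterclockwise on screen), yielding a closed
8-connected cycle of boundary pixels; masks must be a single
simply-connected component of ≥ 50 px. Boundary coordinates, treated as
circular sequences, are convolved with the first derivative of a 1-D
Gaussian (σ = 3 px by default — enough to suppress pixel jaggedness
without rounding gross shape; the value is configurable). This gives a
smoothed tangent; the normal is the tangent rotated by 90°, with one
global sign chosen by a mask-membership probe at +2 px so normals point
outward, and the angle taken with `atan2` (a two-quadrant arctangent of
the derivative ratio would be sign-ambiguous). Points with vanishing
tangent magnitude get angles interpolated from circular neighbors.

Profiles are sampled at unit spacing `l = −15 … +15` along each normal
(31 values; 0-based `(row, col)` coordinates, bilinear interpolation,
out-of-range coordinates clamped to the edge with a warning). Boundary
pixels are used as traced — no arc-length resampling — so the margin
rectangle has one row per boundary pixel. Each row is labeled with the
quadrant (y-axis up, half-open at 0°/90°/180°/270°) of the
centroid-to-point vector: top-right, top-left, down-left, down-right.

## Patches and whitening

Tumor patches: one 7×7 window per mask pixel whose window fits in the
image (the window may extend past the mask — the mask is a sampling
region, not a crop). Margin patches: dense 7×7 windows over the margin
rectangle, circular in the row dimension (the trace seam is arbitrary)
and valid-only in the column dimension, each tagged with its center
row's quadrant. Per-patch normalization is `(p − mean) / sd` with the
population (n-divisor) sd; constant patches map to the zero vector.

Whitening is fitted per region from `C = E[PPᵀ]` over the normalized
patches — uncentered beyond the per-patch normalization — via
eigendecomposition, with the symmetric (ZCA) inverse square root
regularized by `ε = 10⁻⁵ ×` mean eigenvalue by default: near-null
eigendirections of patch covariance otherwise amplify noise.
Eigenvector signs are fixed (largest-magnitude entry positive) so
refits are bitwise-stable.

## Vocabularies and the representation

k-means (k-means++ init, Lloyd iterations, tolerance 10⁻⁴, ≤ 300
iterations, seeded and single-start, via scikit-learn) on a seeded
uniform subsample (cap 100 000 patches by default). Defaults k₀ = 1000
interior words and k₁ = 300 margin words; the phantom-scale tests and
the acceptance script use 100/50, matched to the much smaller phantom
patch budget. If fewer distinct patches than k exist, k is reduced with
a warning.

Encoding is hard assignment: each patch votes 1/n for its nearest word
by squared Euclidean distance, ties to the lowest word index (the
counts are kept as integers internally, so partition identities hold
exactly). The image representation concatenates six blocks —
interior (k₀), whole margin (k₁), and the four quadrants (k₁ each, all
five margin blocks sharing the single margin vocabulary) — each block
normalized by its own patch count. The quadrant counts partition the
whole-margin counts exactly; an empty region yields an all-zero block
with a warning.

## CFML

`M_S` and `M_D` are means of `(x_i − x_j)(x_i − x_j)ᵀ` over all
unordered same-/different-label pairs, computed with the Gram identity
`Σ_{i<j}(x_i−x_j)(x_i−x_j)ᵀ = n XᵀX − ssᵀ` (equal to the explicit pair
loop in exact arithmetic). The projection solves
`min_L tr(L (M_S − M_D) Lᵀ)` under `L (M_S + λI) Lᵀ = I` via the
generalized symmetric eigenproblem `M_D v = μ (M_S + λI) v`, keeping the
d eigenvectors of largest μ, rescaled so `vᵀ(M_S + λI)v = 1` and
sign-fixed for determinism. The generalized formulation avoids forming
`(M_S + λI)^{-1}` explicitly, which matters in the small-sample
large-feature regime where `M_S` is rank-deficient. λ = 10⁻⁶ is an
absolute ridge (not trace-scaled) and d = 2 by default; features enter
CFML exactly as the BoW module produces them, with no extra scaling.

## Retrieval evaluation

Queries are ranked against a disjoint training set (a query never ranks
itself; a self-match would inflate precision), ties in distance broken
by dataset index. Precision, recall, Prec@K, AP and mAP are ratios of
integer counts and are accumulated as exact rationals (`fractions`)
before a single rounding to float, so they match enumeration oracles
exactly. Cross-validation is stratified k-fold (shuffled, seeded),
repeated; within a repeat all models are fitted on the training folds
only, every held-out image queries its training fold, and the repeat's
mAP averages AP over all its queries; the headline numbers are mean ± sd
of mAP across repeats. Defaults: 5 folds × 5 repeats. In these phantoms
each image is its own patient; with real multi-view data, patient
disjointness across folds should be enforced through the manifest's
`patient_id`.

## Numerical and design choices worth knowing

- **Problem sizes.** The end-to-end checks and the acceptance script run
  60 phantoms (3 × 20) with 100/50-word vocabularies and a 20 000-patch
  k-means subsample — small enough for a single CPU in minutes, large
  enough that every class contributes 16 training images per fold.
- **Exactness conventions.** Order-statistic landmarks, integer
  histogram counts, rational metric accumulation, and fixed eigenvector
  signs exist so that determinism and oracle-equivalence tests can
  assert bitwise equality rather than tolerances.
- **Stage split in the CLI.** `standardize` fits the intensity model,
  `features` the per-region whitening, `vocab` the vocabularies,
  `encode` the per-image vectors, `train-metric` the projection; each
  stage checks its prerequisites in the shared HDF5 store and names the
  missing artifact if run out of order.
- **Known limitations.** Single 2-D lesion per image; no patient-level
  grouping in the phantom CV (each phantom is one patient); margin
  profiles assume the lesion keeps ≥ h + patch-radius pixels of border
  clearance (violations clamp and warn); Moore tracing can revisit
  pixels on 1-px-wide necks (revisits are dropped, keeping first
  occurrence), which cannot occur for the phantom shape family.
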