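# regionbow

Content-based retrieval of lesion images in grayscale MRI-like data using
**region-specific bag-of-visual-words (BoW) representations** and
**closed-form Mahalanobis metric learning (CFML)**.

## The problem

A radiologist looking at a lesion in an MRI slice often wants to see
previously diagnosed cases that *look like this one*. Ranking a labeled
image archive by visual similarity to a query is hard for lesions: shape
and size vary wildly within a diagnostic category, while the reliable
cues are (a) the intensity/texture statistics *inside* the lesion and
(b) the appearance of the *tissue immediately surrounding* it. `regionbow`
implements a retrieval pipeline built around exactly those two cues, for
2-D grayscale images with binary lesion masks (image + mask + class label
per case). Because clinical archives are rarely shareable, the package
ships a first-class synthetic phantom generator that reproduces the
statistical structure the method exploits, so every stage is testable
end to end.

## The method

1. **Intensity standardization.** Each image's foreground landmarks
   (1st percentile, median, 99th percentile) are mapped piecewise-linearly
   onto a common standard scale `[0, 4095]`, so equal intensities mean
   equal tissue across images. The map is monotone and exactly idempotent.
2. **Margin region.** The lesion boundary is traced, smoothed with a
   Gaussian (σ = 3 px), and an outward normal is computed at every
   boundary pixel. A 31-pixel intensity profile (15 px inside, the
   boundary pixel, 15 px outside) is sampled along each normal; stacking
   the profiles gives a rectangle — the *margin region* — that is
   rotation-invariant with respect to the lesion and is further split
   into four quadrant subregions (top-left/top-right/down-right/down-left).
3. **Patches.** Raw 7×7 patches are sampled densely (stride 1) from the
   lesion interior and from the margin rectangle, normalized per patch to
   zero mean / unit variance, and whitened with a per-region ZCA transform
   `P̃ = V (D + εI)^(−1/2) Vᵀ P` fitted from the patch second-moment
   matrix `C = E[PPᵀ] = VDVᵀ`.
4. **Region-specific BoW.** Two k-means vocabularies are built (interior,
   k₀ = 1000; margin, k₁ = 300). Each image becomes the concatenation of
   six hard-assignment histograms over three levels —
   `[tumor | margin | four quadrants]`, each block independently
   normalized to sum 1 — a `k₀ + 5·k₁` vector (2500 at the default sizes).
5. **Metric learning.** With `M_S`/`M_D` the mean outer products of
   feature differences over same-/different-class pairs, CFML solves

   `min_L tr(L (M_S − M_D) Lᵀ)  s.t.  L (M_S + λI) Lᵀ = I`

   in closed form via a generalized eigendecomposition (λ = 10⁻⁶,
   projection dimension d = 2). Retrieval ranks the archive by the
   squared Mahalanobis distance `d(x_i, x_j) = ‖L(x_i − x_j)‖²`.
6. **Evaluation.** Precision/recall, Prec@K, average precision and mAP
   under repeated stratified five-fold cross-validation, where each
   held-out image queries the training fold.

## Worked example

```python
from regionbow import phantoms, pipeline, retrieval

dataset = phantoms.generate_dataset(phantoms.default_spec(seed=1), 20)
cfg = pipeline.PipelineConfig(k_tumor=100, k_margin=50, max_fit_patches=20_000, seed=1)
result = retrieval.crossval(dataset, cfg, n_folds=5, n_repeats=1, seed=1)
print(f"mAP = {result.map_mean:.3f} ({result.n_folds}-fold CV, {len(dataset)} phantoms)")
print("per-class mAP:", {c: round(v, 3) for c, v in result.per_class_map.items()})
print(f"Prec@10 = {result.prec_at[10]:.3f}")
```

prints

```
mAP = 1.000 (5-fold CV, 60 phantoms)
per-class mAP: {0: 1.0, 1: 1.0, 2: 1.0}
Prec@10 = 1.000
```

i.e. on 60 phantoms (three classes differing in interior level/texture
and in the surrounding tissue ring) every held-out query ranks all
same-class training images ahead of every other class, even with
vocabularies reduced to 100/50 words to match the phantom patch budget.

The same pipeline is scriptable from the shell:

```bash
regionbow make-phantoms --out data --n-per-class 20 --seed 1
regionbow standardize --manifest data/manifest.csv --store exp.h5
regionbow features    --manifest data/manifest.csv --store exp.h5
regionbow vocab       --manifest data/manifest.csv --store exp.h5
regionbow encode      --manifest data/manifest.csv --store exp.h5
regionbow train-metric --store exp.h5
regionbow query --store exp.h5 --image data/images/img_0000.png \
                --mask data/masks/img_0000_mask.png --top-k 10
regionbow crossval --manifest data/manifest.csv --out-dir eval
```

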