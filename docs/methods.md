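# Methods

`placentex` implements a texture-analysis pipeline for detecting placental
microcalcifications in B-mode ultrasound regions of interest (ROIs). The
clinical images that motivated the pipeline are not redistributable, so the
package ships a synthetic speckle phantom with known ground truth; everything
downstream of image loading is agnostic to where the ROIs came from.

## Pipeline

For each ROI the pipeline runs two arms:

* **M1** — features computed on the raw ROI.
* **M2** — features computed after unsharp-mask contrast enhancement.

In both arms, ten features are extracted per ROI:

1. **First-order** (from the 256-bin intensity histogram, probability-weighted
   population moments): standard deviation SD, skewness SK, and non-excess
   kurtosis KR. SD is the square root of the second central moment; skewness
   and kurtosis are the third and fourth standardized moments. On a constant
   ROI SD is 0 and SK/KR are undefined (recorded as missing).
2. **Second-order** (from a normalized gray-level co-occurrence matrix,
   GLCM): contrast C = ΣΣ (i−j)² p(i,j), homogeneity H = ΣΣ p/(1+|i−j|),
   correlation CR = ΣΣ (i−μᵢ)(j−μⱼ) p / (σᵢσⱼ), energy E = ΣΣ p², and
   Shannon entropy EN = −ΣΣ p log₂ p (bits, with 0·log 0 := 0). The GLCM is
   accumulated symmetrically at the native L = 256 gray levels for offset
   distance δ = 1 (configurable) and averaged over the four standard angles
   θ ∈ {0°, 45°, 90°, 135°}, giving one value per feature per ROI. CR is
   undefined on a constant ROI (zero marginal SD) and recorded as missing.
3. **Fractal dimension** of two binary edge maps: FD_I after Sobel gradient
   binarization (Otsu threshold on the gradient magnitude), FD_II after a
   Laplacian-of-Gaussian (LoG) zero-crossing detector. The dimension is the
   ordinary-least-squares slope of log N_r against log(1/r) over a dyadic
   ladder of box sizes r ∈ {2, 4, 8, …, min(H, W)/2}, with boxes anchored at
   the image origin and ragged edge boxes allowed; the fit's r² is reported
   so callers can reject poor scaling. Edge-free ROIs (e.g. constants) yield
   missing FDs and are excluded listwise from FD-based models only.

Features are screened with an uncorrected two-sided two-sample t-test
(pooled-variance Student by default, Welch available) at α = 0.05; running
ten uncorrected tests inflates the family-wise error rate, and this is kept
deliberately because it is part of the protocol being modeled, not a defect
to repair. Classification uses a from-scratch K-nearest-neighbors model
(K = 3, Euclidean distance, z-score standardization) under a stratified
80/20 train/test split with stratified 5-fold cross-validation inside the
training portion; a polynomial-kernel SVM (degree 3) is run as a comparison
baseline under the identical protocol. Accuracy is
100·(TP+TN)/(TP+TN+FP+FN) with *calcified* as the positive class.

Per-feature (univariate) classifiers are first-class: the study design
reports one accuracy per feature, plus four feature-combination models
(first-order+GLCM, first-order+GLCM+FD, first-order+FD, GLCM+FD).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| GLCM offset δ | 1 | px | unit offset is the near-universal default; larger δ decorrelates pairs |
| unsharp `blur_sigma` | 2.0 | px | low-pass scale of the high-pass stage |
| unsharp `amount` | 0.8 | — | high-pass weight; 0 disables enhancement |
| LoG `sigma` | 2.0 | px | edge-detector scale; kernel half-width ceil(3σ) |
| K-NN `k_neighbors` | 3 | — | odd, avoids binary vote ties in most queries |
| split | 80/20, 5 folds | — | stratified; both classes guaranteed per fold at n = 96 |

## The phantom

The phantom emulates fully developed speckle: independent white-noise real
and imaginary fields are smoothed with an isotropic Gaussian
(`speckle_corr_sigma`), and the envelope (complex magnitude) is taken, giving
a Rayleigh first-order amplitude distribution (mean/SD = √(π/(4−π)) ≈ 1.913)
with a controllable correlation length. The envelope is rescaled to a target
mean intensity (`background_mean`), clipped to [0, 255] and quantized
(round-half-up). Calcifications are isotropic Gaussian bumps (amplitude 80,
radius 1.5 px, 4 per calcified ROI) added at uniform-random interior
positions at least 2σ from the borders. The default set is 96 ROIs of
64×64 px, 48 per class, bit-identical under a fixed seed.

The two free background parameters were fixed by a one-time calibration:
with the speck parameters held at their defaults, a grid over
`background_mean` × `speckle_corr_sigma` was scored on (a) the fraction of
generator seeds in which all ten features pass the t-test screen and (b)
single-feature K-NN test accuracy, seeking clearly-above-chance but
non-saturated performance. The chosen point, `background_mean = 32` and
`speckle_corr_sigma = 1.6` px, gives a representative single feature (SD)
about 84% test accuracy and a type-I error of the screen consistent with the
nominal 5% when the speck amplitude is set to zero.

What the phantom does **not** model: acoustic shadowing distal to
calcifications, depth-dependent attenuation and focusing, sector-probe
geometry, log compression of the display pipeline, and gestational-age
texture progression. Passing tests on the phantom therefore demonstrate that
the pipeline recovers a known textural signal embedded in correlated
Rayleigh speckle under the stated protocol — not clinical performance on
real placental scans.

## Numerical choices

* All intensity images are 8-bit; float intermediates are clipped to
  [0, 255] and rounded half-up before re-quantization.
* Convolutions (Gaussian, Sobel, LoG) use reflective boundary handling.
* The LoG kernel is the analytic form truncated at half-width ceil(3σ) and
  shifted to sum exactly to zero; a pixel is marked as an edge when it is on
  the weak side (smaller |response|) of a 4-neighbor sign change whose
  response span exceeds the threshold (auto: 0.75 × mean |response|, floored
  at 1e−6 so numerically flat responses yield no edges).
* Sobel "auto" binarization is an Otsu threshold on the gradient magnitude;
  a flat magnitude map short-circuits to an empty edge map.
* K-NN tie-breaks are fully deterministic: distance ties resolve to the
  lower training-row index (stable sort), vote ties to the nearest
  neighbor's label.
* Feature columns with zero training variance (to rounding noise) are
  dropped from distance computation with a warning.
* GLCM feature sums iterate only over non-zero matrix entries; this is
  exact, not an approximation.
* Box counting pads the raster with empty cells to a whole number of boxes;
  padding cannot create occupied boxes.

## Design choices on genuinely open points

* The high-pass filter of the contrast-enhancement stage is realized as
  identity minus Gaussian blur (classical unsharp masking); the weight and
  blur scale are exposed as parameters.
* Enhancement is applied per ROI (after cropping), before all feature
  computation in the M2 arm.
* GLCM features are reported angle-averaged; per-angle values remain
  available through `compute_glcm`/`glcm_features`.
* The printed definitions of SD and EN in the source material for this
  method family are degenerate as written (a first-power central "SD" is
  identically zero; an entropy without the minus sign is non-positive);
  both are implemented in their standard forms, which the higher moments
  and the non-negativity of entropy presuppose.
* Pooled (Student) two-sided t-test is the default variant; the protocol's
  tooling default is ambiguous, and Welch is one flag away.
* Stratified splitting/folds are mandatory at n = 96 to guarantee both
  classes per fold.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic inputs
generated at run time: 96-ROI phantom sets (64×64 px), 200 generator seeds
for the amplitude-zero calibration of the t-test screen, 25 seeds for
signal recovery, 30 label permutations for the chance-level check, and
256×256 / 243×243 rasters for the fractal fixtures. These sizes keep the
statistical checks well-powered while remaining desk-scale.

## Known limitations

* Phantom realism is first-order only (amplitude statistics and correlation
  length); B-mode post-processing is not simulated.
* The box-counting estimate is biased slightly downward on finite ternary
  fractals sampled with a dyadic ladder (measured ≈1.869 for the level-5
  Sierpinski carpet against the ideal 1.893).
* At n = 96 a 20% test partition holds ~19 ROIs, so single-run test
  accuracies are quantized in ~5-point steps; cross-validation means are
  more stable and both are reported.
* No multiple-testing correction (by design, see above).
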