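# Methods

`thyrocad` re-implements, as a tested and reusable pipeline, a multimodal-MRI
computer-aided diagnosis approach for thyroid nodules: T2-weighted (b = 0)
diffusion acquisitions and apparent-diffusion-coefficient (ADC) maps at three
b-values feed a compact two-branch 3D convolutional network that classifies a
nodule as benign or malignant.  This note records the model, the numerical
and design choices that were genuinely open, what the synthetic phantom
emulates, and the problem sizes the test suite runs at.

## Signal model and preprocessing

Diffusion attenuation follows the mono-exponential Stejskal–Tanner model

    S_b = S_0 · exp(−b · ADC),

so the two-point estimate against the b = 0 reference is
`ADC = ln(S_0 / S_b) / b` (mm²/s), computed voxelwise for b ∈ {500, 1000,
1500} s/mm².  Voxels whose signal falls below 1e-6 of the volume maximum in
either input are assigned ADC 0: they are empty background in practice and
would otherwise produce ±∞.  No multi-b least-squares fit is performed — the
pairwise two-point estimate is the method under study.

A model sample is built per nodule from the radiologist mask drawn on the
b = 0 volume (reused unregistered for all b-values, as the acquisitions are
co-registered by protocol):

1. crop the in-plane *square* bounding box of the mask (slice axis cropped to
   the tight extent), zeroing out-of-mask voxels;
2. centre the crop in a fixed 48×48×20 block of zeros (floor division for odd
   margins); crops larger than the target are first downscaled by trilinear
   interpolation — a logged fallback that default phantoms never hit;
3. min–max normalize to [0, 1] using **in-mask voxels only**, so the black
   background neither stretches the contrast nor changes under
   normalization.  Two deliberate edge rules: a constant in-mask region maps
   to 1.0, and the in-mask minimum is floored at 1e-6 instead of 0 so the
   nodule support stays distinguishable from background and the operation is
   idempotent.

The default channel plan feeds the b = 0 block to one branch (1 channel) and
the three ADC blocks to the other (3 channels).  Alternative plans expose the
ablation scenarios: `t2_only`, `adc_only`, and `stacked_single_input` (all
four modalities as channels of a single branch).

## Network

Each branch applies twice: Conv3D 3×3×3 (32 filters, ReLU) → Conv3D 1×1×1
(16 filters, ReLU; compresses the feature maps) → 2×2×2 max-pool.  Branch
outputs are flattened, concatenated, and passed through a 10-unit ReLU hidden
layer to a single sigmoid output (malignancy probability).  Two
documentation-level ambiguities in the source description were resolved as
follows:

* **Pooling**: 2×2×2 (the tabulated value) rather than the 2×2×1 variant
  mentioned in prose; both are accepted via `pool_size`.
* **Padding**: `"valid"` by default.  With valid padding and floor pooling
  the model has 129,365 learnable parameters for the (1, 3)-channel pair —
  within 1.2 % of the published total of 127,829, whereas `"same"` padding
  doubles the flattened length and gives 263,765.  We therefore read the
  original model as unpadded; `"same"` remains available.

Training minimizes the class-weighted MSE

    L = (1/N) Σ_i w_i (p_i − y_i)²,

with Adam (lr 1e-3, the Keras-default β/ε) for a fixed number of epochs.
Per-sample weights come from the training labels of the split at hand,
recomputed per cross-validation fold.  Two weight conventions exist:
`inverse-frequency` (default; up-weights the minority class, normalized to
mean weight 1) and `paper-literal` (weight ratio = class count ratio, e.g.
16/32 after leaving out a malignant case from a 17 + 32 training pool).  The
literal convention *down*-weights the minority class, which contradicts its
stated purpose of countering imbalance, hence the default.

The engine is a self-contained NumPy implementation (im2col convolutions
backed by BLAS GEMMs, max-pool argmax caching, manual reverse-mode
gradients); it is exact — verified against central finite differences at
1e-4 relative in float64 — and deterministic under a fixed seed and thread
count.  First-layer im2col patch matrices depend only on the inputs, so they
are precomputed once per cohort and shared across epochs and LOOCV folds.

Training hyperparameters left open by the source were fixed once against
training-convergence behaviour on phantom cohorts: batch size 2 (small-cohort
regime needs more optimizer steps per epoch than the dataset-sized batches a
49-patient study affords), Glorot-uniform initialization, decision threshold
0.5.  A stratified hold-out of 1-in-4 samples (reading "1 to 3" as
validation : training) is monitored during standalone fits; inside LOOCV
folds the harness trains on all remaining cases (`validation_fraction = 0`),
since at desk-scale cohort sizes a further 25 % carve-out measurably starves
the fit.

## Evaluation

Leave-one-out cross-validation: one fold per case, per-fold seed
`seed + fold_index`, class weights and all training state derived only from
the remaining cases (standardization is per-sample, so nothing leaks from
the held-out case).  Pooled held-out probabilities give the confusion matrix
at threshold 0.5 (ties predict positive), the metric set (accuracy,
sensitivity ≡ recall, specificity, precision, and "dice" — the
positive-class F1, *not* a segmentation overlap), and a single pooled ROC
curve whose trapezoidal area equals the Mann–Whitney pairwise concordance
with ties counted ½.  Undefined ratios (empty denominators) are reported as
absent, never as 0.

## Classical baselines

Three hand-crafted feature families per case: shape (voxel count, convex-hull
ratio via Delaunay membership counting, bounding-box ratio, spherical-
harmonic power spectrum of the radial contour function up to degree 8,
sampled on a 32×64 latitude–longitude grid about the centroid with a
star-shaped first-crossing approximation); histogram statistics per modality
(mean, SD, entropy in bits over a fixed 32-bin partition of [0, 1], skewness,
kurtosis — the latter two absent for constant regions); and a fixed nine-
kernel 3×3 filter bank applied slice-wise (Sobel-style edges at
0°/45°/90°/135°, second-derivative line detectors at the same orientations,
and the 8-connected Laplacian point kernel; all zero-sum, edges
odd-symmetric), summarized as mean absolute in-mask response.  Four
classifiers (decision tree, random forest, Gaussian naive Bayes, linear SVM)
are evaluated with the same LOOCV fold structure as the network;
hyperparameters are chosen inside each fold by a stratified 3-fold grid
search so tuning never sees the held-out case.

## Pixel-level texture statistics

For each case the slice with the largest mask area (ties → lowest index) is
high-pass filtered with the 8-connected, 45°-rotation-invariant 3×3 Laplacian
(reflect borders).  Absolute responses at in-mask pixels are pooled across
cases into malignant and benign groups per modality, and compared with a
Welch unequal-variance t-test (explicit Welch–Satterthwaite formulas; the
95 % CI of the mean difference is normalized by the benign group SD, matching
the percentage convention of the original report).  Absolute rather than
signed responses are compared because local intensity variation is a
magnitude concept; a flag restores signed responses.  The sign convention of
the difference defaults to malignant − benign and can be flipped, because the
published table is internally consistent only under benign − malignant.

## Kernel texture visualization

After training, the 32 first-layer 3×3×3 kernels of each branch are averaged
over input channels, then over depth, giving 3×3 tiles.  These are clustered
by hierarchical agglomerative clustering (Euclidean, Ward; average linkage
available) across k = 2..9, scored by mean silhouette, and rendered as
boards: one row per k, one tile per cluster, each tile the min–max-normalized
cluster mean on a white(0)→black(1) gradient; constant tiles map to mid-gray.

## Synthetic phantom cohorts

The study cohort is private, so the phantom module generates paired
T2/DWI volumes with planted class structure:

* one ellipsoidal nodule per case (random semi-axes 5–10 mm, anisotropic
  1×1×3 mm voxels on a 64×64×24 grid) in homogeneous background tissue;
* noise-free signals follow the forward Stejskal–Tanner model with voxelwise
  diffusivity `D`; additive Gaussian noise (SD 2 % of the nodule S₀ level)
  by default, Rician magnitude noise by flag;
* malignant nodules: mean `D` 0.9e-3 mm²/s; benign: 1.8e-3 mm²/s —
  consistent with the reading of ADC as an inverse cellularity marker; both
  classes share a fixed-amplitude smooth radial profile on S₀ and `D` so that
  per-sample min–max normalization cannot erase texture amplitude cues;
* class-dependent texture: smoothed Gaussian random fields multiply S₀ and
  `D`.  Malignant carries the larger (SD 0.12 vs 0.04) and finer-grained
  (correlation 1.2 vs 3.0 voxels) variation on S₀ (the T2 appearance);
  benign carries the larger, finer variation on `D` (hence on every ADC
  map).  This reproduces the qualitative sign pattern of the published
  pixel-level analysis — malignant rougher in T2, benign rougher in ADC —
  through both amplitude and granularity, the latter because correlation
  structure survives per-sample normalization.

A fixed seed makes cohorts byte-identical on disk.  The phantom does not
attempt anatomical realism: no partial-volume or susceptibility effects, no
motion, no non-nodule anatomy, single nodule per case.  Passing tests
demonstrate that the pipeline machinery is correct and can recover planted
class structure; they say nothing about performance on clinical data.

## Problem sizes used by the test suite

Single-CPU BLAS throughput makes the full-scale experiment (48-case LOOCV ×
30 epochs × two input plans) a multi-hour computation, so the packaged
discrimination check runs a scaled version chosen as the package's standard
desk-scale validation: 6 malignant + 12 benign phantoms, 20 epochs, batch 2,
no per-fold validation carve-out, seed 0 — with the unchanged thresholds
(pooled LOOCV AUC ≥ 0.8; multi-input accuracy within 0.05 of, or above, the
T2-only ablation).  At these sizes the run reports AUC ≈ 0.96 and accuracy
0.83 versus 0.50 for T2-only.  The bundled acceptance script repeats the same
experiment end to end (phantom generation → samples → LOOCV for both plans →
random-forest baseline → Welch table → silhouette sweep) at the same sizes.

## Known limitations

* The NumPy engine targets small cohorts on CPU; there is no GPU path, no
  data augmentation, and no mixed precision beyond the float32 default.
* The "dice" metric is classification F1; readers expecting a segmentation
  overlap should use the mask tools directly.
* Pixel pooling in the Welch analysis ignores within-nodule correlation, as
  in the original analysis; its p-values are anti-conservative in that
  sense.
* The spherical-harmonic descriptor assumes a star-shaped nodule about its
  centroid; strongly concave masks fold onto the first surface crossing.
* AlexNet/ResNet18 comparisons are out of scope; external per-sample
  probabilities can be evaluated with `report_from_probs` instead.
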