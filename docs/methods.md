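# Methods

`mamseg` segments mammograms into background, breast and pectoral muscle
with a U-Net, and ships everything around that model: Otsu-based mask
initialization, the training augmentation stack, class-weighted losses with
hyperparameter selection, dice/detection evaluation with group statistics,
and a synthetic phantom generator that makes the whole pipeline testable at
desk scale. This note records the model, its assumptions, and the design
choices that were genuinely open.

## Segmentation model

The network is a classic U-Net. The encoder applies `depth` scales of two
3×3 convolutions (ReLU) followed by 2×2 max pooling; filters start at
`base_filters` and double per scale (the full-scale default, depth 4 / base
64, gives encoder widths 64–1024). Each decoder scale applies bilinear ×2
upsampling, a 1×1 convolution halving the channels, concatenation with the
matching encoder skip, and two 3×3 convolutions. The head is dropout, a 1×1
convolution to 3 channels, and a per-pixel softmax. Weights are
Kaiming-uniform initialized (bound √(6/fan_in)); biases start at zero.

Open choices and how they were resolved:

* **Padding.** Convolutions are same-padded so predictions keep the input
  size; the pixel-level evaluation needs full-size output. Inputs of
  arbitrary size are zero-padded to the next multiple of 2^depth and the
  prediction cropped back.
* **No batch normalization** — the architecture is deliberately plain.
* **Backend.** The network, its initialization, dropout and the Adam
  optimizer are implemented directly in numpy (`mamseg._nn`) with explicit
  forward/backward passes. Convolutions use an im2col/GEMM formulation; the
  input gradient is computed as a full convolution with the
  channel-transposed, 180°-rotated kernel. Every layer's backward pass is
  verified against float64 numeric differentiation in the test suite.
  Float32 is used throughout training.
* **Ties.** Argmax decoding breaks exact probability ties toward the lower
  class index.

## Losses

Two pixel-wise losses address the pectoral class imbalance, both built on
the per-class target probability

    p_t,c = p_c       if y = c
            1 − p_c   otherwise,

so every class contributes a term at every pixel:

* weighted cross-entropy: `L = −Σ_c α_c log p_t,c`
* weighted focal loss:  `L = −Σ_c α_c (1 − p_t,c)^γ log p_t,c`

with class weights `α = [1, 1, α_pectoral]` and focusing exponent `γ` (the
focal default is 2). With this form the focal loss reduces to the weighted
cross-entropy at `γ = 0` — that identity is what the tests assert. Losses
are averaged over pixels (crop-size invariant); `log` is clamped at 1e-12.
The gradient with respect to the logits is obtained analytically through
the softmax Jacobian and cross-checked numerically in the tests.

## Mask initialization

Reference masks are bootstrapped automatically in two steps:

1. **Breast boundary**: global Otsu threshold (256 bins over the observed
   range), then keep the largest connected component and fill interior
   holes. The cleanup stands in for the manual correction a human annotator
   would perform; constant or near-constant images raise a degenerate-input
   error rather than returning an arbitrary mask.
2. **Pectoral muscle (MLO views only)**: a second Otsu pass over
   breast-interior intensities. The split is accepted only if it is
   genuinely bimodal: the two class means must separate by at least 3.2
   pooled within-class standard deviations (`min_separation`). The optimal
   two-way split of a *unimodal* Gaussian yields ≈2.75 on this statistic
   (empirically ≤3.1), so 3.2 rejects splits explainable by smooth texture
   alone while genuine muscle/tissue mixtures score ≈4.5. Among the
   above-threshold pixels, the connected component touching the left image
   edge within the top 25% of rows (images are oriented chest-wall-left) is
   relabeled pectoral. If the gate or the corner rule rejects, the image
   simply has no pectoral label — absence is a valid outcome.

Otsu's threshold is reported as the upper edge of the winning histogram
bin; cuts at empty bins are excluded (they duplicate the previous
partition) and ties break toward the lower bin.

## Augmentation

Training samples pass through, in order: display-window (LUT) jitter of
±5% on center and width, horizontal flip (p = 0.5), rotation uniform in
±5°, elastic deformation (uniform [−1,1] displacement fields smoothed by a
Gaussian of width σ and scaled by α, plus a random affine from corner-point
jitter of scale α_affine), a fixed-size random crop allowed at most
`max_outside` pixels beyond the image (zero/background padded), a gamma
transform with γ ∈ (0.5, 1.5), and Gaussian noise with sd 5% of the image
range, clipped back to [0, 1]. Geometric steps warp image and mask with the
identical transform (linear vs nearest-neighbour); intensity steps are
image-only. Reference values are 512-pixel crops with 64-pixel overshoot,
σ = 100, α = 1, α_affine = 20; pixel-valued parameters scale linearly with
image size in the reduced-scale configurations (e.g. σ = size/5).

Unstated details resolved here: the crop position is uniform over admissible
origins (no breast-centred bias); rotation/elastic fill value is 0, which
is background after windowing; noise is applied last and clipped so the
network input domain stays [0, 1].

## Training

Patient-level splits assign whole patients greedily to test (until ≥
`n_test` images), then validation (≥ `n_val`), remainder to training.
Optimization is Adam; the full-scale defaults are learning rate 1e-4 and
batch size 8. Each epoch ends with a validation pass; training stops when
the epoch-mean validation loss has not strictly improved its running best
for `patience` (default 10) consecutive epochs, and the best-epoch weights
are restored. The grid search trains one model per (loss type, α_pectoral)
pair over α_pectoral ∈ {1, 1.5, 2, 2.5} and selects the highest mean
validation pectoral dice, computed only over images whose truth contains
the pectoral class; ties break by overall dice, then by the lower α.

## Evaluation

Per class, `DICE(c) = 2|ŷ_c ∩ y_c| / (|ŷ_c| + |y_c|)`, computed only when
the truth contains the class (an image without pectoral muscle contributes
no pectoral dice — false-positive pressure is captured by the detection
statistics instead). The overall dice of an image weights the breast and
pectoral dice by their truth pixel counts. Detection outcomes follow the
any-pixel rule: FP = any predicted pectoral pixel with none in truth, FN =
no predicted pectoral pixel when truth has some; FP area is additionally
compared with 1% of the truth breast region. Summaries report mean ±
sample (n−1) standard deviation. Group comparisons use Student t-tests
(unpaired pooled-variance by default, Welch optional; paired for same-image
comparisons), one-way ANOVA with Tukey's HSD post hoc, and Bonferroni
adjustment (α/k) for multiple holdout comparisons.

## Phantom generator

The phantoms emulate the statistical profile of screening mammogram
collections, not their appearance. Geometry: a half-ellipse breast attached
to the left (chest-wall) edge with a smoothed-noise boundary wobble; MLO
breasts are taller, sheared, and reach the top-left corner; CC breasts are
vertically centred. The pectoral muscle is present with probability 0.99
(MLO) / 0.28 (CC) and occupies a breast-area fraction drawn from
Normal(0.21, 0.14) (MLO) / Normal(0.04, 0.03) (CC), clipped to (0.005,
0.9) with fallback to the mean after 100 rejections. The region itself is
carved by thresholding a monotone corner field at the quantile matching the
drawn fraction — a wedge from the top-left corner (MLO) or a thin
chest-wall half-ellipse (CC) — so the realized area matches the draw to
about a pixel and truth masks are exact by construction.

Rendering: a tissue map (breast 0.52 ± 0.08 smoothed texture, pectoral
0.85 ± 0.04) is passed through a vendor style — gain, background offset,
gamma, noise, optional polarity inversion, optional bright film
labels/edges. The pectoral/breast contrast is deliberately large relative
to the texture so that Otsu-based initialization is meaningful on this
data, mirroring the real situation where the muscle is distinctly brighter
than fibroglandular tissue. The paired raw rendering is attenuation-like:
bright unattenuated background, darker dense tissue, compressed contrast —
the opposite display polarity, which is exactly why a model trained only on
processed images collapses on raw input. Raw and processed renderings share
one truth mask.

What the phantoms do **not** model: anatomy (no ducts, vessels, lesions or
calcifications), x-ray physics, scanner blur/heel effects, or burned-in
annotations. Passing phantom benchmarks therefore demonstrates that the
pipeline's machinery is correct and that its experimental contrasts point
in the right direction; it does not certify clinical-grade accuracy on real
mammograms.

## Reduced-scale benchmark configurations

CPU-scale reference experiments (`mamseg.benchmarks`) fix these problem
sizes:

* **Segmentation benchmark**: depth-3/base-8 U-Net, 200 processed training
  phantoms at 128×128 from two vendor styles, 32 validation / 50 test
  images on disjoint patients, cross-entropy with α_pectoral = 2, Adam at
  2e-3, batch 4, ≤20 epochs with patience 10.
* **Raw-inclusion benchmark**: the same model at 64×64, 80 training
  phantoms, ≤50 epochs at 2.5e-3 with a 25-epoch floor before early
  stopping may fire (mixed raw/processed training spends its first epochs
  in a plateau that the patience rule would otherwise mistake for
  convergence); one arm trains on processed only, the other adds the raw
  renderings as independent samples sharing the mask.
* **Style-holdout benchmark**: 64×64, ≤20 epochs; an adversarial round
  holds an inverted-contrast style out of training, and a null round holds
  out one of two identically parameterized styles.

Reduced-width models use dropout 0.1 before the head instead of the
full-scale 0.5: with only 8 feature channels, 0.5 dropout removes half the
classifier's input and mixed raw/processed training fails to converge; at
the reference width of 64 channels the same rate is mild regularization.
Batch size 4 and the raised learning rates compensate for the small cohort
(more updates per epoch). These are scaling choices for the small
configuration, not recommendations for full-scale training.

## Known limitations

* Single-threaded numpy training is ~100× slower than a GPU framework;
  the package is built for method development and testing, not large-scale
  training.
* The raw-image normalization applied before the network (min–max to
  [0, 1], optional log toggle left off) is a convention; acquisition
  metadata-driven normalization is out of scope.
* VOI LUT handling reduces every window description to a linear
  (center, width) ramp; explicit LUT tables and sigmoid functions are
  approximated by their equivalent linear window.
* Phantom realism limits are listed above; in particular CC-view pectoral
  detection at phantom scale is noisy because CC pectorals are tiny
  (≈4% of the breast area) at 128×128.
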