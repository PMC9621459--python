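# Methods

## Overview

`skinet` implements an uncertainty-gated two-stage pipeline for skin-lesion
diagnosis. A Bayesian encoder–decoder network segments the lesion; if the
segmentation is trustworthy (low predictive uncertainty) the lesion-focused
image is handed to a Bayesian classifier, otherwise the original image is.
If the classification itself is too uncertain the case is referred for a
human second opinion instead of being diagnosed. Both networks quantify
uncertainty by Monte-Carlo sampling of their predictive posterior, and every
diagnosis carries a saliency map explaining which pixels drove it.

## Posterior sampling and uncertainty

Let s* be a test image and p(y | s*, Ŵ) the network output under weights Ŵ.

* **Epistemic (model) uncertainty** — Monte-Carlo dropout: dropout layers
  stay active at inference and B stochastic passes are averaged,
  μ_e ≈ (1/B) Σ_b p(y | s*, Ŵ_b).
* **Aleatoric (data) uncertainty** — test-time augmentation: V
  label-preserving transforms (horizontal/vertical flips, rotations in
  [−65°, 65°]) are applied with dropout off, μ_a ≈ (1/V) Σ_v p(y | s*_v, Ŵ).
  For segmentation each output map is warped back through the inverse
  geometric transform before averaging so maps stay aligned.
* **Combined** — M passes each with a fresh augmentation *and* a fresh
  dropout mask. The pipeline gates on this mode by default since it captures
  both sources.

The scalar uncertainty is the predictive entropy of the averaged
probability vector, φ = −Σ_n p_n ln p_n (natural log throughout), linearly
normalized to φ_norm ∈ [0, 1]. Default normalization bounds are analytic —
φ_min = 0 and φ_max = ln N for an N-class vector; per-pixel binary entropy
is bounded by ln 2. An empirical mode (min/max over a calibration batch) is
available because the entropy range in practice varies with the number of
Monte-Carlo samples.

A prediction is *certain* iff φ_norm < φ_T; a value exactly at the
threshold counts as uncertain (the gate's strict inequality is on the
certain side). Defaults: φ_T = 0.25 for segmentation, 0.35 for
classification. Crossing certainty with correctness yields the four
categories cc/cu/ic/iu, and the diagnostic accuracy
A(φ_T) = (L_cc + L_iu) / (L_cc + L_cu + L_ic + L_iu) measures how often the
gate does the desirable thing (confident when right, hesitant when wrong).

For segmentation the map→scalar reduction is the mean per-pixel binary
entropy divided by ln 2; an alternative reduction (fraction of pixels with
entropy above ½ ln 2) is available behind a flag. Argmax ties resolve to
the lowest class index. Default sample counts are B = V = M = 20;
the TTA family equals the training augmentation family.

## Networks

**Segmenter — Bayesian MultiResUNet.** MultiRes blocks approximate parallel
3×3/5×5/7×7 filtering with three chained 3×3 convolutions whose output
channels are floor(W/6), floor(W/3), floor(W/2) for W = 1.67·U, concatenated
and fused with a 1×1-convolved residual; all convolutions use batch
normalization and ReLU. Encoder–decoder skips pass through Res paths with
4, 3, 2, 1 residual blocks (32, 64, 128, 256 filters at full width). Four
2× poolings (so input sides must be divisible by 16), a fifth MultiRes
bridge, 2×2 transposed-convolution upsampling, and a final 1×1 convolution
with sigmoid. Dropout (rate 0.5) follows every pooling and every
upsampling step.

**Classifier.** A width-scalable conv/pool CNN (3×3 conv + batch-norm +
ReLU + 2×2 max-pool per stage, channels doubling per stage) with global
average pooling and a softmax head. Dropout insertion points are
configurable; the default places dropout after the last two conv stages and
before the head — a minimal perturbation of features that still yields
Monte-Carlo variance. Full-size pretrained backbones are out of scope; the
dropout contract, not the backbone, is what the pipeline depends on.

**Batch-norm during sampling** stays in evaluation mode (frozen running
statistics) so that dropout is the only stochastic element; mixing batch
statistics across Monte-Carlo passes would confound the epistemic estimate.

**Numerical core.** The networks run on a small reverse-mode automatic
differentiation engine written on numpy (`skinet.nn`): im2col convolution,
non-overlapping 2×2 transposed convolution, max pooling, batch-norm,
dropout and dense layers, verified against central finite differences in
the test suite. Every intermediate tensor retains its gradient after a
backward pass, which is what the saliency methods consume.

## Training

Adam, learning rate 1e-3; pixel-wise binary cross-entropy for the
segmenter and categorical cross-entropy (the standard multi-class extension
of the binary form) for the classifier. No learning-rate schedule, weight
decay or early stopping by default. Data order, weight initialization and
dropout masks all derive from explicit seeds, so training runs are exactly
reproducible. Validation split: seeded 80/20 shuffle.

## Saliency

* **Guided Backpropagation** — input gradient where every ReLU's backward
  signal is zeroed if either the forward input or the incoming gradient is
  negative; channels reduced by sum of absolute values.
* **Grad-CAM** — neuron-importance weights β_a = (1/G) Σ_kl ∂z_e/∂F^a_kl
  (global average pooling of the class-score gradient over the target conv
  layer, by default the last one), heatmap ReLU(Σ_a β_a F^a), bilinearly
  upsampled to input resolution.
* **Guided Grad-CAM** — the elementwise product of the two maps above.
* **Integrated gradients** — midpoint-rule path integral of gradients from
  a baseline to the input, scaled by (input − baseline); channel-summed
  signed, so attributions satisfy the completeness axiom up to quadrature
  error (default 64 steps).
* **XRAI** — integrated gradients averaged over all-black and all-white
  baselines; Felzenszwalb over-segmentation at three scales; regions merged
  greedily by attribution gain per unit novel area until the image is
  covered, ties broken by region index.

Saliency is computed for the model's *predicted* class, since explanations
accompany predictions.

**Bokeh evaluation.** Blur the image with a Gaussian kernel (default sigma
= 5% of the shorter side), restore the top fraction (default 10%) of pixels
ranked by the saliency map, re-classify, and score accuracy against the
labels. At top fraction 1 this reproduces plain accuracy exactly, which
anchors the harness.

## Pipeline defaults

Segmentation input 224×224, classification input 450×600 (both bicubic,
[0, 1] range; desk-scale runs shrink both proportionally). Handoff image:
mask-multiplied then cropped to the binarized mask's bounding box dilated
by a 10% margin and resized (pure masking available); an empty mask
degrades to the original image with a warning. Batch evaluation always
records the classifier's underlying prediction — also for referred cases —
so the four-category tally covers every sample; prediction accuracy is
reported both over all samples and over diagnosed samples only.

## Synthetic data

The generator emulates the statistical structure the pipeline needs, not
dermoscopic realism: a skin-tone background with a gentle illumination
gradient, one elliptical lesion per image with class-dependent color and
mottled texture (7-class default palette whose pairwise color distances
exceed 3× the pixel noise, guaranteeing a learnable label signal),
pixel-exact elliptical masks, i.i.d. Gaussian pixel noise, and two artifact
types drawn over the image but never into the mask: dark curved hair
strokes (quadratic Bézier, ~2 px wide) and bright circular sweat-droplet
highlights. Artifacts occlude evidence and therefore raise predictive
entropy, which is exactly the mechanism the referral gate is meant to
exploit; their per-type probability (`artifact_rate`, default 0.3) makes
gating behaviour reproducible on demand.

What passing tests on this data do **not** show: robustness to real
dermoscopic variation (lesion morphology, vignetting, rulers, color
calibration), to class-imbalanced data, or to label noise. The generator's
classes are separable by construction; real diagnostic categories are not.

Offline augmentation mirrors the training-time family: flips and rotations
uniform in [−65°, 65°], masks resampled nearest-neighbor so they stay
binary, rotation fill equal to the background skin tone, and the expansion
factor (copies per sample) a parameter.

## Desk-scale study conditions

The end-to-end suite trains on 7 classes × 200 samples at 32×32 (the
smallest side the four-pooling segmenter accepts), classifier base width 8
(15 epochs), segmenter base width 8 trained on a 100-sample subset (12
epochs), noise SD 0.06, artifact rate 0.3. These sizes make the whole
suite a few minutes of CPU work while leaving enough residual difficulty
(noise + artifacts) that the uncertain subset has measurably higher error —
the qualitative pattern the gate exists to exploit.

## Known limitations

* The autodiff core is stride-1/2×-pool only — sufficient for these
  architectures, not a general tensor library.
* Aleatoric TTA rotation uses nearest-edge padding at borders; inverse
  warping of probability maps is bilinear, so map-space posteriors blur
  slightly near edges.
* The Jaccard formula is exposed as similarity with an explicit
  `as_distance` flag (some sources print the complement form while
  reporting similarity-scale values); both mean-per-image and global-pixel
  aggregations are provided for batch mask evaluation.
* Empty-vs-empty mask pairs define Dice and Jaccard similarity as 1
  (both raters agree there is no lesion).
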