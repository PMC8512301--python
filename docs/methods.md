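# Methods

## Problem setting

Biological image collections — plankton imagery is the motivating case —
contain many images on which trained annotators disagree: image quality is
limited and genuinely intermediate morphologies exist. Averaging several
annotations yields a *fuzzy* label, a probability vector `l ∈ (0,1)^k` over
the `k_GT` classes; an image is *certain* when all annotations agree (`l`
one-hot). Standard semi-supervised classifiers force every image into one
class and handle such data poorly.

The framework implemented here treats certainly-labeled images as the
supervised set `X_l` and fuzzy images as unlabeled data `X_u`, and trains a
shared backbone with two families of linear softmax heads:

* **normal heads** with `k_GT` outputs — ordinary classifiers;
* **overclustering heads** with `k > k_GT` outputs — they spread the data
  over more clusters than classes so that substructure inside ambiguous
  classes becomes visible. A surjective cluster→class map obtained by
  majority vote makes them comparable to classifiers.

Each family has several independently initialized copies (default 5) sharing
the backbone; training averages their losses, evaluation reports the copy
with the best validation score.

## Inputs and losses

From each anchor image `x` a triplet is built: `x1` an augmentation of `x`;
`x2` a *supervised augmentation* (an augmentation of a different image with
the same label) when a label exists, otherwise a second augmentation of `x`;
and `x3` an *inverse example* — an augmentation of an image with a different
label (labeled case) or of a random other image (unlabeled case).

The loss is `L = λ_s·L_s + λ_u·L_u` with `λ_s = λ_u = 1`:

* `L_s` for normal heads is cross-entropy,
  `0.5·CE(y, Φ(x1)) + 0.5·CE(y, Φ(x2))`;
* `L_s` for overclustering heads is the **inverse cross-entropy**
  `CE⁻¹(p, q) = −Σ_c p(c)·ln(1 − q(c))`, applied as
  `0.5·CE⁻¹(Φ(x1), Φ(x3)) + 0.5·CE⁻¹(Φ(x2), Φ(x3))`. It pushes the outputs
  of differently-labeled images onto disjoint clusters and is zero exactly
  when the supports are disjoint. `1 − q` is deliberately not renormalized:
  renormalizing would penalize a prediction that spreads over two clusters
  against a one-hot prediction on a third (correct behaviour), and would
  implicitly minimize the entropy of `p`;
* `L_u` for both families is the negated mutual information `−I(z, z′)` of
  the symmetrized joint distribution
  `P = (Q + Qᵀ)/2`, `Q = (1/n) Σ_i Φ(x1_i)·Φ(x2_i)ᵀ` estimated per batch.
  Maximizing `I` pulls the two views of an image into the same cluster while
  keeping cluster marginals spread.

Unlabeled data is capped at a fixed fraction `r` of every batch
(default `r = 0.5`); unlabeled anchors are drawn from a seeded rotation over
reshuffled permutations, so the whole pool is covered across epochs. Every
selected anchor appears 3 times per batch with fresh augmentations
(repetitions stabilize the batch estimate of the joint distribution).

## Training schedule and variants

Head families are trained in alternation, one family per epoch. The full
framework (`foc`) runs three phases: a **warm-up** with `λ_s = 0` and no
supervised augmentations (the mutual-information pretext task), a
**heads-only** phase with a frozen backbone at a higher learning rate, and
the **main** phase training everything. `foc-light` sets `λ_u = 0`, skips
the warm-up and the repetitions, and uses no unlabeled data (no remaining
loss term consumes it). `warmup-only` runs the pretext task alone.

With both weights zero no parameter changes (checked bitwise). Cross-entropy
is backpropagated with the fused softmax gradient `(p − y)`; the clamped
probability-space gradient can vanish when a head saturates on the wrong
class (observed in the heads-only phase on harder label configurations) and
is kept only as a reference implementation.

## The SYN-CE benchmark

The synthetic benchmark draws a single colored ellipse ("bubble") on a black
64×64 canvas. Two continuous factors define the class: hue (anchors red 0°,
green 120°, blue 240°) and major/minor axis ratio (anchors circle 1,
ellipse 2). The soft label is the outer product of a color distribution
(piecewise-linear in hue between the two adjacent primaries, wrapping
through 360°) and a geometry distribution (linear in the ratio); it is
one-hot exactly at the anchors. Center, size (major axis 0.3–0.6 of the
canvas) and rotation are uniform; fuzzy samples draw hue at least 5° away
from the primaries and ratio at least 0.05 away from the endpoints, so
their labels are never one-hot. Edges are hard (no anti-aliasing); the
block-mean downsampling used for training softens them.

Each of the train / validation / unlabeled splits holds 1800 certain and
1000 fuzzy images, drawn independently. Three labeling modes emulate
annotation regimes: *ideal* (hard label = argmax of the soft label for all
images), *real* (hard label sampled from the soft label — one noisy
annotation), *fuzzy* (only certain images keep labels; fuzzy images are
consumed as unlabeled data). Evaluation truth on the unlabeled split is
always the most likely class of the soft label.

What the generator does **not** emulate: image noise, occlusion, class
imbalance, more than one object, or annotator biases that correlate across
images. Passing the scaled-down experiments shows the framework separates
product-form fuzzy factors at desk scale, not that it reproduces the
published full-scale numbers on real plankton data.

## Desk-scale configuration

All defaults were fixed before the acceptance experiments were finalized and
are the package's own desk-scale choices:

* images are generated at 64×64 and block-mean downsampled to 16×16 for
  training; augmentation is horizontal flip, ±10% translation, a mild
  anisotropic rescale (aspect jitter up to ×1.33, as in standard
  random-resized-crop pipelines) and ×[0.8, 1.2] brightness. Hue jitter is
  deliberately absent: on SYN-CE the hue *is* the class-defining factor;
* the backbone (`shape_color`) runs a 3-layer strided CNN
  (16/32/64 channels, 3×3 kernels, stride 2, flatten) over the *value*
  channel (per-pixel max over RGB) and appends the pooled mean foreground
  color to the features. Shape features are thereby structurally independent
  of hue — the same decoupling motive behind feeding sobel-filtered images
  to networks trained without pretrained weights. With a plain RGB CNN and
  training hues restricted to the three primaries, shape predictions on
  interpolated hues were close to arbitrary (the "tiny_cnn" RGB backbone is
  kept for comparison);
* overclustering heads have k = 30 outputs (5× the 6 classes), 5 copies per
  family; batches hold 252 slots = 84 anchors × 3 repetitions, r = 0.5; an
  epoch is one pass over the labeled pool (an optional cap on batches per
  epoch is available for fixed-compute experiments);
* schedules: `foc` 4 warm-up + 4 heads-only + 60 main epochs; `foc-light`
  60 epochs (42-slot batches, no repetitions). Adam with learning rate
  3e-3 throughout the desk preset — the short schedule needs a faster rate
  than the published full-scale one; the `paper` preset mirrors the
  published schedule (500 + 100 + 500 epochs, 1e-4 with 1e-3 heads-only);
* model selection: after every pair of main-phase epochs the validation
  macro-F1 of each head family's best copy is computed (overclustering heads
  majority-mapped first) and a parameter snapshot is kept per family at its
  own validation optimum; the two families peak at different epochs, and
  separate snapshots keep the selection of the normal heads free of the
  noisier overclustering validation signal. Reported scores evaluate each
  family at its own snapshot; the returned model carries the better
  family's weights.

## Evaluation protocol

Accuracy is micro-averaged (summed confusion counts; for single-label data
this equals the fraction correct and the micro F1). The headline metric is
macro-F1 — the unweighted mean of per-class `F1 = 2TP/(2TP+FP+FN)`; a class
absent from predictions and truths contributes 0. Overclustering heads are
first mapped cluster→class by majority vote; on fuzzy-type data the mapping
is derived on the unlabeled split itself (experts would be in the loop
there), otherwise on the training data; the reference split is
configurable. Clusters empty on the mapping split stay unmapped and count
as errors if they ever predict. The per-head score used both for head
selection and for early-stopping snapshots is validation macro-F1; reported
numbers are unlabeled-split macro-F1 of the validation-selected head, and
the headline is the better of the two families. The expert-consistency
score (fraction of images judged visually consistent with their cluster,
overall and per cluster with population standard deviation) consumes
judgments from a table; it never simulates raters.

## Numerical choices

* logs are clamped: `ln(max(·, 1e-6))` in the cross-entropies, `1e-12`
  inside the mutual information (joint entries scale like 1/k²);
  `0·ln 0 := 0` throughout;
* the MI gradient is the analytic `∂I/∂P_ab = ln P_ab − ln P_a − ln P_b − 1`
  propagated through the symmetrization and the batch average; all gradients
  are finite-difference checked in the test suite;
* ties: argmax everywhere breaks to the lowest index (head selection,
  majority vote, hard-label assignment);
* reproducibility: every random draw derives from `numpy` generators seeded
  from the run seed; two fits with equal seeds produce identical loss
  traces on the same machine.

## Known limitations

* At desk scale the mutual-information objective is the weak link: batch MI
  optimization stalls in cluster-merging local optima (reproducible even on
  linearly separable toy data), so overclustering heads trained from scratch
  stay far from their full-scale quality and the reported headline usually
  comes from the normal heads. With `λ_u = 0` (the light variant) the
  overclustering heads track the normal heads closely — consistent with the
  published observation that the light variant is competitive on fuzzy data.
* The desk backbone's color/shape decoupling is tailored to data whose
  within-class appearance is a color × shape product; it is not a general
  substitute for pretrained features on natural images.
* The `paper` preset reproduces the published schedule but not the published
  backbones (no residual networks or pretrained weights ship with this
  package); applying it to full-scale data is untested here.
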