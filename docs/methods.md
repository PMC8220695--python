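# Methods

## Problem and model

`floramet` addresses fine-grained, open-set identification of flower
cultivars from single-flower top-view images. A convolutional feature
extractor followed by a fully connected layer maps an image patch to a
d-dimensional embedding `f(x)`. Training jointly minimizes

* the **L2-softmax loss**: softmax cross-entropy on logits `Wᵀf(x) + b`
  computed after the embedding is rescaled to a fixed norm α
  (`‖f(x)‖₂ = α`). Fixing the norm removes the "easy" way of reducing
  cross-entropy by inflating feature magnitude and forces angular
  discrimination;
* the **center loss** `L_C = ½ Σ ‖f(x_i) − c_{y_i}‖²`, which pulls each
  embedding toward a learned per-class center and thereby shrinks
  intra-class spread. Centers are not free parameters of the optimizer;
  after every mini-batch each observed class center moves by
  `−lr · Σ_{y_i=j}(c_j − f_i)/(1 + n_j)` (damped by the per-batch class
  count `n_j`, `lr` = 0.5 by default), which keeps centers stable when a
  class appears only a few times per batch. Centers are initialized at
  zero and live in the same α-scaled space as the features the losses see;
  they are not renormalized.

The total objective is `L = L_S + λ·L_C` with λ = 1 by default; λ = 0
recovers plain L2-softmax training ("Model S", vs "Model C" with the center
term). Mini-batches use P-K sampling — P classes drawn without replacement,
then K images per class (with replacement only when a class holds fewer
than K records) — so every batch carries within-class positives for `L_C`.
An epoch is ⌊N/(P·K)⌋ batches.

**Center-gradient reduction.** `L_S` is a batch mean while Eq.-style `L_C`
is a batch sum, so the raw gradient of `λ·L_C` on each feature,
`λ(f_i − c_{y_i})`, is effectively M times stronger than the softmax term.
In our experiments this freezes features to their centers and stalls
training at λ = 1 (training Top-1 ≈ 0.57 after 30 epochs versus 1.0 for
λ = 0). The training step therefore averages the center gradient over the
batch — it backpropagates `dL/df_i = dL_S/df_i + (λ/M)(f_i − c_{y_i})` — so
the balance expressed by λ is independent of the P-K batch size. The
*reported* `L_C` and `L = L_S + λL_C` keep the sum convention; only the
descent direction is rescaled, which is equivalent to a batch-size-
dependent reparameterization of λ. With this choice λ = 1 reproduces the
expected behavior (equal Top-1, strongly compacted classes).

At test time embeddings are extracted with deterministic center-crop
preprocessing, tapped *before* the α rescaling, and unit-normalized. A pair
is scored by cosine similarity; for unit vectors squared Euclidean distance
equals `2 − 2s`, so the two metrics are interchangeable (asserted to 1e−9
in the tests).

## Dataset construction

The pipeline mirrors how real cultivar collections are prepared:

1. **Balancing**: classes with fewer than `per_class` original images
   (default 20) are dropped; survivors are subsampled to exactly
   `per_class` originals and relabeled contiguously. Although one source
   protocol is worded as selecting from already-augmented images, only
   balancing *originals first* reproduces all published collection sizes
   (56 × 20 × 10 = 11 200; 77 × 20 × 10 = 15 400), so that order is
   implemented.
2. **Crop augmentation**: each original is expanded into `factor` (default
   10) random square crops, side fraction drawn from [0.5, 0.9] of the
   short side (the sources state only that patches carry local
   information; the range is configurable), saved as PNG. Originals are
   not retained, so counts multiply exactly.
3. **Splits**: class-disjoint (open-set verification; e.g. 100 train / 26
   held-out cultivars) or within-class stratified 80/20 with round-half-up
   per class and at least one train and one test record each. Cropping
   happens *after* the class-disjoint split so no held-out-class pixels
   influence training.
4. **Preprocessing**: bilinear resize to 256, then a 224 crop — random
   during training, center at test time for determinism (desk-scale runs
   use 72 → 64 with the same geometry). Values are scaled to [0, 1].

## Verification protocol

From a test manifest, `n_pos` same-class and `n_neg` different-class
unordered pairs (2600 + 2600 at reference scale) are sampled uniformly
without duplicates. Scores are thresholded; the threshold is chosen by
stratified 10-fold cross-validation — an exhaustive accuracy-maximizing
search over score midpoints on nine folds, evaluated on the tenth (the
face-verification convention; the sources do not spell the selection out).
ROC curves and trapezoidal AUC are computed over the pooled score set.
Top-k accuracy uses classifier logits with ties broken toward the lowest
class index. Distance diagnostics are five-number summaries of all
intra-/inter-class Euclidean distances between unit embeddings, and the
2-D view is a seeded t-SNE (perplexity 30, 1000 iterations, PCA init);
class centers, when supplied, are projected jointly and drawn as "×".

## Synthetic data generator

Real collections are not redistributable, so the generator emulates the
two cues that drive cultivar confusions: **color** and **petal
morphology**. A class is a parametric radial shape — a central disc plus
`petal_count` cosine lobes at the class hue — and a palette guarantees any
two classes differ by a minimum hue separation or by petal count.
Instances jitter in rotation (uniform), scale (±10%), brightness (±10%)
and per-pixel noise, each driven by a seed derived from (global seed,
class, instance), so datasets are reproducible record by record and
bit-exact as PNG. Backgrounds are uniform gray (controlled imaging rig) or
low-frequency colored clutter (field photographs).

What the generator does *not* emulate: photorealistic texture, occlusion,
lighting gradients, multi-flower scenes, viewpoint changes, or the
within-class morphological drift of real cultivars. Passing tests
therefore demonstrate that the pipeline's machinery (losses, sampling,
protocol, metrics) behaves as specified on separable-by-construction
classes — not that the reference accuracies on real collections are
reproduced, which would require the original images and GPU-scale training
of ResNet-class backbones. Accordingly only the compact `tiny_ref`
backbone (four stride-2 conv-ReLU blocks, global average pooling) is
trainable here; ResNet/DenseNet ids raise a clear error.

## Desk-scale study conditions

The behavioral experiments use: 16 synthetic classes (12 train / 4
held-out), 20 originals per class, 10× crops (2400 training patches),
64-px renders with 72 → 64 preprocessing, a 32-D embedding over channels
(8, 16, 32, 64), P = 6, K = 5, 10 epochs of Adam at lr 0.001 (step decay
×0.1 every 10 epochs, i.e. constant within a 10-epoch run), 600 + 600
held-out pairs. These sizes were chosen once as the smallest configuration
on which the qualitative effects are unambiguous; under them the package
measures (seeds 1/7/42 give the same picture): held-out-class pair AUC
1.0, 10-fold mean accuracy 1.0, training Top-1 1.0 for both λ = 1 and
λ = 0, intra-class median distance ≈ 0.035 with center loss versus
≈ 0.20–0.26 without (ratio ≈ 0.14–0.18), and t-SNE silhouette ≈ 0.93 —
the open-set generalization and intra-class compaction the joint objective
is designed to produce.

## Numerical choices and edge cases

* Zero-norm feature rows are rejected (α rescaling and cosine similarity
  are undefined there); the embedding FC bias makes them non-generic.
* He initialization is fan-in Gaussian, biases zero, fully seeded;
  `build_model` initializes from `config.seed` so weights never depend on
  external checkpoints.
* Two seeded runs agree exactly on the first step's loss; full-run bitwise
  equality across BLAS implementations is not promised.
* The classifier bias `b` is kept (initialized to zero) as the loss is
  printed with it; `use_bias=False` is available since the L2-softmax
  formulation is often used without it.
* ROC ties are grouped per threshold, giving AUC = 0.5 for constant
  scores; the threshold search returns the lowest maximizing midpoint.
* `round`-half-up is used for split sizes to avoid banker's-rounding
  surprises.

## Known limitations

* The hand-written NumPy backbone is CPU-bound; it is a vehicle for
  testing the method end to end, not a production trainer.
* Center loss only compacts classes; it has no inter-class repulsion term,
  so overlapping classes must be separated by the softmax term alone.
* Pair sampling is uniform; hard-negative mining is out of scope.
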