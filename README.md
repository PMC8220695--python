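# floramet

Metric learning for image-based identification of flower cultivars.

Cultivars of one ornamental species (chrysanthemum, peony, ...) differ only
in fine-grained cues — petal color and petal morphology — and new cultivars
appear constantly, so a closed-set classifier is not enough. `floramet`
trains a convolutional network to map single-flower, top-view image patches
into an embedding space where distance reflects cultivar identity, and then
decides whether two images show the *same* cultivar, including cultivars
never seen in training (open-set verification).

## The objective

The network `f` is supervised jointly by an L2-constrained softmax loss and
a center loss:

```
L   = L_S + λ·L_C
L_S = −(1/M) Σ_i log [ exp(W_{y_i}ᵀ f(x_i) + b_{y_i}) / Σ_j exp(W_jᵀ f(x_i) + b_j) ]
        subject to ‖f(x_i)‖₂ = α  for all i
L_C = ½ Σ_i ‖f(x_i) − c_{y_i}‖₂²
```

where `c_j` is the learned center of class `j`, updated once per mini-batch
with the damped rule `c_j ← c_j − lr·Σ_{y_i=j}(c_j − f(x_i)) / (1 + n_j)`.
Defaults are λ = 1, α = 10, a 128-D embedding, He initialization, Adam at
lr 0.001 with step decay, and P-K mini-batches (P classes × K images, so
every batch contains within-class positives for the center loss).

At test time embeddings are unit-normalized and a pair (x_g, x_p) is scored
by cosine similarity `s = f(x_g)ᵀf(x_p) / (‖f(x_g)‖‖f(x_p)‖)`; for unit
vectors the squared Euclidean distance is `2 − 2s`, so the two scores are
equivalent. Decisions threshold `s`, with the threshold chosen by 10-fold
cross-validation; quality is summarized by ROC/AUC, Top-k accuracy,
intra/inter-class distance summaries and a t-SNE projection.

Because curated cultivar image collections are large and not redistributable,
the package ships a procedural generator of labeled synthetic flower images
(classes differ in hue and petal morphology, instances jitter in rotation,
scale, brightness and noise) so the whole pipeline runs and is tested at
desk scale on one CPU. The trainable backbone is `tiny_ref`, a compact
four-block strided convnet with hand-written gradients defined in this
package.

## Worked example

```python
import numpy as np
import floramet as fm
from floramet import (BatchSpec, LossConfig, ModelConfig, build_model,
                      he_initialize, train, extract_embeddings,
                      make_verification_pairs, verify_pairs, roc_auc,
                      distance_stats)

spec = fm.RenderSpec(image_size=64, global_seed=5)
raw = fm.generate_dataset(16, 20, spec, "scratch/flowers", min_hue_sep=18.0)
balanced = fm.balance_classes(raw, 20, seed=1)
train_m, test_m = fm.split_disjoint_classes(balanced, 12, seed=1)   # 4 held-out classes
aug_train = fm.augment_crops(train_m, 10, "scratch/crops_train", seed=1)
aug_test = fm.augment_crops(test_m, 10, "scratch/crops_test", seed=2)

lc = LossConfig(lam=1.0, alpha=10.0)                 # Model C; lam=0 is Model S
mc = ModelConfig(n_classes=12, embed_dim=32, channels=(8, 16, 32, 64),
                 epochs=10, input_size=64, resize_to=72, seed=3)
model, log = train(he_initialize(build_model(mc, lc), 3),
                   aug_train, BatchSpec(P=6, K=5), lc, mc)
print(round(log.epochs[-1]["top1"], 3))              # 1.0  (training Top-1)

emb = extract_embeddings(model, aug_test)            # unit-normalized, never-seen classes
pairs = make_verification_pairs(aug_test, 600, 600, seed=11)
_, scores = verify_pairs(emb, pairs, 0.0)
flags = np.array([p.same_class for p in pairs])
print(round(roc_auc(scores, flags).auc, 3))          # 1.0  (open-set pair AUC)

stats = distance_stats(extract_embeddings(model, aug_train))
print(round(stats.intra_median, 3))                  # 0.035 (vs ~0.27 with lam=0)
```

The three printed numbers say: the model classifies its 12 training classes
perfectly; pairs of images from the 4 classes it has never seen are verified
essentially without error; and the center loss has pulled same-class
embeddings about 8× closer together than softmax-only training — the
intra-class compaction that motivates the joint objective.

The same pipeline is available from the shell:

```
flora demo --seed 0 --out-root runs     # generate → prepare → train → evaluate → visualize
```

which writes manifests, a checkpoint, `metrics.json` and figures under
`runs/run_seed0/`.

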