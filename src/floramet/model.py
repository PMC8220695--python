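"""Embedding network, He initialization, and the seeded training loop.

The architecture is backbone feature extractor -> fully-connected layer to a
d-dimensional embedding -> norm-alpha rescaling -> fully-connected classifier.
During training the classifier consumes the alpha-scaled embedding (the
L2-softmax constraint) and the center loss acts in the same alpha-scaled
space; at test time the embedding is tapped before the rescaling and
unit-normalized for verification and diagnostics.

Only the compact ``tiny_ref`` backbone — a four-block strided convnet defined
here — is trainable in this package; it is small enough to learn separable
synthetic flower classes on one CPU in minutes. ResNet/DenseNet backbone ids
are recognized but unavailable in this build and raise
:class:`BackboneUnavailableError`.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from PIL import Image

from . import nn
from .data import BatchSpec, DatasetManifest, pk_batches, preprocess
from .losses import (
    ClassCenters,
    EmbeddingBatch,
    LossConfig,
    center_loss_and_grad,
    l2_normalize_scale,
    softmax_loss_and_grad,
    total_loss,
    update_centers,
)

KNOWN_BACKBONES = ("tiny_ref", "resnet18", "resnet50", "densenet121")


class BackboneUnavailableError(RuntimeError):
    """Raised for architecture ids this build cannot construct."""


@dataclass
class ModelConfig:
    """Network and optimization settings.

    Full-scale defaults follow the reference protocol: 128-D embedding, no
    pretraining, He initialization, Adam at lr 0.001 with step decay (x0.1
    every ``lr_step`` epochs), 30 epochs, 256 -> 224 crop preprocessing.
    Desk-scale runs shrink ``input_size``/``epochs``/``embed_dim`` instead of
    changing the procedure.
    """

    n_classes: int = 0
    backbone: str = "tiny_ref"
    embed_dim: int = 128
    pretrained: bool = False
    init: str = "he"
    optimizer: str = "adam"
    lr: float = 0.001
    lr_decay: float = 0.1
    lr_step: int = 10
    epochs: int = 30
    seed: int = 0
    input_size: int = 224
    resize_to: int = 256
    channels: tuple[int, ...] = (16, 32, 64, 128)

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.backbone not in KNOWN_BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.pretrained:
            raise ValueError("pretrained weights are not supported; the model "
                             "is trained from He-initialized random weights")
        if self.init != "he" or self.optimizer != "adam":
            raise ValueError("only he initialization and adam are supported")


@dataclass
class TrainLog:
    """Per-epoch means of L, L_S, L_C and training Top-1."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.epochs.append(dict(kw))

    def to_csv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        pd.DataFrame(self.epochs).to_csv(path, index=False)


class EmbeddingModel:
    """Backbone -> embedding FC -> L2Scale(alpha) -> classifier FC."""

    def __init__(self, config: ModelConfig, loss_config: LossConfig):
        self.config = config
        self.loss_config = loss_config
        chans = config.channels
        blocks: list[nn.Layer] = []
        prev = 3
        for c in chans:
            blocks.append(nn.Conv2d(prev, c, ksize=3, stride=2, pad=1))
            blocks.append(nn.ReLU())
            prev = c
        blocks.append(nn.GlobalAvgPool())
        self.backbone = nn.Sequential(blocks)
        self.embed_fc = nn.Linear(prev, config.embed_dim)
        self.l2scale = nn.L2Scale(loss_config.alpha)
        self.classifier = nn.Linear(
            config.embed_dim, config.n_classes, use_bias=loss_config.use_bias
        )
        self.centers = ClassCenters.zeros(config.n_classes, config.embed_dim)

    # --- forward passes -------------------------------------------------
    def embed_raw(self, x: np.ndarray) -> np.ndarray:
        """Embedding before the alpha constraint; x is NCHW in [0, 1]."""
        return self.embed_fc.forward(self.backbone.forward(x))

    def embed_scaled(self, x: np.ndarray) -> np.ndarray:
        return self.l2scale.forward(self.embed_raw(x))

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.classifier.forward(self.embed_scaled(x))

    def classifier_params(self):
        from .losses import ClassifierParams

        return ClassifierParams(self.classifier.W, self.classifier.b)

    def params(self):
        return (
            self.backbone.params()
            + self.embed_fc.params()
            + self.classifier.params()
        )

    def zero_grad(self) -> None:
        for _, obj, _, gname in self.params():
            getattr(obj, gname).fill(0.0)

    # --- persistence ----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"centers": self.centers.centers}
        for i, (_, obj, vname, _) in enumerate(self.params()):
            out[f"p{i}_{vname}"] = getattr(obj, vname)
        return out

    def load_state_arrays(self, arrays) -> None:
        self.centers = ClassCenters(np.array(arrays["centers"]))
        for i, (_, obj, vname, _) in enumerate(self.params()):
            setattr(obj, vname, np.array(arrays[f"p{i}_{vname}"]))


def build_model(config: ModelConfig, loss_config: LossConfig | None = None) -> EmbeddingModel:
    """Construct the network chain for ``config``.

    Raises :class:`BackboneUnavailableError` for the ResNet/DenseNet ids —
    this build ships only the self-contained ``tiny_ref`` backbone.
    """
    if config.backbone != "tiny_ref":
        raise BackboneUnavailableError(
            f"backbone {config.backbone!r} requires a deep-learning runtime "
            "that this build does not include; use 'tiny_ref'"
        )
    if config.n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    model = EmbeddingModel(config, loss_config or LossConfig())
    # initial weights depend only on the seed (never on a checkpoint)
    return he_initialize(model, config.seed)


def he_initialize(model: EmbeddingModel, seed: int) -> EmbeddingModel:
    """He (fan-in) normal initialization of all conv/FC weights, zero biases."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4E17]))
    for layer in model.backbone.layers:
        if hasattr(layer, "he_init"):
            layer.he_init(rng)
    model.embed_fc.he_init(rng)
    model.classifier.he_init(rng)
    return model


class _ImageCache:
    """Decoded, pre-resized float arrays kept in memory for fast crops."""

    def __init__(self, manifest: DatasetManifest, resize_to: int):
        self.arrays: list[np.ndarray] = []
        for path in manifest.paths:
            with Image.open(path) as im:
                im = im.convert("RGB")
                if im.size != (resize_to, resize_to):
                    im = im.resize((resize_to, resize_to), Image.BILINEAR)
                self.arrays.append(np.asarray(im, dtype=np.float32) / 255.0)

    def crop_batch(self, indices, out_size, rng=None) -> np.ndarray:
        """Stack of NCHW crops: random offsets when rng is given, else center."""
        out = np.empty((len(indices), 3, out_size, out_size), dtype=np.float64)
        for k, i in enumerate(indices):
            arr = self.arrays[i]
            margin = arr.shape[0] - out_size
            if rng is not None:
                r = int(rng.integers(0, margin + 1))
                c = int(rng.integers(0, margin + 1))
            else:
                r = c = margin // 2
            out[k] = arr[r : r + out_size, c : c + out_size, :].transpose(2, 0, 1)
        return out


def _remap_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary distinct labels onto 0..C-1 (ascending order)."""
    uniq = np.unique(labels)
    lut = {int(v): i for i, v in enumerate(uniq)}
    return np.array([lut[int(v)] for v in labels], dtype=np.int64), uniq


def train(
    model: EmbeddingModel,
    train_manifest: DatasetManifest,
    batch_spec: BatchSpec,
    loss_config: LossConfig,
    model_config: ModelConfig,
    progress: bool = False,
) -> tuple[EmbeddingModel, TrainLog]:
    """P-K mini-batch training under L = L_S + lambda * L_C.

    Each step: random-crop preprocessing -> forward -> alpha rescaling ->
    L2-softmax + center loss -> backprop through classifier, embedding FC and
    backbone -> Adam update -> damped class-center update. Fully seeded; the
    log records per-epoch mean losses and training Top-1.
    """
    if len(train_manifest) == 0:
        raise ValueError("empty training manifest")
    labels, uniq = _remap_labels(train_manifest.labels)
    if len(uniq) != model.config.n_classes:
        raise ValueError(
            f"model expects {model.config.n_classes} classes, manifest has "
            f"{len(uniq)}"
        )
    if len(uniq) < batch_spec.P:
        raise ValueError("P exceeds the number of available classes")
    cache = _ImageCache(train_manifest, model_config.resize_to)
    opt = nn.Adam(model.params(), lr=model_config.lr)
    crop_rng = np.random.default_rng(
        np.random.SeedSequence([model_config.seed, 0xC509])
    )
    log = TrainLog()
    iterator = range(model_config.epochs)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="epochs")
    for epoch in iterator:
        opt.lr = model_config.lr * (
            model_config.lr_decay ** (epoch // model_config.lr_step)
        )
        batches = pk_batches(
            labels, batch_spec, seed=int(model_config.seed + 1000 + epoch)
        )
        sums = {"L": 0.0, "L_S": 0.0, "L_C": 0.0}
        correct = 0
        seen = 0
        for batch_idx in batches:
            y = labels[batch_idx]
            x = cache.crop_batch(batch_idx, model_config.input_size, rng=crop_rng)
            model.zero_grad()
            feats = model.backbone.forward(x)
            emb = model.embed_fc.forward(feats)
            emb_a = model.l2scale.forward(emb)
            eb = EmbeddingBatch(emb_a, y)
            params = model.classifier_params()
            l_s, dF_s, dW, db = softmax_loss_and_grad(eb, params)
            l_c, dF_c = center_loss_and_grad(eb, model.centers)
            l_tot = total_loss(l_s, l_c, loss_config.lam)
            # gradient w.r.t. the alpha-scaled embedding; the center term is
            # averaged over the batch so that the balance between the two
            # losses does not depend on the P-K batch size (the softmax term
            # is already a batch mean)
            dF = dF_s + (loss_config.lam / eb.M) * dF_c
            model.classifier.dW += dW
            if model.classifier.use_bias:
                model.classifier.db += db
            d_emb = model.l2scale.backward(dF)
            d_feats = model.embed_fc.backward(d_emb)
            model.backbone.backward(d_feats)
            opt.step()
            model.centers = update_centers(model.centers, eb, loss_config.center_lr)
            logits = emb_a @ params.weights + params.bias
            correct += int((logits.argmax(axis=1) == y).sum())
            seen += len(y)
            sums["L"] += l_tot
            sums["L_S"] += l_s
            sums["L_C"] += l_c
        nb = max(1, len(batches))
        log.append(
            epoch=epoch,
            L=sums["L"] / nb,
            L_S=sums["L_S"] / nb,
            L_C=sums["L_C"] / nb,
            top1=correct / max(1, seen),
            lr=opt.lr,
        )
    return model, log


def extract_embeddings(
    model: EmbeddingModel, manifest: DatasetManifest, batch_size: int = 256
) -> EmbeddingBatch:
    """Deterministic unit-length embeddings, one row per manifest record.

    Uses center-crop preprocessing and taps the embedding before the alpha
    rescaling; rows are normalized to unit length for verification and
    distance diagnostics.
    """
    feats = []
    cfg = model.config
    for start in range(0, len(manifest), batch_size):
        chunk = manifest.records[start : start + batch_size]
        x = np.empty((len(chunk), 3, cfg.input_size, cfg.input_size))
        for k, rec in enumerate(chunk):
            with Image.open(rec.path) as im:
                arr = preprocess(
                    im.convert("RGB"), out_size=cfg.input_size,
                    resize_to=cfg.resize_to, train=False,
                )
            x[k] = arr.transpose(2, 0, 1)
        feats.append(model.embed_raw(x))
    F = np.concatenate(feats, axis=0) if feats else np.zeros((0, cfg.embed_dim))
    return EmbeddingBatch(l2_normalize_scale(F, 1.0), manifest.labels)


def predict_logits(
    model: EmbeddingModel, manifest: DatasetManifest, batch_size: int = 256
) -> np.ndarray:
    """Classifier logits under deterministic center-crop preprocessing."""
    out = []
    cfg = model.config
    for start in range(0, len(manifest), batch_size):
        chunk = manifest.records[start : start + batch_size]
        x = np.empty((len(chunk), 3, cfg.input_size, cfg.input_size))
        for k, rec in enumerate(chunk):
            with Image.open(rec.path) as im:
                arr = preprocess(
                    im.convert("RGB"), out_size=cfg.input_size,
                    resize_to=cfg.resize_to, train=False,
                )
            x[k] = arr.transpose(2, 0, 1)
        out.append(model.logits(x))
    return np.concatenate(out, axis=0)


def save_checkpoint(model: EmbeddingModel, path: str | os.PathLike) -> None:
    """Model parameters + centers as NPZ, with configs in a JSON sidecar."""
    path = os.fspath(path)
    np.savez(path, **model.state_arrays())
    with open(path + ".json", "w") as fh:
        cfg = asdict(model.config)
        cfg["channels"] = list(cfg["channels"])
        json.dump({"model": cfg, "loss": model.loss_config.to_dict()}, fh, indent=1)


def load_checkpoint(path: str | os.PathLike) -> EmbeddingModel:
    path = os.fspath(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    meta["model"]["channels"] = tuple(meta["model"]["channels"])
    config = ModelConfig(**meta["model"])
    model = build_model(config, LossConfig.from_dict(meta["loss"]))
    with np.load(path if path.endswith(".npz") else path + ".npz") as arrays:
        model.load_state_arrays(arrays)
    return model
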