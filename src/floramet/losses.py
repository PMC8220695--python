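"""Joint metric-learning objective: L2-constrained softmax loss + center loss.

The total loss is ``L = L_S + lambda * L_C`` where

* ``L_S`` is softmax cross-entropy over logits ``W^T f(x_i) + b`` computed on
  features constrained to a fixed Euclidean norm alpha (L2-softmax), and
* ``L_C = 1/2 * sum_i || f(x_i) - c_{y_i} ||^2`` pulls each embedding toward
  its learned class center ``c_{y_i}``, shrinking intra-class spread.

Class centers are not trained by gradient descent on ``L``; they follow the
damped per-mini-batch update of the original center-loss formulation,
``c_j <- c_j - lr * sum_{y_i=j}(c_j - f_i) / (1 + n_j)``, which keeps them
stable even when a class appears in a batch only a few times.

All quantities here are plain NumPy; gradients needed by the trainer are
exposed alongside the forward values so the whole stack composes inside the
hand-rolled reverse-mode training step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EmbeddingBatch:
    """An M x d block of feature descriptors with their class labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be an M x d matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on batch size M")
        if self.features.shape[0] < 1:
            raise ValueError("batch must contain at least one sample")

    @property
    def M(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


@dataclass
class ClassifierParams:
    """Last-layer weights W (d x C) and bias b (C,)."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValueError("weights must be d x C")
        if self.bias.shape != (self.weights.shape[1],):
            raise ValueError("bias length must equal the class count C")

    @property
    def n_classes(self) -> int:
        return self.weights.shape[1]


@dataclass
class ClassCenters:
    """C x d matrix of learned class centers in embedding space."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 2:
            raise ValueError("centers must be a C x d matrix")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")

    @classmethod
    def zeros(cls, n_classes: int, dim: int) -> "ClassCenters":
        return cls(np.zeros((n_classes, dim)))

    @property
    def n_classes(self) -> int:
        return self.centers.shape[0]


@dataclass
class LossConfig:
    """Hyperparameters of the joint objective.

    lam balances center loss against L2-softmax (1 by default), alpha is the
    feature-norm constraint (10 by default) and center_lr the damped
    center-update rate.
    """

    lam: float = 1.0
    alpha: float = 10.0
    center_lr: float = 0.5
    use_bias: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 < self.center_lr <= 1):
            raise ValueError("center_lr must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "alpha": self.alpha,
            "center_lr": self.center_lr,
            "use_bias": self.use_bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        return cls(
            lam=float(d.get("lambda", 1.0)),
            alpha=float(d.get("alpha", 10.0)),
            center_lr=float(d.get("center_lr", 0.5)),
            use_bias=bool(d.get("use_bias", True)),
        )


def l2_normalize_scale(features: np.ndarray, alpha: float) -> np.ndarray:
    """Rescale every row to Euclidean norm ``alpha``, preserving direction."""
    features = np.asarray(features, dtype=np.float64)
    norms = np.linalg.norm(features, axis=-1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("cannot normalize a zero-norm feature row")
    return alpha * features / norms


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def softmax_loss(batch: EmbeddingBatch, params: ClassifierParams) -> float:
    """Mean softmax cross-entropy of the true class, from logits W^T f + b.

    When the features were first passed through :func:`l2_normalize_scale`
    this is the L2-softmax loss.
    """
    return softmax_loss_and_grad(batch, params)[0]


def softmax_loss_and_grad(
    batch: EmbeddingBatch, params: ClassifierParams
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss plus gradients w.r.t. features, weights and bias."""
    if batch.labels.min() < 0 or batch.labels.max() >= params.n_classes:
        raise ValueError("label out of range of the classifier")
    F, y = batch.features, batch.labels
    M = batch.M
    logits = F @ params.weights + params.bias
    logp = _log_softmax(logits)
    loss = float(-logp[np.arange(M), y].mean())
    # d(loss)/d(logits) = (softmax - onehot)/M
    dlogits = np.exp(logp)
    dlogits[np.arange(M), y] -= 1.0
    dlogits /= M
    dF = dlogits @ params.weights.T
    dW = F.T @ dlogits
    db = dlogits.sum(axis=0)
    return loss, dF, dW, db


def center_loss(batch: EmbeddingBatch, centers: ClassCenters) -> float:
    """Half the summed squared distance of each feature to its class center."""
    return center_loss_and_grad(batch, centers)[0]


def center_loss_and_grad(
    batch: EmbeddingBatch, centers: ClassCenters
) -> tuple[float, np.ndarray]:
    """Center loss plus its gradient w.r.t. the features, ``f_i - c_{y_i}``."""
    if batch.labels.min() < 0 or batch.labels.max() >= centers.n_classes:
        raise ValueError("label without a center row")
    resid = batch.features - centers.centers[batch.labels]
    loss = 0.5 * float(np.sum(resid * resid))
    return loss, resid


def total_loss(l_s: float, l_c: float, lam: float) -> float:
    """Joint objective L = L_S + lambda * L_C."""
    if not (np.isfinite(l_s) and np.isfinite(l_c)):
        raise ValueError("loss terms must be finite")
    return float(l_s + lam * l_c)


def update_centers(
    centers: ClassCenters, batch: EmbeddingBatch, center_lr: float
) -> ClassCenters:
    """Damped per-mini-batch center update.

    For each class j present in the batch,
    ``c_j <- c_j - center_lr * sum_{i: y_i=j}(c_j - f_i) / (1 + n_j)``;
    classes absent from the batch are left untouched. Returns new centers.
    """
    if not (0 < center_lr <= 1):
        raise ValueError("center_lr must lie in (0, 1]")
    if batch.labels.max() >= centers.n_classes:
        raise ValueError("label without a center row")
    out = centers.centers.copy()
    for j in np.unique(batch.labels):
        mask = batch.labels == j
        n_j = int(mask.sum())
        delta = (out[j] * n_j - batch.features[mask].sum(axis=0)) / (1.0 + n_j)
        out[j] = out[j] - center_lr * delta
    return ClassCenters(out)
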