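"""Open-set pair verification, ROC/AUC, Top-k, distance diagnostics, t-SNE.

The test protocol is the one used in face verification: sample same-class
("gallery", "probe") pairs and different-class pairs from a test manifest,
score each pair by the cosine similarity of its unit-normalized embeddings
(equivalently, squared Euclidean distance 2 - 2s), and threshold. The
threshold is chosen by 10-fold cross-validation: fit on nine folds, measure
accuracy on the tenth.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .data import DatasetManifest
from .losses import ClassCenters, EmbeddingBatch


@dataclass(frozen=True)
class VerificationPair:
    """A (gallery, probe) record-index pair with its same-class flag."""

    gallery_index: int
    probe_index: int
    same_class: bool

    def __post_init__(self) -> None:
        if self.gallery_index == self.probe_index:
            raise ValueError("a pair must join two distinct records")


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class FoldReport:
    accuracies: np.ndarray
    thresholds: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std())


@dataclass
class DistanceSummary:
    """Five-number summaries (min, Q1, median, Q3, max) of pair distances."""

    intra: np.ndarray
    inter: np.ndarray

    @property
    def intra_median(self) -> float:
        return float(self.intra[2])

    @property
    def inter_median(self) -> float:
        return float(self.inter[2])


def cosine_similarity(f_g: np.ndarray, f_p: np.ndarray) -> float:
    """s = f_g . f_p / (||f_g|| ||f_p||); for unit vectors ||f_g-f_p||^2 = 2-2s."""
    f_g = np.asarray(f_g, dtype=np.float64)
    f_p = np.asarray(f_p, dtype=np.float64)
    ng, np_ = np.linalg.norm(f_g), np.linalg.norm(f_p)
    if ng < 1e-12 or np_ < 1e-12:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(f_g @ f_p / (ng * np_))


def _count_pairs(labels: np.ndarray) -> tuple[int, int]:
    n = len(labels)
    _, counts = np.unique(labels, return_counts=True)
    pos = int(np.sum(counts * (counts - 1) // 2))
    neg = n * (n - 1) // 2 - pos
    return pos, neg


def make_verification_pairs(
    manifest: DatasetManifest, n_pos: int, n_neg: int, seed: int
) -> list[VerificationPair]:
    """Sample distinct unordered pairs: ``n_pos`` same-class, ``n_neg``
    different-class, uniformly over the available pairs, deterministically."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("pair counts must be >= 0")
    labels = manifest.labels
    pos_avail, neg_avail = _count_pairs(labels)
    if n_pos > pos_avail:
        raise ValueError(f"requested {n_pos} positive pairs, only {pos_avail} exist")
    if n_neg > neg_avail:
        raise ValueError(f"requested {n_neg} negative pairs, only {neg_avail} exist")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA175]))
    groups = {lab: np.flatnonzero(labels == lab) for lab in np.unique(labels)}
    out: list[VerificationPair] = []

    def sample_distinct(n_req, avail, draw):
        chosen: set[tuple[int, int]] = set()
        if n_req == 0:
            return []
        if n_req * 4 >= avail:  # dense request: enumerate and choose exactly
            universe = draw(None)
            picked = rng.choice(len(universe), size=n_req, replace=False)
            return [universe[i] for i in sorted(picked)]
        while len(chosen) < n_req:
            chosen.add(draw(rng))
        return sorted(chosen)

    def draw_pos(r):
        if r is None:
            return [
                (int(a), int(b))
                for idx in groups.values()
                for a, b in itertools.combinations(idx, 2)
            ]
        lab_keys = sorted(groups)
        weights = np.array(
            [len(groups[k]) * (len(groups[k]) - 1) / 2 for k in lab_keys], float
        )
        lab = lab_keys[int(r.choice(len(lab_keys), p=weights / weights.sum()))]
        a, b = r.choice(groups[lab], size=2, replace=False)
        return (int(min(a, b)), int(max(a, b)))

    def draw_neg(r):
        if r is None:
            n = len(labels)
            return [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if labels[i] != labels[j]
            ]
        while True:
            a, b = r.choice(len(labels), size=2, replace=False)
            if labels[a] != labels[b]:
                return (int(min(a, b)), int(max(a, b)))

    for a, b in sample_distinct(n_pos, pos_avail, draw_pos):
        out.append(VerificationPair(a, b, True))
    for a, b in sample_distinct(n_neg, neg_avail, draw_neg):
        out.append(VerificationPair(a, b, False))
    return out


def pairs_to_csv(
    pairs: list[VerificationPair], manifest: DatasetManifest, path: str | os.PathLike
) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "gallery_path": [manifest.records[p.gallery_index].path for p in pairs],
            "probe_path": [manifest.records[p.probe_index].path for p in pairs],
            "same_class": [int(p.same_class) for p in pairs],
        }
    ).to_csv(path, index=False)


def verify_pairs(
    embeddings: EmbeddingBatch, pairs: list[VerificationPair], threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cosine score per pair and the decision ``same iff s > threshold``."""
    F = embeddings.features
    g = np.array([p.gallery_index for p in pairs], dtype=np.int64)
    q = np.array([p.probe_index for p in pairs], dtype=np.int64)
    if len(pairs) and (g.max() >= F.shape[0] or q.max() >= F.shape[0]):
        raise IndexError("pair index out of range of the embedding batch")
    Fg, Fq = F[g], F[q]
    norms = np.linalg.norm(Fg, axis=1) * np.linalg.norm(Fq, axis=1)
    scores = np.sum(Fg * Fq, axis=1) / norms
    return scores > threshold, scores


def roc_auc(scores, labels) -> RocResult:
    """ROC over all score thresholds (ties grouped) and trapezoidal AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both positive and negative pairs")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def _best_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing accuracy of the rule ``predict same iff s > t``.

    Candidates are midpoints between consecutive distinct scores plus
    sentinels below/above all scores; exhaustive and deterministic (the
    lowest maximizing threshold wins).
    """
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order].astype(int)
    n = len(scores)
    distinct = np.unique(s_sorted)
    cand = np.concatenate(
        ([distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0])
    )
    # for threshold t: correct = #neg with s <= t + #pos with s > t
    cum_neg = np.concatenate(([0], np.cumsum(1 - y_sorted)))
    cum_pos = np.concatenate(([0], np.cumsum(y_sorted)))
    k = np.searchsorted(s_sorted, cand, side="right")
    correct = cum_neg[k] + (cum_pos[n] - cum_pos[k])
    return float(cand[int(np.argmax(correct))])


def cross_validate_verification(
    scores, labels, n_folds: int = 10, seed: int = 0
) -> FoldReport:
    """Stratified k-fold thresholded-accuracy protocol.

    For each fold, the threshold maximizing accuracy on the remaining folds
    is selected, then accuracy is measured on the held-out fold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if n_folds > len(scores):
        raise ValueError("more folds than pairs")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both pair classes for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs, thrs = [], []
    for train_idx, test_idx in skf.split(scores.reshape(-1, 1), labels):
        t = _best_threshold(scores[train_idx], labels[train_idx])
        pred = scores[test_idx] > t
        accs.append(float((pred == labels[test_idx].astype(bool)).mean()))
        thrs.append(t)
    return FoldReport(accuracies=np.array(accs), thresholds=np.array(thrs))


def topk_accuracy(logits, labels, k: int) -> float:
    """Fraction of rows whose true label is among the k highest logits.

    Ties are broken toward the lowest class index, deterministically.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    C = logits.shape[1]
    if not (1 <= k <= C):
        raise ValueError(f"k must lie in [1, {C}]")
    order = np.argsort(-logits, axis=1, kind="stable")  # stable => lowest index wins ties
    topk = order[:, :k]
    return float(np.mean(np.any(topk == labels[:, None], axis=1)))


def distance_stats(embeddings: EmbeddingBatch) -> DistanceSummary:
    """Five-number summaries of within- and between-class Euclidean distances
    over all unordered record pairs."""
    F, y = embeddings.features, embeddings.labels
    n = F.shape[0]
    if n < 2:
        raise ValueError("need at least two records")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    d = pdist(F)
    ii, jj = np.triu_indices(n, k=1)
    same = y[ii] == y[jj]
    if not same.any():
        raise ValueError("no within-class pairs (all classes are singletons)")
    q = [0, 25, 50, 75, 100]
    return DistanceSummary(
        intra=np.percentile(d[same], q), inter=np.percentile(d[~same], q)
    )


def project_2d(
    embeddings: EmbeddingBatch,
    seed: int,
    centers: ClassCenters | None = None,
    perplexity: float = 30.0,
    out_path: str | os.PathLike | None = None,
) -> np.ndarray:
    """Seeded t-SNE projection of the embedding rows to 2-D.

    When class centers are supplied they are projected jointly and drawn as
    "x" marks on the scatter. Returns the M x 2 coordinates of the records;
    writes the scatter plot to ``out_path`` when given.
    """
    from sklearn.manifold import TSNE

    F, y = embeddings.features, embeddings.labels
    M = F.shape[0]
    if M < 5:
        raise ValueError("need at least 5 rows for a 2-D projection")
    X = F if centers is None else np.vstack([F, centers.centers])
    perp = min(perplexity, (X.shape[0] - 1) / 3.0)
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perp, init="pca",
        learning_rate="auto", max_iter=1000,
    ).fit_transform(X)
    pts = coords[:M]
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        sc = ax.scatter(pts[:, 0], pts[:, 1], c=y, cmap="tab20", s=8)
        if centers is not None:
            cc = coords[M:]
            ax.scatter(cc[:, 0], cc[:, 1], marker="x", c="black", s=60)
        ax.set_title("2-D embedding projection (t-SNE)")
        fig.colorbar(sc, ax=ax, label="class")
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return pts
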