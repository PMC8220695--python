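"""Dataset manifests, balancing, crop augmentation, splits and P-K batch sampling.

The pipeline mirrors how fine-grained cultivar image sets are prepared for
metric learning: balance each class to a fixed number of original photographs,
expand by random cropping (patches carry the local information the embedding
is trained on), split either by class (open-set verification) or within class
(closed-set classification), and sample P-K mini-batches that guarantee
within-batch positives for the center loss.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image

ROLE_ORIGINAL = "original"
ROLE_CROP = "crop"


@dataclass(frozen=True)
class ImageRecord:
    """One labeled image on disk.

    ``origin_id`` identifies the source photograph; crop records inherit the
    origin of exactly one original record.
    """

    path: str
    label: int
    origin_id: str
    role: str = ROLE_ORIGINAL

    def __post_init__(self) -> None:
        if self.label < 0:
            raise ValueError("labels must be non-negative integers")
        if self.role not in (ROLE_ORIGINAL, ROLE_CROP):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class DatasetManifest:
    """Ordered list of image records plus the size of the label universe."""

    records: list[ImageRecord] = field(default_factory=list)
    n_classes: int = 0

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.label >= self.n_classes:
                raise ValueError(
                    f"record label {rec.label} outside universe of {self.n_classes}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def paths(self) -> list[str]:
        return [r.path for r in self.records]

    def distinct_labels(self) -> np.ndarray:
        return np.unique(self.labels) if self.records else np.array([], dtype=np.int64)

    def by_label(self) -> dict[int, list[int]]:
        """Record indices grouped by label, labels in sorted order."""
        groups: dict[int, list[int]] = {}
        for i, rec in enumerate(self.records):
            groups.setdefault(rec.label, []).append(i)
        return {k: groups[k] for k in sorted(groups)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [r.path for r in self.records],
                "class_id": [r.label for r in self.records],
                "origin_id": [r.origin_id for r in self.records],
                "role": [r.role for r in self.records],
            }
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        df = self.to_frame()
        df.attrs["n_classes"] = self.n_classes
        with open(path, "w") as fh:
            fh.write(f"# n_classes={self.n_classes}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "DatasetManifest":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# n_classes="):
                raise ValueError(f"{path} is not a manifest CSV")
            n_classes = int(header.split("=", 1)[1])
            df = pd.read_csv(fh)
        records = [
            ImageRecord(str(p), int(c), str(o), str(r))
            for p, c, o, r in zip(df.path, df.class_id, df.origin_id, df.role)
        ]
        return cls(records=records, n_classes=n_classes)


@dataclass(frozen=True)
class SplitSpec:
    """Description of a train/test partition for provenance records."""

    mode: str  # disjoint_classes | within_class
    train_part: tuple
    test_part: tuple

    def __post_init__(self) -> None:
        if self.mode not in ("disjoint_classes", "within_class"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if set(self.train_part) & set(self.test_part):
            raise ValueError("train and test parts must be disjoint")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mode": self.mode,
                    "train_part": list(self.train_part),
                    "test_part": list(self.test_part),
                },
                fh,
            )


@dataclass(frozen=True)
class BatchSpec:
    """P classes x K images per mini-batch (batch size P*K)."""

    P: int
    K: int

    def __post_init__(self) -> None:
        if self.P < 2:
            raise ValueError("P must be >= 2")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def batch_size(self) -> int:
        return self.P * self.K


def balance_classes(
    manifest: DatasetManifest, per_class: int, seed: int
) -> DatasetManifest:
    """Drop classes with fewer than ``per_class`` originals and sample exactly
    ``per_class`` originals from each surviving class.

    Surviving classes are re-indexed contiguously in ascending original-label
    order. Selection is deterministic given ``seed``.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    groups = manifest.by_label()
    survivors = [lab for lab, idx in groups.items() if len(idx) >= per_class]
    if not survivors:
        raise ValueError(
            f"no class has {per_class} or more original images; balancing "
            "would produce an empty dataset"
        )
    records: list[ImageRecord] = []
    for new_label, old_label in enumerate(survivors):
        idx = groups[old_label]
        rng = np.random.default_rng(np.random.SeedSequence([seed, old_label]))
        chosen = rng.choice(len(idx), size=per_class, replace=False)
        chosen.sort()
        for j in chosen:
            records.append(replace(manifest.records[idx[j]], label=new_label))
    return DatasetManifest(records=records, n_classes=len(survivors))


def augment_crops(
    manifest: DatasetManifest,
    factor: int,
    out_dir: str | os.PathLike,
    crop_frac_range: tuple[float, float] = (0.5, 0.9),
    seed: int = 0,
) -> DatasetManifest:
    """Expand every original image into ``factor`` random crops saved as PNG.

    The crop window is an axis-aligned square whose side is a random fraction
    of the image's short side, drawn from ``crop_frac_range``; the top-left
    corner is uniform over valid positions ((row, col), 0-based, half-open
    windows). Originals are not retained in the returned manifest, so the
    output size is exactly ``factor * len(manifest)``.
    """
    lo, hi = crop_frac_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("crop_frac_range must lie inside (0, 1]")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out_dir = os.fspath(out_dir)
    records: list[ImageRecord] = []
    for r_idx, rec in enumerate(manifest.records):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r_idx]))
        with Image.open(rec.path) as im:
            im = im.convert("RGB")
            w, h = im.size
            short = min(w, h)
            cls_dir = os.path.join(out_dir, f"{rec.label:04d}")
            os.makedirs(cls_dir, exist_ok=True)
            stem = os.path.splitext(os.path.basename(rec.path))[0]
            for j in range(factor):
                side = max(1, int(round(rng.uniform(lo, hi) * short)))
                side = min(side, short)
                row = int(rng.integers(0, h - side + 1))
                col = int(rng.integers(0, w - side + 1))
                crop = im.crop((col, row, col + side, row + side))
                crop_path = os.path.join(cls_dir, f"{stem}_crop{j:02d}.png")
                crop.save(crop_path)
                records.append(
                    ImageRecord(crop_path, rec.label, rec.origin_id, ROLE_CROP)
                )
    return DatasetManifest(records=records, n_classes=manifest.n_classes)


def split_disjoint_classes(
    manifest: DatasetManifest, n_train_classes: int, seed: int
) -> tuple[DatasetManifest, DatasetManifest]:
    """Partition by class: train classes never appear in the test manifest.

    This is the open-set protocol — verification is evaluated on classes the
    model has never seen.
    """
    labels = manifest.distinct_labels()
    if not (0 < n_train_classes < len(labels)):
        raise ValueError(
            f"n_train_classes must be in (0, {len(labels)}), got {n_train_classes}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(labels)
    train_labels = set(int(x) for x in perm[:n_train_classes])
    train_recs = [r for r in manifest.records if r.label in train_labels]
    test_recs = [r for r in manifest.records if r.label not in train_labels]
    n = manifest.n_classes
    return (
        DatasetManifest(records=train_recs, n_classes=n),
        DatasetManifest(records=test_recs, n_classes=n),
    )


def split_within_class(
    manifest: DatasetManifest, train_frac: float, seed: int
) -> tuple[DatasetManifest, DatasetManifest]:
    """Per-class stratified split after a random shuffle.

    Each class contributes round(train_frac * count) records to the train
    part, clamped so that every class keeps at least one train and one test
    record.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label, idx in manifest.by_label().items():
        n = len(idx)
        if n < 2:
            raise ValueError(f"class {label} has fewer than 2 records")
        perm = rng.permutation(n)
        n_train = int(math.floor(train_frac * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)
        train_idx.extend(idx[j] for j in perm[:n_train])
        test_idx.extend(idx[j] for j in perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    n_cls = manifest.n_classes
    return (
        DatasetManifest([manifest.records[i] for i in train_idx], n_cls),
        DatasetManifest([manifest.records[i] for i in test_idx], n_cls),
    )


def preprocess(
    image,
    out_size: int = 224,
    resize_to: int = 256,
    train: bool = False,
    rng: np.random.Generator | None = None,
    crop_offset: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resize then crop to the network input size; values scaled to [0, 1].

    The image is bilinearly resized to ``resize_to`` square, then an
    ``out_size`` window is cut: a random window in training (``rng``
    required), the center window at test time, or the explicit ``crop_offset``
    (row, col) when given. Returns float32 of shape (out_size, out_size, 3).
    """
    if isinstance(image, np.ndarray):
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an RGB raster of shape (H, W, 3)")
        pil = Image.fromarray(np.ascontiguousarray(image.astype(np.uint8)), "RGB")
    else:
        pil = image
        if pil.mode != "RGB":
            raise ValueError(f"expected RGB input, got mode {pil.mode}")
    if out_size > resize_to:
        raise ValueError("out_size cannot exceed resize_to")
    if pil.size != (resize_to, resize_to):
        pil = pil.resize((resize_to, resize_to), Image.BILINEAR)
    margin = resize_to - out_size
    if crop_offset is not None:
        row, col = crop_offset
    elif train:
        if rng is None:
            raise ValueError("train-time preprocessing needs an rng")
        row = int(rng.integers(0, margin + 1))
        col = int(rng.integers(0, margin + 1))
    else:
        row = col = margin // 2
    if not (0 <= row <= margin and 0 <= col <= margin):
        raise ValueError("crop offset outside the resized image")
    arr = np.asarray(pil, dtype=np.float32) / 255.0
    return arr[row : row + out_size, col : col + out_size, :]


def pk_batches(
    labels, spec: BatchSpec, seed: int, n_batches: int | None = None
) -> list[np.ndarray]:
    """One epoch of P-K mini-batches over ``labels``.

    Each batch draws P distinct classes without replacement, then K record
    indices per class (without replacement within the batch; with replacement
    only for classes holding fewer than K records). An epoch is
    floor(N / (P*K)) batches unless ``n_batches`` overrides it.
    """
    labels = np.asarray(labels, dtype=np.int64)
    classes = np.unique(labels)
    if len(classes) < spec.P:
        raise ValueError(
            f"need at least P={spec.P} distinct labels, found {len(classes)}"
        )
    pools = {int(c): np.flatnonzero(labels == c) for c in classes}
    if n_batches is None:
        n_batches = len(labels) // spec.batch_size
    rng = np.random.default_rng(seed)
    batches: list[np.ndarray] = []
    for _ in range(n_batches):
        picked = rng.choice(classes, size=spec.P, replace=False)
        idx: list[np.ndarray] = []
        for c in picked:
            pool = pools[int(c)]
            replace_flag = len(pool) < spec.K
            idx.append(rng.choice(pool, size=spec.K, replace=replace_flag))
        batches.append(np.concatenate(idx))
    return batches
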