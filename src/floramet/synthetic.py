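"""Procedural generator of labeled single-flower, top-view image datasets.

Classes differ in the two cues that drive confusions between real cultivars:
petal color (hue) and petal morphology (petal count, petal length, disc
size). Flowers are drawn as parametric radial shapes — a central disc plus
``petal_count`` cosine lobes at the class hue — with per-instance jitter in
rotation, scale and brightness, so every record is reproducible from its
seeds while no two instances are pixel-identical.
"""

from __future__ import annotations

import colorsys
import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np
from PIL import Image

from .data import ROLE_ORIGINAL, DatasetManifest, ImageRecord

#: petal counts a palette may assign; classes sharing a hue slot must take
#: distinct entries from this list
PETAL_COUNT_OPTIONS = tuple(range(4, 25))


@dataclass(frozen=True)
class ClassAppearance:
    """Rendering parameters of one flower class."""

    class_id: int
    hue_deg: float
    petal_count: int
    petal_len_frac: float
    disc_frac: float
    texture_scale: float = 0.02

    def __post_init__(self) -> None:
        if not (0 <= self.hue_deg < 360):
            raise ValueError("hue_deg must lie in [0, 360)")
        if self.petal_count < 3:
            raise ValueError("petal_count must be >= 3")
        if not (0 < self.petal_len_frac <= 1):
            raise ValueError("petal_len_frac must lie in (0, 1]")
        if not (0 < self.disc_frac < 0.5):
            raise ValueError("disc_frac must lie in (0, 0.5)")
        if self.texture_scale < 0:
            raise ValueError("texture_scale must be >= 0")


@dataclass(frozen=True)
class RenderSpec:
    """Global rendering options shared by a dataset."""

    image_size: int = 64
    background_mode: str = "uniform"
    global_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.background_mode not in ("uniform", "cluttered"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")


def circular_hue_distance(a: float, b: float) -> float:
    """Smallest angular distance between two hues, in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def make_class_palette(
    n_classes: int,
    seed: int,
    min_hue_sep: float = 15.0,
    texture_scale: float = 0.02,
) -> list[ClassAppearance]:
    """Draw ``n_classes`` mutually distinguishable appearances.

    Any two appearances either sit at least ``min_hue_sep`` degrees apart on
    the hue circle or carry different petal counts. Hues are evenly spaced
    slots (with a seeded global rotation); when classes outnumber slots the
    slots are reused with distinct petal counts, and a palette that cannot
    honor this raises ``ValueError``.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if min_hue_sep > 0:
        n_slots = max(1, int(360.0 // min_hue_sep))
    else:
        n_slots = n_classes
    slots_used = min(n_classes, n_slots)
    per_slot = math.ceil(n_classes / slots_used)
    if per_slot > len(PETAL_COUNT_OPTIONS):
        raise ValueError(
            f"cannot build {n_classes} distinct classes with min_hue_sep="
            f"{min_hue_sep}: only {n_slots} hue slots and "
            f"{len(PETAL_COUNT_OPTIONS)} petal-count options are available"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A1E77]))
    offset = rng.uniform(0, 360.0 / slots_used)
    slot_hues = (offset + np.arange(slots_used) * (360.0 / slots_used)) % 360.0
    # distinct petal counts for the classes stacked on one hue slot
    slot_counts = [
        rng.permutation(len(PETAL_COUNT_OPTIONS))[:per_slot] for _ in range(slots_used)
    ]
    order = rng.permutation(n_classes)  # decorrelate class id from hue order
    palette: list[ClassAppearance] = [None] * n_classes  # type: ignore[list-item]
    for rank, class_id in enumerate(order):
        slot = rank % slots_used
        layer = rank // slots_used
        petals = PETAL_COUNT_OPTIONS[slot_counts[slot][layer]]
        palette[int(class_id)] = ClassAppearance(
            class_id=int(class_id),
            hue_deg=float(slot_hues[slot]),
            petal_count=int(petals),
            petal_len_frac=float(rng.uniform(0.6, 0.92)),
            disc_frac=float(rng.uniform(0.12, 0.28)),
            texture_scale=float(texture_scale),
        )
    return palette


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def render_flower(
    appearance: ClassAppearance, instance_seed: int, spec: RenderSpec
) -> np.ndarray:
    """Render one flower instance as an (S, S, 3) uint8 raster.

    Deterministic given (appearance, instance_seed, spec); the instance seed
    drives rotation (uniform on the circle), scale jitter (±10%), brightness
    jitter (±10%) and the additive pixel noise.
    """
    s = spec.image_size
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [spec.global_seed, appearance.class_id, int(instance_seed)]
        )
    )
    rot = rng.uniform(0.0, 2.0 * math.pi)
    scale = 1.0 + rng.uniform(-0.1, 0.1)
    brightness = 1.0 + rng.uniform(-0.1, 0.1)

    half = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    dx = (xx - half) / (s / 2.0)
    dy = (yy - half) / (s / 2.0)
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    lobe = np.clip(np.cos(appearance.petal_count * (theta - rot)), 0.0, 1.0) ** 0.8
    disc_r = scale * appearance.disc_frac
    envelope = scale * (
        appearance.disc_frac
        + (appearance.petal_len_frac - appearance.disc_frac) * lobe
    )
    edge = 1.5 / (s / 2.0)  # ~1.5 px soft edge for antialiasing
    fore = _smoothstep((envelope - r) / edge)
    disc = _smoothstep((disc_r - r) / edge)

    h = appearance.hue_deg / 360.0
    petal_rgb = np.array(colorsys.hsv_to_rgb(h, 0.85, min(1.0, 0.95 * brightness)))
    disc_rgb = np.array(colorsys.hsv_to_rgb(h, 0.9, min(1.0, 0.45 * brightness)))

    if spec.background_mode == "uniform":
        bg = np.full((s, s, 3), 0.35)
    else:
        # low-frequency colored clutter: a coarse random field upsampled
        coarse = rng.uniform(0.1, 0.8, size=(8, 8, 3))
        bg = np.asarray(
            Image.fromarray((coarse * 255).astype(np.uint8), "RGB").resize(
                (s, s), Image.BILINEAR
            ),
            dtype=np.float64,
        ) / 255.0

    fore3 = fore[..., None]
    disc3 = disc[..., None]
    img = bg * (1.0 - fore3) + petal_rgb * (fore3 - disc3) + disc_rgb * disc3
    if appearance.texture_scale > 0:
        img = img + rng.normal(0.0, appearance.texture_scale, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def generate_dataset(
    n_classes: int,
    n_per_class: int,
    spec: RenderSpec,
    out_dir: str | os.PathLike,
    per_class_counts: list[int] | None = None,
    min_hue_sep: float = 15.0,
    texture_scale: float = 0.02,
) -> DatasetManifest:
    """Render a labeled dataset of flower images under ``out_dir``.

    Writes PNG files as ``out_dir/<class_id>/<instance>.png``, a manifest CSV
    and a JSON sidecar recording the palette and seeds. ``per_class_counts``
    overrides the uniform ``n_per_class`` with one count per class (useful
    for emulating unbalanced field collections).
    """
    out_dir = os.fspath(out_dir)
    if per_class_counts is not None:
        if len(per_class_counts) != n_classes:
            raise ValueError("per_class_counts must list one count per class")
        counts = list(per_class_counts)
    else:
        counts = [n_per_class] * n_classes
    if any(c < 0 for c in counts):
        raise ValueError("per-class counts must be >= 0")
    os.makedirs(out_dir, exist_ok=True)
    palette = make_class_palette(
        n_classes, spec.global_seed, min_hue_sep=min_hue_sep,
        texture_scale=texture_scale,
    )
    records: list[ImageRecord] = []
    for app in palette:
        c = app.class_id
        if counts[c] == 0:
            continue
        cls_dir = os.path.join(out_dir, f"{c:04d}")
        os.makedirs(cls_dir, exist_ok=True)
        for i in range(counts[c]):
            img = render_flower(app, i, spec)
            path = os.path.join(cls_dir, f"img_{i:04d}.png")
            Image.fromarray(img, "RGB").save(path)
            records.append(ImageRecord(path, c, f"c{c}i{i}", ROLE_ORIGINAL))
    manifest = DatasetManifest(records=records, n_classes=n_classes)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"))
    with open(os.path.join(out_dir, "palette.json"), "w") as fh:
        json.dump(
            {
                "render_spec": asdict(spec),
                "min_hue_sep": min_hue_sep,
                "per_class_counts": counts,
                "palette": [asdict(a) for a in palette],
            },
            fh,
            indent=1,
        )
    return manifest
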