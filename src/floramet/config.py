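"""Config-driven pipeline runner: generate -> prepare -> train -> evaluate.

One YAML-serializable :class:`RunConfig` holds every stage's parameters and a
single global seed; each randomized stage receives a seed derived from the
global seed and the stage tag, so any number in a metrics report can be
regenerated from the config alone.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import synthetic
from .data import BatchSpec, augment_crops, balance_classes, split_disjoint_classes
from .evaluation import (
    cross_validate_verification,
    distance_stats,
    make_verification_pairs,
    pairs_to_csv,
    project_2d,
    roc_auc,
    topk_accuracy,
    verify_pairs,
)
from .losses import LossConfig
from .model import (
    ModelConfig,
    build_model,
    extract_embeddings,
    he_initialize,
    predict_logits,
    save_checkpoint,
    train,
)


def derive_seed(global_seed: int, tag: str) -> int:
    """Stage seed: deterministic mix of the global seed and a stage tag."""
    h = zlib.crc32(tag.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(global_seed), h])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All stage parameters of one reproducible run."""

    seed: int = 0
    out_root: str = "runs"
    generate: dict = field(default_factory=lambda: {
        "n_classes": 16, "n_per_class": 20, "image_size": 64,
        "background_mode": "uniform", "min_hue_sep": 18.0, "texture_scale": 0.02,
    })
    prepare: dict = field(default_factory=lambda: {
        "per_class": 20, "factor": 10, "crop_frac_range": [0.5, 0.9],
        "n_train_classes": 12,
    })
    train: dict = field(default_factory=lambda: {
        "backbone": "tiny_ref", "embed_dim": 32, "channels": [8, 16, 32, 64],
        "P": 6, "K": 5, "lambda": 1.0, "alpha": 10.0, "center_lr": 0.5,
        "lr": 0.001, "lr_step": 10, "epochs": 10, "input_size": 64,
        "resize_to": 72,
    })
    evaluate: dict = field(default_factory=lambda: {
        "n_pos": 600, "n_neg": 600, "n_folds": 10, "topk": [1, 5],
    })
    visualize: dict = field(default_factory=lambda: {
        "max_per_class": 40, "perplexity": 30.0,
    })

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def desk_demo_config(seed: int = 0, out_root: str = "runs") -> RunConfig:
    """The bundled desk demo: 12 synthetic train classes, 4 held-out classes,
    tiny_ref backbone, 10 epochs — finishes on one CPU."""
    return RunConfig(seed=seed, out_root=out_root)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier stage outputs are left intact."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> str:
    """Execute the requested stages in order under a seed-named run directory.

    Returns the run directory path. Writes a config copy, manifests, the
    checkpoint, metrics JSON and figures.
    """
    all_stages = ("generate", "prepare", "train", "evaluate", "visualize")
    stages = tuple(stages or all_stages)
    run_dir = os.path.join(config.out_root, f"run_seed{config.seed}")
    os.makedirs(run_dir, exist_ok=True)
    config.to_yaml(os.path.join(run_dir, "config.yaml"))
    state: dict = {}

    def _stage(name):
        def deco(fn):
            if name in stages:
                try:
                    fn()
                except Exception as exc:  # noqa: BLE001 - report failed stage
                    raise StageError(name, exc) from exc
            return fn
        return deco

    @_stage("generate")
    def _generate():
        g = config.generate
        spec = synthetic.RenderSpec(
            image_size=int(g["image_size"]),
            background_mode=g.get("background_mode", "uniform"),
            global_seed=derive_seed(config.seed, "generate"),
        )
        state["raw"] = synthetic.generate_dataset(
            int(g["n_classes"]), int(g["n_per_class"]), spec,
            os.path.join(run_dir, "raw"),
            min_hue_sep=float(g.get("min_hue_sep", 18.0)),
            texture_scale=float(g.get("texture_scale", 0.02)),
        )

    @_stage("prepare")
    def _prepare():
        from .data import DatasetManifest

        p = config.prepare
        raw = state.get("raw") or DatasetManifest.from_csv(
            os.path.join(run_dir, "raw", "manifest.csv")
        )
        seed = derive_seed(config.seed, "prepare")
        balanced = balance_classes(raw, int(p["per_class"]), seed)
        train_m, test_m = split_disjoint_classes(
            balanced, int(p["n_train_classes"]), seed
        )
        # crop after the class split so no test-class pixels enter training
        state["train"] = augment_crops(
            train_m, int(p["factor"]), os.path.join(run_dir, "crops_train"),
            tuple(p.get("crop_frac_range", (0.5, 0.9))), seed,
        )
        state["test"] = augment_crops(
            test_m, int(p["factor"]), os.path.join(run_dir, "crops_test"),
            tuple(p.get("crop_frac_range", (0.5, 0.9))), seed + 1,
        )
        state["train"].to_csv(os.path.join(run_dir, "train_manifest.csv"))
        state["test"].to_csv(os.path.join(run_dir, "test_manifest.csv"))

    @_stage("train")
    def _train():
        from .data import DatasetManifest

        t = config.train
        train_m = state.get("train") or DatasetManifest.from_csv(
            os.path.join(run_dir, "train_manifest.csv")
        )
        n_classes = len(np.unique(train_m.labels))
        loss_cfg = LossConfig(
            lam=float(t.get("lambda", 1.0)), alpha=float(t.get("alpha", 10.0)),
            center_lr=float(t.get("center_lr", 0.5)),
        )
        model_cfg = ModelConfig(
            n_classes=n_classes, backbone=t.get("backbone", "tiny_ref"),
            embed_dim=int(t.get("embed_dim", 32)),
            channels=tuple(t.get("channels", (8, 16, 32, 64))),
            lr=float(t.get("lr", 0.001)), lr_step=int(t.get("lr_step", 10)),
            epochs=int(t.get("epochs", 10)),
            input_size=int(t.get("input_size", 64)),
            resize_to=int(t.get("resize_to", 72)),
            seed=derive_seed(config.seed, "train"),
        )
        model = he_initialize(build_model(model_cfg, loss_cfg), model_cfg.seed)
        spec = BatchSpec(int(t.get("P", 6)), int(t.get("K", 5)))
        model, log = train(model, train_m, spec, loss_cfg, model_cfg)
        log.to_csv(os.path.join(run_dir, "train_log.csv"))
        save_checkpoint(model, os.path.join(run_dir, "checkpoint.npz"))
        state["model"] = model

    @_stage("evaluate")
    def _evaluate():
        from .data import DatasetManifest
        from .model import load_checkpoint

        e = config.evaluate
        model = state.get("model") or load_checkpoint(
            os.path.join(run_dir, "checkpoint.npz")
        )
        test_m = state.get("test") or DatasetManifest.from_csv(
            os.path.join(run_dir, "test_manifest.csv")
        )
        train_m = state.get("train") or DatasetManifest.from_csv(
            os.path.join(run_dir, "train_manifest.csv")
        )
        seed = derive_seed(config.seed, "evaluate")
        pairs = make_verification_pairs(
            test_m, int(e["n_pos"]), int(e["n_neg"]), seed
        )
        pairs_to_csv(pairs, test_m, os.path.join(run_dir, "pairs.csv"))
        emb_test = extract_embeddings(model, test_m)
        _, scores = verify_pairs(emb_test, pairs, 0.0)
        flags = np.array([p.same_class for p in pairs])
        roc = roc_auc(scores, flags)
        folds = cross_validate_verification(
            scores, flags, int(e.get("n_folds", 10)), seed
        )
        logits = predict_logits(model, train_m)
        from .model import _remap_labels

        y_train, _ = _remap_labels(train_m.labels)
        stats = distance_stats(extract_embeddings(model, train_m))
        metrics = {
            "auc": roc.auc,
            "fold_accuracies": folds.accuracies.tolist(),
            "mean_accuracy": folds.mean_accuracy,
            "distance_summary": {
                "intra": stats.intra.tolist(), "inter": stats.inter.tolist(),
            },
        }
        for k in e.get("topk", [1, 5]):
            if k <= logits.shape[1]:
                metrics[f"top{k}"] = topk_accuracy(logits, y_train, int(k))
        with open(os.path.join(run_dir, "metrics.json"), "w") as fh:
            json.dump(metrics, fh, indent=1)
        state["metrics"] = metrics

    @_stage("visualize")
    def _visualize():
        from .data import DatasetManifest
        from .model import load_checkpoint

        v = config.visualize
        model = state.get("model") or load_checkpoint(
            os.path.join(run_dir, "checkpoint.npz")
        )
        train_m = state.get("train") or DatasetManifest.from_csv(
            os.path.join(run_dir, "train_manifest.csv")
        )
        rng = np.random.default_rng(derive_seed(config.seed, "visualize"))
        keep: list[int] = []
        for _, idx in train_m.by_label().items():
            take = min(len(idx), int(v.get("max_per_class", 40)))
            keep.extend(rng.choice(idx, size=take, replace=False))
        from .data import DatasetManifest as DM

        sub = DM([train_m.records[i] for i in sorted(keep)], train_m.n_classes)
        emb = extract_embeddings(model, sub)
        project_2d(
            emb, seed=derive_seed(config.seed, "tsne"),
            centers=None, perplexity=float(v.get("perplexity", 30.0)),
            out_path=os.path.join(run_dir, "embedding_scatter.png"),
        )

    return run_dir
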