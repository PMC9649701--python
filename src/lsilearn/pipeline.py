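"""End-to-end training and evaluation harness.

The training loop follows the multi-view recipe: for every sample of every
epoch, build the augmented group (rotated originals, block-shuffled copy and
its rotations, with fresh shuffle permutations each epoch), run each view
through the shared backbone once, apply both heads, and descend the combined
objective ``L_c + lambda_sm * L_sm`` by stochastic gradient descent.
Inference uses the plain image only: augmentation is training-time.

Runs are self-describing: the configuration is serialized into the run
directory before training, the per-epoch log is CSV, and the checkpoint
stores all parameters together with the configuration, so a run can be
reproduced from its own artifacts.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model_losses import (
    LSIModel,
    PROB_FLOOR,
    lsfsm_loss_and_grad,
    total_objective,
)
from .preprocessing import RotationSchedule, build_augmented_set
from .synthetic import ToyDataset, make_toy_dataset
from . import nn

__all__ = [
    "ExperimentConfig",
    "RunReport",
    "train",
    "train_index_head",
    "evaluate",
    "export_feature_maps",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ExperimentConfig:
    """Everything a run needs; defaults are the desk-scale configuration.

    A full-scale configuration (384x384 crops, ResNet-class backbone,
    160 epochs, batch 16, lr 0.001 decayed x0.1 every 60 epochs) is
    expressible here but untested at that scale; the tested path is the
    toy one.
    """

    # data
    n_classes: int = 5
    n_per_class: int = 10
    image_size: int = 48
    data_seed: int = 0
    # preprocessing
    n_blocks: int = 6
    angles_original: tuple[float, ...] = (0.0, math.pi / 6, math.pi / 4)
    angles_shuffled: tuple[float, ...] = (0.0,)
    # model
    backbone_widths: tuple[int, ...] = (8, 16, 32)
    per_view_index_head: bool = True
    # optimization
    lambda_sm: float = 1.0 / 36.0
    epochs: int = 100
    batch_size: int = 5
    learning_rate: float = 0.01
    head_learning_rate: float = 0.3
    momentum: float = 0.9
    clip_norm: float | None = 5.0
    lr_decay_every: int = 60
    lr_decay_factor: float = 0.1
    shuffle_each_epoch: bool = True
    seed: int = 0
    # output
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.angles_original = tuple(float(a) for a in self.angles_original)
        self.angles_shuffled = tuple(float(a) for a in self.angles_shuffled)
        if self.lambda_sm < 0:
            raise ValueError("lambda_sm must be >= 0")

    @property
    def schedule(self) -> RotationSchedule:
        return RotationSchedule(self.angles_original, self.angles_shuffled)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["angles_original"] = list(self.angles_original)
        data["angles_shuffled"] = list(self.angles_shuffled)
        data["backbone_widths"] = list(self.backbone_widths)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("angles_original", "angles_shuffled", "backbone_widths"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunReport:
    """Per-epoch losses/accuracy plus final metrics for one training run."""

    epochs: list[dict] = field(default_factory=list)
    final_train_accuracy: float = 0.0
    final_test_accuracy: float = 0.0
    wall_clock_s: float = 0.0

    def loss_curve(self, key: str = "total") -> np.ndarray:
        return np.asarray([row[key] for row in self.epochs])

    def to_csv(self, path: str | Path) -> None:
        fields = ["epoch", "l_c", "l_sm", "total", "train_accuracy"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for row in self.epochs:
                writer.writerow({k: row[k] for k in fields})


def _shuffle_seed(master: int, epoch: int, sample: int) -> int:
    # deterministic per (run, epoch, sample), kept within int32 range
    return (master * 1_000_003 + epoch * 10_007 + sample * 101 + 7) % (2**31 - 1)


def _train_sample(
    model: LSIModel,
    image: np.ndarray,
    label: int,
    schedule: RotationSchedule,
    n_blocks: int,
    lambda_sm: float,
    shuffle_seed: int,
    n_classes: int,
) -> tuple[float, float]:
    """Forward/backward for one sample; returns its (L_c, L_sm) contributions."""
    aset = build_augmented_set(
        image, label, schedule, n_blocks, seed=shuffle_seed, n_classes=n_classes
    )
    onehot = aset.class_label
    z = aset.label_scale
    l_c = 0.0
    l_sm = 0.0
    for view, (view_image, view_labels) in enumerate(zip(aset.images, aset.labels)):
        fmap, caches = model.backbone.forward(view_image)
        probs, ccache = model.cls_head.forward(fmap)
        p_true = max(float(probs @ onehot), PROB_FLOOR)
        l_c += -math.log(p_true)
        gfmap = model.cls_head.backward(probs - onehot, ccache)
        if lambda_sm > 0:
            head_view = view if model.index_head.n_views > 1 else 0
            pred, icache = model.index_head.forward(fmap, view=head_view)
            loss_v, gpred = lsfsm_loss_and_grad(pred, view_labels / z)
            l_sm += loss_v
            gfmap = gfmap + model.index_head.backward(lambda_sm * gpred, icache)
        model.backbone.backward(gfmap, caches)
    return l_c, l_sm


def train(
    config: ExperimentConfig,
    dataset: ToyDataset | None = None,
    model: LSIModel | None = None,
) -> tuple[LSIModel, RunReport, ToyDataset]:
    """Train a model per the configuration; returns (model, report, dataset).

    If no dataset is given a toy dataset is generated from the config; if no
    model is given one is initialized from ``config.seed``.  Aborts on a
    non-finite loss with a diagnostic message naming the offending batch.
    """
    t0 = time.time()
    if dataset is None:
        dataset = make_toy_dataset(
            n_classes=config.n_classes,
            n_per_class=config.n_per_class,
            size=config.image_size,
            seed=config.data_seed,
        )
    train_images, train_labels, test_images, test_labels = dataset.split()
    schedule = config.schedule
    if model is None:
        model = LSIModel(
            n_classes=dataset.n_classes,
            n_blocks=config.n_blocks,
            n_views=schedule.n_views,
            widths=config.backbone_widths,
            seed=config.seed,
            per_view_index_head=config.per_view_index_head,
        )
    opt_backbone = nn.SGD(
        model.backbone.params(),
        lr=config.learning_rate,
        momentum=config.momentum,
        clip_norm=config.clip_norm,
    )
    opt_heads = nn.SGD(
        model.cls_head.params() + model.index_head.params(),
        lr=config.head_learning_rate,
        momentum=config.momentum,
        clip_norm=config.clip_norm,
    )
    optimizers = (opt_backbone, opt_heads)
    order_rng = np.random.default_rng(config.seed + 1)
    n_train = len(train_images)
    report = RunReport()

    out_dir: Path | None = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")

    for epoch in range(config.epochs):
        if config.lr_decay_every > 0 and epoch > 0 and epoch % config.lr_decay_every == 0:
            for opt in optimizers:
                opt.lr *= config.lr_decay_factor
        order = (
            order_rng.permutation(n_train)
            if config.shuffle_each_epoch
            else np.arange(n_train)
        )
        epoch_lc = 0.0
        epoch_lsm = 0.0
        for start in range(0, n_train, config.batch_size):
            batch = order[start : start + config.batch_size]
            for opt in optimizers:
                opt.zero_grad()
            for sample in batch:
                l_c, l_sm = _train_sample(
                    model,
                    train_images[sample],
                    int(train_labels[sample]),
                    schedule,
                    config.n_blocks,
                    config.lambda_sm,
                    _shuffle_seed(config.seed, epoch, int(sample)),
                    dataset.n_classes,
                )
                if not (math.isfinite(l_c) and math.isfinite(l_sm)):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch starting {start}, "
                        f"sample {sample}: L_c={l_c}, L_sm={l_sm}"
                    )
                epoch_lc += l_c
                epoch_lsm += l_sm
            for opt in optimizers:
                opt.scale_grad(1.0 / len(batch))
                opt.step()
        train_acc = evaluate(model, train_images, train_labels)[0]
        report.epochs.append(
            {
                "epoch": epoch,
                "l_c": epoch_lc,
                "l_sm": epoch_lsm,
                "total": total_objective(epoch_lc, epoch_lsm, config.lambda_sm),
                "train_accuracy": train_acc,
            }
        )
    report.final_train_accuracy = evaluate(model, train_images, train_labels)[0]
    report.final_test_accuracy = (
        evaluate(model, test_images, test_labels)[0] if len(test_images) else float("nan")
    )
    report.wall_clock_s = time.time() - t0
    if out_dir is not None:
        report.to_csv(out_dir / "log.csv")
        save_checkpoint(model, config, out_dir / "checkpoint.npz")
    return model, report, dataset


def train_index_head(
    model: LSIModel,
    augmented_sets: list,
    epochs: int = 400,
    lr: float = 0.05,
    momentum: float = 0.9,
    lr_decay_every: int = 50,
    lr_decay_factor: float = 0.5,
) -> tuple[list[float], float]:
    """Train only the index head on fixed augmented sets (backbone frozen).

    Backbone feature maps are computed once and reused, since no backbone
    parameter moves.  Returns the per-epoch similarity-loss curve and the
    final mean per-block Euclidean error in normalized index units.

    The similarity loss is a sum of unsquared Euclidean distances, so its
    per-block gradient keeps unit magnitude until the distance reaches zero;
    gradient descent therefore stalls at an error floor proportional to the
    learning rate unless the rate decays.  The default halves it every
    ``lr_decay_every`` epochs.
    """
    cached: list[tuple[int, np.ndarray, np.ndarray]] = []
    for aset in augmented_sets:
        z = aset.label_scale
        for view, (img, lab) in enumerate(zip(aset.images, aset.labels)):
            fmap, _ = model.backbone.forward(img)
            head_view = view if model.index_head.n_views > 1 else 0
            cached.append((head_view, fmap, lab / z))
    opt = nn.SGD(model.index_head.params(), lr=lr, momentum=momentum)
    curve: list[float] = []
    for epoch in range(epochs):
        if lr_decay_every > 0 and epoch > 0 and epoch % lr_decay_every == 0:
            opt.lr *= lr_decay_factor
        total = 0.0
        opt.zero_grad()
        for head_view, fmap, target in cached:
            pred, icache = model.index_head.forward(fmap, view=head_view)
            loss_v, gpred = lsfsm_loss_and_grad(pred, target)
            total += loss_v
            model.index_head.backward(gpred, icache)
        opt.scale_grad(1.0 / len(cached))
        opt.step()
        curve.append(total)
    mean_err = 0.0
    for head_view, fmap, target in cached:
        pred, _ = model.index_head.forward(fmap, view=head_view)
        mean_err += float(np.sqrt(((pred - target) ** 2).sum(axis=-1)).mean())
    return curve, mean_err / len(cached)


def evaluate(
    model: LSIModel, images: np.ndarray, labels: np.ndarray
) -> tuple[float, dict[int, float]]:
    """Top-1 accuracy (%) and per-class accuracies on plain images.

    No rotation and no shuffling at test time: the augmented group exists
    only to shape training.
    """
    if len(images) == 0:
        raise ValueError("empty evaluation set")
    labels = np.asarray(labels)
    predictions = np.asarray([model.predict_class(img) for img in images])
    if labels.max() >= model.n_classes:
        raise ValueError(
            f"label {labels.max()} out of range for a {model.n_classes}-class model"
        )
    correct = predictions == labels
    accuracy = 100.0 * float(correct.mean())
    per_class = {
        int(cls): 100.0 * float(correct[labels == cls].mean())
        for cls in np.unique(labels)
    }
    return accuracy, per_class


def export_feature_maps(model: LSIModel, image: np.ndarray, path: str | Path) -> np.ndarray:
    """Write the channel-averaged last backbone activation as a gray PNG.

    The map is min-max normalized to [0, 255]; a constant map exports as
    mid-gray.  Returns the raw channel-averaged map.
    """
    import imageio.v3 as iio

    fmap, _ = model.backbone.forward(np.asarray(image, dtype=float))
    # average the learned channels only, not the fixed coordinate ramps
    mean_map = fmap[: model.backbone.out_channels - 2].mean(axis=0)
    lo, hi = float(mean_map.min()), float(mean_map.max())
    if hi - lo < 1e-12:
        norm = np.full_like(mean_map, 0.5)
    else:
        norm = (mean_map - lo) / (hi - lo)
    iio.imwrite(Path(path), (norm * 255).astype(np.uint8))
    return mean_map


def save_checkpoint(model: LSIModel, config: ExperimentConfig, path: str | Path) -> None:
    """Single-archive checkpoint: all parameters plus the full configuration."""
    meta = dataclasses.asdict(config)
    arrays = model.state_arrays()
    np.savez(
        Path(path),
        __meta__=json.dumps(
            {
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v) for k, v in meta.items()
                },
                "n_classes": model.n_classes,
                "n_blocks": model.n_blocks,
                "n_views": model.n_views,
            }
        ),
        **arrays,
    )


def load_checkpoint(path: str | Path) -> tuple[LSIModel, ExperimentConfig]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg_data = meta["config"]
        for key in ("angles_original", "angles_shuffled", "backbone_widths"):
            cfg_data[key] = tuple(cfg_data[key])
        config = ExperimentConfig(**cfg_data)
        model = LSIModel(
            n_classes=meta["n_classes"],
            n_blocks=meta["n_blocks"],
            n_views=meta["n_views"],
            widths=config.backbone_widths,
            seed=config.seed,
            per_view_index_head=config.per_view_index_head,
        )
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model, config
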