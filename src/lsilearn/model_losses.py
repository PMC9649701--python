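"""Classification and index-regression heads, their losses, and the toy model.

Two objectives drive training.  For each input image the preprocessing stage
produces ``K1 + K2`` views (rotated originals and rotated shuffled copies),
every view passes once through a shared backbone, and:

* the classification head (global average pool + fully connected + softmax)
  yields a class distribution per view; the classification loss is the
  cross-entropy against the one-vs-all label *summed over all views* and, at
  the epoch level, over the training set;
* the index head (per-cell 1x1 linear projection to two channels, tanh,
  adaptive average pooling onto the N x N block grid, axis reordering) yields
  per-block index predictions in normalized units; the local-structure
  feature-similarity loss is the *sum over views and blocks of the per-block
  Euclidean distance* between predicted and true indices.

The total objective is ``L_c + lambda_sm * L_sm`` (``lambda_sm`` = 1 by
default).  Labels and predictions enter the similarity loss in normalized
units (raw centered indices divided by ``Z = sqrt(2)(N-1)/2``) so that the
tanh-saturated head can represent every reachable label; multiplying by ``Z``
recovers the raw-unit value.

The backbone contract is any map from an image to a (C, H, W) activation
grid.  The bundled :class:`ConvBackbone` is a small strided convnet whose
output grid is augmented with two fixed coordinate channels, sized for
desk-scale experiments; larger backbones plug in through the same interface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .preprocessing import label_scale

__all__ = [
    "PROB_FLOOR",
    "LossValues",
    "classification_loss",
    "lsfsm_loss",
    "lsfsm_loss_and_grad",
    "total_objective",
    "ConvBackbone",
    "ClassificationHead",
    "IndexHead",
    "LSIModel",
]

#: numerical guard inside log(.); a modelling floor, not part of the model
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LossValues:
    """The two loss terms and their weighted total for one batch or epoch."""

    l_c: float
    l_sm: float
    lambda_sm: float = 1.0

    def __post_init__(self) -> None:
        if self.l_c < 0 or self.l_sm < 0:
            raise ValueError("losses must be non-negative")

    @property
    def total(self) -> float:
        return total_objective(self.l_c, self.l_sm, self.lambda_sm)


def classification_loss(
    distributions: list[np.ndarray] | tuple[np.ndarray, ...],
    class_label: np.ndarray,
) -> float:
    """Summed cross-entropy of all augmented views against a one-hot label.

    Returns ``-sum_views l . log(phi(view))`` in nats for one sample; the
    epoch-level loss is the sum of this over the training set.  A zero
    probability at the true class is clamped at :data:`PROB_FLOOR` with a
    warning.
    """
    class_label = np.asarray(class_label, dtype=float)
    total = 0.0
    for dist in distributions:
        dist = np.asarray(dist, dtype=float)
        if dist.shape != class_label.shape:
            raise ValueError(
                f"distribution shape {dist.shape} != label shape {class_label.shape}"
            )
        if np.any(dist < -1e-9) or abs(dist.sum() - 1.0) > 1e-6:
            raise ValueError("each distribution must be a probability vector")
        p_true = float(dist @ class_label)
        if p_true < PROB_FLOOR:
            warnings.warn("true-class probability clamped at floor", RuntimeWarning)
            p_true = PROB_FLOOR
        total -= math.log(p_true)
    return total


def lsfsm_loss(
    predictions: list[np.ndarray] | tuple[np.ndarray, ...],
    labels: list[np.ndarray] | tuple[np.ndarray, ...],
) -> float:
    """Sum over views and blocks of the per-block Euclidean index distance.

    ``predictions[v]`` and ``labels[v]`` are ``(N, N, 2)`` grids in the same
    (normalized) units.  The loss is a sum of per-block 2-D distances, not a
    single global norm, so it is additive over views and blocks.
    """
    if len(predictions) != len(labels):
        raise ValueError("need one prediction grid per label grid")
    total = 0.0
    for pred, lab in zip(predictions, labels):
        pred = np.asarray(pred, dtype=float)
        lab = np.asarray(lab, dtype=float)
        if pred.shape != lab.shape or pred.shape[-1] != 2:
            raise ValueError(f"shape mismatch: {pred.shape} vs {lab.shape}")
        total += float(np.sqrt(((pred - lab) ** 2).sum(axis=-1)).sum())
    return total


def lsfsm_loss_and_grad(pred: np.ndarray, lab: np.ndarray) -> tuple[float, np.ndarray]:
    """Single-view similarity loss and its gradient w.r.t. the predictions."""
    pred = np.asarray(pred, dtype=float)
    lab = np.asarray(lab, dtype=float)
    diff = pred - lab
    dist = np.sqrt((diff**2).sum(axis=-1))
    grad = np.where(dist[..., None] > 1e-12, diff / np.maximum(dist, 1e-12)[..., None], 0.0)
    return float(dist.sum()), grad


def total_objective(l_c: float, l_sm: float, lambda_sm: float = 1.0) -> float:
    """Weighted combination ``L_c + lambda_sm * L_sm`` of the two losses."""
    if lambda_sm < 0:
        raise ValueError(f"lambda_sm must be >= 0, got {lambda_sm}")
    return float(l_c) + float(lambda_sm) * float(l_sm)


class ConvBackbone:
    """Small strided convnet: image (C, H, W) -> feature grid (C', H/8, W/8).

    Three stride-2 3x3 conv + leaky-ReLU stages followed by a stride-1 stage; the
    output grid gets two fixed coordinate channels appended so downstream
    per-cell linear heads can express positional targets.
    """

    def __init__(
        self,
        in_channels: int = 1,
        widths: tuple[int, ...] = (8, 16, 32),
        rng: np.random.Generator | None = None,
        input_offset: float = 0.5,
    ) -> None:
        rng = rng or np.random.default_rng()
        self.input_offset = input_offset
        layers: list = []
        cin = in_channels
        for cout in widths:
            layers.append(nn.Conv2D(cin, cout, ksize=3, stride=2, pad=1, rng=rng))
            layers.append(nn.LeakyReLU())
            cin = cout
        layers.append(nn.Conv2D(cin, cin, ksize=3, stride=1, pad=1, rng=rng))
        layers.append(nn.LeakyReLU())
        layers.append(nn.CoordAppend())
        self.net = nn.Sequential(*layers)
        self.out_channels = widths[-1] + 2

    def forward(self, image: np.ndarray) -> tuple[np.ndarray, list]:
        image = np.asarray(image, dtype=float) - self.input_offset
        if image.ndim == 2:
            image = image[None]
        return self.net.forward(image)

    def backward(self, grad: np.ndarray, caches: list) -> np.ndarray:
        return self.net.backward(grad, caches)

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.net.params()


class ClassificationHead:
    """Global average pooling followed by a fully connected softmax classifier."""

    def __init__(self, in_channels: int, n_classes: int, rng: np.random.Generator | None = None) -> None:
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_channels, n_classes, rng=rng)
        self.n_classes = n_classes

    def forward(self, fmap: np.ndarray) -> tuple[np.ndarray, tuple]:
        pooled, pcache = self.pool.forward(fmap)
        logits, lcache = self.fc.forward(pooled)
        return nn.softmax(logits), (pcache, lcache)

    def backward(self, glogits: np.ndarray, cache: tuple) -> np.ndarray:
        pcache, lcache = cache
        return self.pool.backward(self.fc.backward(glogits, lcache), pcache)

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.fc.params()


class IndexHead:
    """Per-block index predictor: 1x1 projection, tanh, adaptive pool, reorder.

    Every spatial cell of the feature map is projected to two channels by a
    learned linear map, squashed by tanh into (-1, 1), average-pooled onto the
    ``N x N`` block grid and reordered to per-block ``(first, second)``
    coordinate pairs — shape ``(N, N, 2)``, in normalized index units.

    The projection may be *per view* (``n_views > 1``): the group of augmented
    views carries view-specific label maps (each rotation has its own index
    rotation), and a per-view projection lets the head represent each view's
    map.  ``n_views = 1`` shares one projection across all views.
    """

    def __init__(
        self,
        in_channels: int,
        n_blocks: int,
        n_views: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, math.sqrt(1.0 / in_channels), (n_views, 2, in_channels))
        self.b = np.zeros((n_views, 2))
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.n_blocks = n_blocks
        self.n_views = n_views
        self.tanh = nn.Tanh()
        self.pool = nn.AdaptiveAvgPool2D(n_blocks)

    def forward(self, fmap: np.ndarray, view: int = 0) -> tuple[np.ndarray, tuple]:
        c, h, w_ = fmap.shape
        if h < self.n_blocks or w_ < self.n_blocks:
            raise ValueError(
                f"feature map {h}x{w_} smaller than block grid "
                f"{self.n_blocks}x{self.n_blocks}"
            )
        if not 0 <= view < self.n_views:
            raise ValueError(f"view {view} out of range 0..{self.n_views - 1}")
        z = np.tensordot(self.w[view], fmap, axes=([1], [0])) + self.b[view][:, None, None]
        t, tcache = self.tanh.forward(z)
        pooled, pcache = self.pool.forward(t)
        pred = pooled.transpose(1, 2, 0)  # (N, N, 2)
        return pred, (fmap, tcache, pcache, view)

    def backward(self, gpred: np.ndarray, cache: tuple) -> np.ndarray:
        fmap, tcache, pcache, view = cache
        gt = self.pool.backward(gpred.transpose(2, 0, 1), pcache)
        gz = self.tanh.backward(gt, tcache)
        self.gw[view] += np.tensordot(gz, fmap, axes=([1, 2], [1, 2]))
        self.gb[view] += gz.sum(axis=(1, 2))
        return np.tensordot(self.w[view], gz, axes=([0], [0]))

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.w, self.gw), (self.b, self.gb)]


class LSIModel:
    """Backbone plus both heads, wired for multi-view training.

    Parameters mirror the desk-scale defaults; the class-count, block-grid
    size and number of views come from the experiment configuration.
    """

    def __init__(
        self,
        n_classes: int,
        n_blocks: int,
        n_views: int,
        in_channels: int = 1,
        widths: tuple[int, ...] = (8, 16, 32),
        seed: int = 0,
        per_view_index_head: bool = True,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.backbone = ConvBackbone(in_channels=in_channels, widths=widths, rng=rng)
        self.cls_head = ClassificationHead(self.backbone.out_channels, n_classes, rng=rng)
        self.index_head = IndexHead(
            self.backbone.out_channels,
            n_blocks,
            n_views=n_views if per_view_index_head else 1,
            rng=rng,
        )
        self.n_classes = n_classes
        self.n_blocks = n_blocks
        self.n_views = n_views
        self.label_scale = label_scale(n_blocks)

    def forward_view(self, image: np.ndarray) -> tuple[np.ndarray, list]:
        """Backbone pass for one view; heads are applied on the result."""
        return self.backbone.forward(image)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        fmap, _ = self.backbone.forward(image)
        probs, _ = self.cls_head.forward(fmap)
        return probs

    def predict_class(self, image: np.ndarray) -> int:
        return int(np.argmax(self.predict_proba(image)))

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.backbone.params() + self.cls_head.params() + self.index_head.params()

    # -- persistence ---------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": w for i, (w, _) in enumerate(self.params())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (w, _) in enumerate(self.params()):
            w[...] = arrays[f"param_{i}"]
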