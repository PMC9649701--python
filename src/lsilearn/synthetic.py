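"""Synthetic fixtures: canonical local structures and toy labeled image sets.

Two families of generators keep every other module testable without any
external data.

*Structure fixtures* are idealized grayscale patches holding exactly one
canonical local structure at the center pixel: a two-level step edge, a
T-type junction (a contrasting bar-and-stem stroke on a flat background,
three homogeneous regions meeting at the center), or an isotropic Gaussian
blob.  Their construction parameters (gray levels, orientations, bar width,
blob width) are recorded on the fixture, and the *constructed* truth
category travels with the image so the filter-based classifier can be
checked against it.  Region boundaries are anti-aliased (the junction by 4x
supersampling, the edge by an analytic one-pixel linear ramp) so that
discrete orientation profiles are smooth enough for extrema counting.

*Toy datasets* emulate a fine-grained classification regime at desk scale:
each class is a distinct parametric silhouette (disk, square, triangle,
star, cross, annulus, ellipse, diamond) rendered with small per-image jitter
(position <= 5% of the image size, rotation <= 10 degrees) and additive
Gaussian noise (sigma = 0.02).  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructureFixture",
    "ToyDataset",
    "make_step_edge",
    "make_t_corner",
    "make_blob",
    "make_toy_dataset",
    "SHAPE_FAMILIES",
]

DEFAULT_FIXTURE_SIZE = 129  # odd, feature point at the exact center


@dataclass(frozen=True)
class StructureFixture:
    """A synthetic image holding one canonical structure at ``feature_point``."""

    image: np.ndarray
    feature_point: tuple[int, int]
    truth: str  # {"corner", "edge", "blob", "none"}
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ToyDataset:
    """A balanced, seeded toy classification set with a disjoint split."""

    images: np.ndarray  # (n, H, W) in [0, 1]-ish (noise may leak slightly out)
    labels: np.ndarray  # (n,) integer class ids
    train_idx: np.ndarray
    test_idx: np.ndarray
    n_classes: int
    seed: int
    params: dict = field(default_factory=dict)

    def split(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (
            self.images[self.train_idx],
            self.labels[self.train_idx],
            self.images[self.test_idx],
            self.labels[self.test_idx],
        )


def _center_xy(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian coordinates (x rightward, y upward) about the center pixel."""
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    return cols - c, c - rows


def make_step_edge(
    size: int = DEFAULT_FIXTURE_SIZE,
    orientation: float = math.pi / 2,
    levels: tuple[float, float] = (0.2, 0.8),
    blur_sigma: float = 0.0,
) -> StructureFixture:
    """Two half-planes split along ``orientation`` through the center.

    ``orientation`` is the angle of the boundary *line* (default pi/2: a
    vertical edge, low level on the left).  The transition is a one-pixel
    linear ramp, optionally further smoothed by a Gaussian of ``blur_sigma``.
    Degenerate levels (low == high) give a constant image with truth "none".
    """
    low, high = levels
    if not (0.0 <= low <= high <= 1.0):
        raise ValueError(f"need 0 <= low <= high <= 1, got {levels}")
    x, y = _center_xy(size)
    # signed distance along the boundary normal; positive side gets `high`
    nx, ny = math.cos(orientation - math.pi / 2), math.sin(orientation - math.pi / 2)
    s = x * nx + y * ny
    image = low + (high - low) * np.clip(s + 0.5, 0.0, 1.0)
    if blur_sigma > 0:
        from scipy import ndimage

        image = ndimage.gaussian_filter(image, blur_sigma, mode="nearest")
    truth = "none" if low == high else "edge"
    return StructureFixture(
        image=image,
        feature_point=(size // 2, size // 2),
        truth=truth,
        params={"orientation": orientation, "levels": levels, "blur_sigma": blur_sigma},
    )


def make_t_corner(
    size: int = DEFAULT_FIXTURE_SIZE,
    levels: tuple[float, float, float] = (0.9, 0.1, 0.5),
    bar_width: float = 1.5,
    orientation: float = 0.0,
    supersample: int = 4,
) -> StructureFixture:
    """A T-type junction: a stroke T (bar plus stem) on a flat background.

    The canonical T (``orientation = 0``) is a horizontal bar of half-width
    ``bar_width`` through the center at gray ``levels[1]`` and a vertical
    stem of the same half-width descending from it at ``levels[2]``, on a
    background of ``levels[0]`` -- three homogeneous regions meeting at the
    center, with two collinear arms and one perpendicular arm, the way
    junctions appear between contrasting strips (frames, mullions, walls) in
    real photographs.  ``orientation`` rotates the whole junction; boundaries
    are anti-aliased by ``supersample``-fold supersampling.

    With three distinct levels the first-order orientation profile at the
    junction has three circular maxima and three minima.  Degeneracies are
    reflected in the truth label: a uniform stroke (bar == stem) or an
    invisible bar (bar == background, leaving a terminating line) are still
    corner-type structures; an invisible stem (stem == background) leaves a
    symmetric ridge whose first-order response vanishes at the center
    (truth "none"); a single level gives a constant image ("none").
    """
    g_bg, g_bar, g_stem = levels
    n_hi = size * supersample
    c = (n_hi - 1) / 2.0
    rows, cols = np.mgrid[0:n_hi, 0:n_hi]
    x = (cols - c) / supersample
    y = (c - rows) / supersample
    if orientation:
        ct, st = math.cos(-orientation), math.sin(-orientation)
        x, y = x * ct - y * st, x * st + y * ct
    hi = np.full((n_hi, n_hi), float(g_bg))
    hi[(np.abs(x) <= bar_width) & (y < 0)] = g_stem
    hi[np.abs(y) <= bar_width] = g_bar
    image = hi.reshape(size, supersample, size, supersample).mean(axis=(1, 3))
    distinct = len({g_bg, g_bar, g_stem})
    if distinct == 3:
        truth = "corner"
    elif distinct == 1:
        truth = "none"
        warnings.warn("T-junction degenerated to a constant image", RuntimeWarning)
    elif g_stem == g_bg:  # bar only: symmetric ridge, zero first-order center response
        truth = "none"
        warnings.warn("T-junction degenerated to a symmetric ridge", RuntimeWarning)
    else:  # uniform stroke or terminating line: still corner-type
        truth = "corner"
        warnings.warn("T-junction degenerated but remains corner-type", RuntimeWarning)
    return StructureFixture(
        image=image,
        feature_point=(size // 2, size // 2),
        truth=truth,
        params={"levels": levels, "bar_width": bar_width, "orientation": orientation},
    )


def make_blob(
    size: int = DEFAULT_FIXTURE_SIZE,
    sigma_b: float = 6.0,
    amplitude: float = 0.6,
    background: float = 0.2,
) -> StructureFixture:
    """Isotropic Gaussian bump of width ``sigma_b`` on a flat background."""
    if sigma_b <= 0:
        raise ValueError(f"sigma_b must be positive, got {sigma_b}")
    if amplitude == 0:
        raise ValueError("amplitude must be nonzero")
    if 3.0 * sigma_b > (size - 1) / 2.0:
        warnings.warn("blob is clipped by the image border", RuntimeWarning)
    x, y = _center_xy(size)
    image = background + amplitude * np.exp(-(x**2 + y**2) / (2.0 * sigma_b**2))
    return StructureFixture(
        image=image,
        feature_point=(size // 2, size // 2),
        truth="blob",
        params={"sigma_b": sigma_b, "amplitude": amplitude, "background": background},
    )


# -- toy fine-grained datasets ----------------------------------------------


def _shape_mask(family: str, x: np.ndarray, y: np.ndarray, r: float) -> np.ndarray:
    """Boolean silhouette of a parametric shape of nominal radius ``r``."""
    if family == "disk":
        return x**2 + y**2 <= r**2
    if family == "square":
        return (np.abs(x) <= r * 0.85) & (np.abs(y) <= r * 0.85)
    if family == "triangle":
        return (y <= r * 0.8) & (y >= -r * 0.7 + 1.8 * np.abs(x))
    if family == "star":
        theta = np.arctan2(y, x)
        radius = np.hypot(x, y)
        return radius <= r * (0.55 + 0.45 * np.cos(5 * theta))
    if family == "cross":
        return (np.abs(x) <= r * 0.3) | (np.abs(y) <= r * 0.3)
    if family == "annulus":
        rad2 = x**2 + y**2
        return (rad2 <= r**2) & (rad2 >= (0.55 * r) ** 2)
    if family == "ellipse":
        return (x / r) ** 2 + (y / (0.45 * r)) ** 2 <= 1.0
    if family == "diamond":
        return np.abs(x) + np.abs(y) <= r
    raise ValueError(f"unknown shape family {family!r}")


SHAPE_FAMILIES = (
    "disk",
    "cross",
    "triangle",
    "star",
    "annulus",
    "square",
    "ellipse",
    "diamond",
)


def make_toy_dataset(
    n_classes: int = 5,
    n_per_class: int = 10,
    size: int = 48,
    seed: int = 0,
    position_jitter: float = 0.05,
    rotation_jitter: float = math.radians(10.0),
    noise_sigma: float = 0.02,
    foreground: float = 0.85,
    background: float = 0.15,
    supersample: int = 2,
) -> ToyDataset:
    """Balanced toy image set: one silhouette family per class, jittered.

    Each image places its class silhouette near the center with a uniformly
    drawn offset (up to ``position_jitter`` of the image size per axis), a
    uniformly drawn rotation (up to ``rotation_jitter`` radians either way)
    and i.i.d. Gaussian pixel noise.  Within a class the first
    ``n_per_class - n_per_class // 2`` images are the training split, the
    rest the test split (disjoint by construction).  Everything is a pure
    function of the arguments and ``seed``.
    """
    if n_classes < 2:
        raise ValueError(f"need at least 2 classes, got {n_classes}")
    if n_per_class < 2:
        raise ValueError(f"need at least 2 images per class to split, got {n_per_class}")
    if n_classes > len(SHAPE_FAMILIES):
        raise ValueError(
            f"at most {len(SHAPE_FAMILIES)} classes supported, got {n_classes}"
        )
    rng = np.random.default_rng(seed)
    n_hi = size * supersample
    c = (n_hi - 1) / 2.0
    rows, cols = np.mgrid[0:n_hi, 0:n_hi]
    x0 = (cols - c) / supersample
    y0 = (c - rows) / supersample
    radius = 0.32 * size
    images = np.empty((n_classes * n_per_class, size, size))
    labels = np.empty(n_classes * n_per_class, dtype=int)
    idx = 0
    for cls in range(n_classes):
        family = SHAPE_FAMILIES[cls]
        for _ in range(n_per_class):
            dx, dy = rng.uniform(-position_jitter, position_jitter, size=2) * size
            ang = rng.uniform(-rotation_jitter, rotation_jitter)
            ct, st = math.cos(-ang), math.sin(-ang)
            xs = (x0 - dx) * ct - (y0 - dy) * st
            ys = (x0 - dx) * st + (y0 - dy) * ct
            mask = _shape_mask(family, xs, ys, radius)
            img = np.where(mask, foreground, background).astype(float)
            img = img.reshape(size, supersample, size, supersample).mean(axis=(1, 3))
            img += rng.normal(0.0, noise_sigma, size=img.shape)
            images[idx] = img
            labels[idx] = cls
            idx += 1
    n_train = n_per_class - n_per_class // 2
    train_idx, test_idx = [], []
    for cls in range(n_classes):
        base = cls * n_per_class
        train_idx.extend(range(base, base + n_train))
        test_idx.extend(range(base + n_train, base + n_per_class))
    return ToyDataset(
        images=images,
        labels=labels,
        train_idx=np.asarray(train_idx),
        test_idx=np.asarray(test_idx),
        n_classes=n_classes,
        seed=seed,
        params={
            "n_per_class": n_per_class,
            "size": size,
            "position_jitter": position_jitter,
            "rotation_jitter": rotation_jitter,
            "noise_sigma": noise_sigma,
        },
    )
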