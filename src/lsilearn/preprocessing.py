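"""Information preprocessing: block shuffling, rotation schedules, index labels.

A training image is partitioned into an ``N x N`` grid of sub-image blocks.
Each block carries a *centered* grid index ``(i, j)`` -- ``i`` horizontal
(rightward positive), ``j`` vertical (upward positive) -- taking the ``N``
symmetric values ``{-(N-1)/2, ..., (N-1)/2}`` in unit steps (half-integers
when ``N`` is even).  From one input image the pipeline derives an augmented
group: rotated copies of the original, plus a block-shuffled copy (blocks
placed uniformly at random) and optionally rotated copies of it.

Index labels travel with the group:

* a rotation by angle ``a`` maps each block index by the row-vector product
  ``[u, v] = [i, j] @ R(a)`` with ``R = [[cos a, -sin a], [sin a, cos a]]``;
  the mapped labels are continuous and are never snapped back to the grid;
* the shuffled image's labels are recovered by gray-value matching: each
  original block's index is assigned to the shuffled grid position whose
  block has the closest mean gray value, under a one-to-one matching;
* rotated shuffled images compose the two: gray-matched labels, then the
  rotation map.

These labels are regression targets for the auxiliary index-prediction head;
dividing them by ``Z = sqrt(2) * (N-1) / 2`` puts every reachable label in
``[-1, 1]`` componentwise, matching a tanh-saturated prediction head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BlockGrid",
    "ShuffleRecord",
    "RotationSchedule",
    "AugmentedSet",
    "to_gray",
    "centered_index_coords",
    "partition_blocks",
    "unshuffle",
    "assemble_blocks",
    "shuffle_blocks",
    "rotation_matrix",
    "rotation_matrix_from_angle",
    "map_block_index",
    "rotate_image",
    "assign_shuffled_indices",
    "label_scale",
    "build_augmented_set",
]


def to_gray(image: np.ndarray) -> np.ndarray:
    """Reduce a multi-channel image to gray by averaging channels.

    One luminance rule is used everywhere in the package (filtering and
    block-mean matching alike): the plain per-pixel channel mean.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image.mean(axis=2)
    if image.ndim == 2:
        return image
    raise ValueError(f"expected (H, W) or (H, W, C) image, got shape {image.shape}")


@dataclass(frozen=True)
class BlockGrid:
    """An ``N x N`` partition of an image into equal blocks with centered indices.

    ``blocks[a, b]`` is the patch at grid row ``a``, grid column ``b``;
    ``index_coords[a, b] = (i, j)`` is its centered Cartesian index.
    """

    blocks: np.ndarray  # (N, N, bh, bw[, C])
    index_coords: np.ndarray  # (N, N, 2)
    n_blocks: int

    @property
    def block_shape(self) -> tuple[int, int]:
        return self.blocks.shape[2], self.blocks.shape[3]

    def block_means(self) -> np.ndarray:
        """Mean gray value of every block, shape (N, N)."""
        axes = tuple(range(2, self.blocks.ndim))
        return self.blocks.mean(axis=axes)


@dataclass(frozen=True)
class ShuffleRecord:
    """A seeded uniform permutation of block positions and its result.

    ``permutation[s] = t`` sends the block at flat source position ``s``
    (row-major over the grid) to flat target position ``t``.
    """

    permutation: np.ndarray
    seed: int
    shuffled_image: np.ndarray


@dataclass(frozen=True)
class RotationSchedule:
    """Rotation angles for the original and the shuffled image.

    The first angle of each list must be 0, so the first rotated original is
    the input itself and the first rotated shuffled image is the shuffle
    itself.  ``uniform(K1, K2)`` spaces angles by ``pi/K`` over
    ``[0, (K-1)*pi/K]``; ``recommended()`` is the 4-image group found best in
    ablations: the original, its pi/6 and pi/4 rotations, and the shuffle.
    """

    angles_original: tuple[float, ...] = (0.0,)
    angles_shuffled: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles_original", tuple(float(a) for a in self.angles_original))
        object.__setattr__(self, "angles_shuffled", tuple(float(a) for a in self.angles_shuffled))
        if not self.angles_original:
            raise ValueError("schedule needs at least one original-image angle")
        if abs(self.angles_original[0]) > 1e-12:
            raise ValueError("first original angle must be 0 (I_1 = I)")
        if self.angles_shuffled and abs(self.angles_shuffled[0]) > 1e-12:
            raise ValueError("first shuffled angle must be 0 (S_1 = S)")

    @property
    def k1(self) -> int:
        return len(self.angles_original)

    @property
    def k2(self) -> int:
        return len(self.angles_shuffled)

    @property
    def n_views(self) -> int:
        return self.k1 + self.k2

    @classmethod
    def uniform(cls, k1: int, k2: int = 0) -> "RotationSchedule":
        if k1 < 1 or k2 < 0:
            raise ValueError(f"need k1 >= 1 and k2 >= 0, got {k1}, {k2}")
        return cls(
            angles_original=tuple((k * math.pi / k1) for k in range(k1)),
            angles_shuffled=tuple((k * math.pi / k2) for k in range(k2)),
        )

    @classmethod
    def recommended(cls) -> "RotationSchedule":
        return cls(
            angles_original=(0.0, math.pi / 6, math.pi / 4),
            angles_shuffled=(0.0,),
        )

    def rotation_matrices(self) -> list[np.ndarray]:
        """One matrix per view, in view order (originals then shuffleds)."""
        return [
            rotation_matrix_from_angle(a)
            for a in (*self.angles_original, *self.angles_shuffled)
        ]


@dataclass(frozen=True)
class AugmentedSet:
    """The training group {I_1..I_K1, S_1..S_K2} with labels for one input image.

    ``labels[view][a, b] = (u, v)`` are raw centered index labels;
    ``normalized_labels`` divides by ``Z = sqrt(2) * (N-1) / 2``.
    """

    images: tuple[np.ndarray, ...]
    labels: tuple[np.ndarray, ...]
    class_label: np.ndarray
    schedule: RotationSchedule
    n_blocks: int
    shuffle: ShuffleRecord | None

    def __post_init__(self) -> None:
        if len(self.images) != self.schedule.n_views:
            raise ValueError("one image per scheduled view required")
        if abs(float(self.class_label.sum()) - 1.0) > 1e-9:
            raise ValueError("class_label must be one-vs-all (sum to 1)")

    @property
    def label_scale(self) -> float:
        return label_scale(self.n_blocks)

    @property
    def normalized_labels(self) -> tuple[np.ndarray, ...]:
        z = self.label_scale
        return tuple(lab / z for lab in self.labels)


def centered_index_coords(n: int) -> np.ndarray:
    """Centered block indices, shape (N, N, 2) of (i horizontal, j vertical)."""
    offset = (n - 1) / 2.0
    coords = np.empty((n, n, 2))
    for a in range(n):  # grid row: j decreases downward
        for b in range(n):  # grid column: i increases rightward
            coords[a, b] = (b - offset, offset - a)
    return coords


def label_scale(n: int) -> float:
    """Normalization constant Z = sqrt(2)*(N-1)/2 (1 for the degenerate N=1)."""
    return math.sqrt(2.0) * (n - 1) / 2.0 if n > 1 else 1.0


def partition_blocks(image: np.ndarray, n: int) -> BlockGrid:
    """Partition an image into an ``N x N`` :class:`BlockGrid`.

    If the height/width is not divisible by ``N`` the image is center-cropped
    to the largest divisible size first.  Reassembling the blocks reproduces
    the (cropped) image bit-exactly.
    """
    image = np.asarray(image)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    h, w = image.shape[:2]
    if n > h or n > w:
        raise ValueError(f"n={n} exceeds image size {h}x{w}")
    bh, bw = h // n, w // n
    top, left = (h - bh * n) // 2, (w - bw * n) // 2
    cropped = image[top : top + bh * n, left : left + bw * n]
    trailing = cropped.shape[2:]
    blocks = (
        cropped.reshape(n, bh, n, bw, *trailing)
        .swapaxes(1, 2)
        .copy()
    )
    return BlockGrid(blocks=blocks, index_coords=centered_index_coords(n), n_blocks=n)


def assemble_blocks(grid: BlockGrid) -> np.ndarray:
    """Inverse of :func:`partition_blocks` (on the cropped image)."""
    n = grid.n_blocks
    bh, bw = grid.block_shape
    trailing = grid.blocks.shape[4:]
    return grid.blocks.swapaxes(1, 2).reshape(n * bh, n * bw, *trailing)


def shuffle_blocks(grid: BlockGrid, seed: int) -> ShuffleRecord:
    """Place every block at a uniformly random grid position (seeded).

    The permutation is drawn uniformly from all ``(N^2)!`` arrangements with
    ``numpy``'s seeded generator, so the shuffle is reproducible and the pixel
    multiset is conserved exactly.
    """
    n = grid.n_blocks
    rng = np.random.default_rng(seed)
    permutation = rng.permutation(n * n)
    shuffled = np.empty_like(grid.blocks)
    flat_src = grid.blocks.reshape(n * n, *grid.blocks.shape[2:])
    flat_dst = shuffled.reshape(n * n, *grid.blocks.shape[2:])
    for s, t in enumerate(permutation):
        flat_dst[t] = flat_src[s]
    shuffled_grid = BlockGrid(blocks=shuffled, index_coords=grid.index_coords, n_blocks=n)
    return ShuffleRecord(
        permutation=permutation, seed=seed, shuffled_image=assemble_blocks(shuffled_grid)
    )


def unshuffle(record: ShuffleRecord, n: int) -> np.ndarray:
    """Apply the inverse of a recorded permutation; reproduces the original."""
    grid = partition_blocks(record.shuffled_image, n)
    flat = grid.blocks.reshape(n * n, *grid.blocks.shape[2:])
    # permutation[s] = t, so the original block s sits at shuffled position t
    restored = flat[record.permutation].reshape(grid.blocks.shape)
    grid2 = BlockGrid(blocks=restored, index_coords=grid.index_coords, n_blocks=n)
    return assemble_blocks(grid2)


def rotation_matrix(k: int, n_rotations: int) -> np.ndarray:
    """Rotation matrix of the ``k``-th scheduled view, angle ``(k-1)*pi/K``.

    ``k`` is 1-based; ``k = 1`` is the identity (the unrotated view).
    """
    if not (1 <= k <= n_rotations):
        raise ValueError(f"k={k} out of range 1..{n_rotations}")
    return rotation_matrix_from_angle((k - 1) * math.pi / n_rotations)


def rotation_matrix_from_angle(angle: float) -> np.ndarray:
    """2x2 counterclockwise rotation matrix for an arbitrary angle."""
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


def map_block_index(index: tuple[float, float] | np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-vector index map ``[u, v] = [i, j] @ R``.

    The result is continuous: rotated labels are regression targets and are
    not snapped back to the block grid.
    """
    index = np.asarray(index, dtype=float)
    r = np.asarray(r, dtype=float)
    if r.shape != (2, 2):
        raise ValueError(f"rotation matrix must be 2x2, got {r.shape}")
    if not np.allclose(r.T @ r, np.eye(2), atol=1e-9):
        raise ValueError("rotation matrix must be orthonormal")
    return index @ r


def rotate_image(image: np.ndarray, angle: float) -> np.ndarray:
    """Rotate counterclockwise about the image center, same output size.

    Bilinear interpolation with zero fill outside the support.  Angles 0 and
    pi are computed as exact index operations (identity and both-axis flip).
    """
    image = np.asarray(image, dtype=float)
    a = float(angle) % (2.0 * math.pi)
    if not 0.0 <= a < 2.0 * math.pi:  # numerical wrap guard
        a = 0.0
    if abs(a) < 1e-12 or abs(a - 2.0 * math.pi) < 1e-12:
        return image.copy()
    if abs(a - math.pi) < 1e-12:
        return image[::-1, ::-1].copy()
    # scipy rotates in the (row, col) plane; positive angle there is
    # counterclockwise for the y-up convention when axes=(1, 0)
    return ndimage.rotate(
        image,
        math.degrees(a),
        axes=(1, 0),
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )


def assign_shuffled_indices(original: BlockGrid, shuffled: BlockGrid) -> np.ndarray:
    """Recover index labels for a shuffled grid by mean-gray matching.

    Each original block's index ``(i, j)`` is assigned to the shuffled grid
    position whose block mean gray value is closest, under a one-to-one
    matching: candidate (original, position) pairs are visited in ascending
    order of absolute mean discrepancy (ties broken by raster order) and
    greedily accepted, so every position receives exactly one label.  When all
    block means are distinct this equals the naive per-block closest-mean rule
    and recovers the true inverse permutation.
    """
    if original.n_blocks != shuffled.n_blocks:
        raise ValueError("grids must have the same N")
    if original.block_shape != shuffled.block_shape:
        raise ValueError("grids must have the same block size")
    n = original.n_blocks
    mo = original.block_means().reshape(-1)
    ms = shuffled.block_means().reshape(-1)
    diff = np.abs(mo[:, None] - ms[None, :])
    order = np.argsort(diff, axis=None, kind="stable")  # raster-order tie-break
    labels = np.full((n * n, 2), np.nan)
    used_src = np.zeros(n * n, dtype=bool)
    used_dst = np.zeros(n * n, dtype=bool)
    flat_coords = original.index_coords.reshape(-1, 2)
    assigned = 0
    for flat in order:
        s, t = divmod(int(flat), n * n)
        if used_src[s] or used_dst[t]:
            continue
        labels[t] = flat_coords[s]
        used_src[s] = used_dst[t] = True
        assigned += 1
        if assigned == n * n:
            break
    return labels.reshape(n, n, 2)


def _one_hot(class_label: int | np.ndarray, n_classes: int | None) -> np.ndarray:
    if np.isscalar(class_label) or np.asarray(class_label).ndim == 0:
        if n_classes is None:
            raise ValueError("n_classes required for an integer class label")
        vec = np.zeros(n_classes)
        vec[int(class_label)] = 1.0
        return vec
    vec = np.asarray(class_label, dtype=float)
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError("class label vector must sum to 1")
    return vec


def build_augmented_set(
    image: np.ndarray,
    class_label: int | np.ndarray,
    schedule: RotationSchedule,
    n: int,
    seed: int,
    n_classes: int | None = None,
) -> AugmentedSet:
    """Build the full augmented group and its index labels for one image.

    Views are the scheduled rotations of the input followed by the scheduled
    rotations of its block-shuffled copy.  Labels: rotated originals get
    ``index_coords @ R``; the unrotated shuffle gets gray-matched labels; a
    rotated shuffle gets the gray-matched labels mapped through its ``R``.
    """
    image = np.asarray(image, dtype=float)
    grid = partition_blocks(image, n)
    base = assemble_blocks(grid)  # center-cropped to divisibility
    images: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for angle in schedule.angles_original:
        r = rotation_matrix_from_angle(angle)
        images.append(rotate_image(base, angle))
        labels.append(grid.index_coords @ r)
    record: ShuffleRecord | None = None
    if schedule.k2 > 0:
        record = shuffle_blocks(grid, seed)
        shuffled_grid = partition_blocks(record.shuffled_image, n)
        s1_labels = assign_shuffled_indices(grid, shuffled_grid)
        for angle in schedule.angles_shuffled:
            r = rotation_matrix_from_angle(angle)
            images.append(rotate_image(record.shuffled_image, angle))
            labels.append(s1_labels @ r)
    return AugmentedSet(
        images=tuple(images),
        labels=tuple(labels),
        class_label=_one_hot(class_label, n_classes),
        schedule=schedule,
        n_blocks=n,
        shuffle=record,
    )
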