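"""Anisotropic Gaussian directional-derivative analysis of local image structure.

The canonical local structures of a grayscale image -- step edges, corners
(junctions) and blobs -- are distinguished by how their directional-derivative
response varies as the filter orientation sweeps ``[0, 2*pi)``:

* a step edge responds with a single sinusoid-like lobe pair: one circular
  local maximum and one minimum of the first-order profile;
* a T-type junction, where three homogeneous regions meet, produces three
  maxima and three minima;
* an isotropic blob gives a (near-)zero first-order response at its center by
  symmetry, while its second-order response is large at every orientation.

Sampling the profile at two orthogonal orientations only -- what a plain
horizontal/vertical derivative pair does -- cannot separate these cases; the
full multi-orientation profile can.  This module builds the oriented filters,
computes per-pixel orientation profiles and whole-image response stacks, and
classifies structures from the extrema pattern of their profiles.

The filters are first/second derivatives, along the steering direction, of an
anisotropic Gaussian: the Gaussian is elongated across the steering direction
by the anisotropy factor ``rho`` so that the response concentrates on
intensity variation *along* the chosen orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FilterParams",
    "OrientationProfile",
    "StructureLabel",
    "DetectionThresholds",
    "build_directional_kernel",
    "directional_response",
    "orientation_angles",
    "count_circular_extrema",
    "classify_structure",
    "default_thresholds",
    "response_map",
]

_SQRT15 = math.sqrt(1.5)


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the anisotropic Gaussian directional-derivative filter bank.

    Parameters
    ----------
    sigma : float
        Scale factor of the Gaussian envelope, in pixels. Default ``sqrt(1.5)``.
    rho : float
        Anisotropy factor (>= 1, dimensionless); the Gaussian is compressed by
        ``rho`` along the steering direction and stretched by ``rho`` across
        it. ``rho = 1`` recovers the isotropic Gaussian derivative. Default
        ``sqrt(1.5)``.
    support_radius : int, optional
        Half-width of the discrete square kernel, in pixels. Defaults to
        ``ceil(4 * sigma * rho)``, which truncates less than 1e-6 of the
        envelope mass at the default scale.
    n_orientations : int
        Number ``P`` of sampled filter orientations ``theta_p = 2*pi*p/P``.
        Must be even (so that ``theta`` and ``theta + pi`` are both sampled)
        and at least 8.
    """

    sigma: float = _SQRT15
    rho: float = _SQRT15
    support_radius: int | None = None
    n_orientations: int = 64

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (self.rho >= 1):
            raise ValueError(f"rho must be >= 1, got {self.rho}")
        if self.support_radius is None:
            object.__setattr__(
                self, "support_radius", int(math.ceil(4 * self.sigma * self.rho))
            )
        min_radius = int(math.ceil(3 * self.sigma * self.rho))
        if self.support_radius < min_radius:
            raise ValueError(
                f"support_radius={self.support_radius} too small for "
                f"sigma*rho={self.sigma * self.rho:.3f}; need >= {min_radius}"
            )
        if self.n_orientations < 8 or self.n_orientations % 2:
            raise ValueError(
                f"n_orientations must be even and >= 8, got {self.n_orientations}"
            )


@dataclass(frozen=True)
class OrientationProfile:
    """Directional-derivative responses at one pixel over the orientation set.

    ``responses[p]`` is the order-``order`` response at orientation
    ``theta_p = 2*pi*p/P``.  First-order profiles are antisymmetric under
    ``theta -> theta + pi`` (odd kernel), second-order profiles symmetric.
    """

    responses: np.ndarray
    order: int
    location: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", np.asarray(self.responses, dtype=float))
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order}")

    @property
    def n_orientations(self) -> int:
        return len(self.responses)

    @property
    def angles(self) -> np.ndarray:
        return orientation_angles(self.n_orientations)


@dataclass(frozen=True)
class StructureLabel:
    """Classification of a local structure from its orientation profiles."""

    category: str  # one of {"corner", "edge", "blob", "none"}
    n_maxima: int
    n_minima: int
    blob_score: float


@dataclass(frozen=True)
class DetectionThresholds:
    """Decision thresholds for :func:`classify_structure`.

    ``t1`` bounds the first-order peak magnitude below which a point is
    considered flat enough to be a blob candidate; ``t2`` is the minimum
    second-order peak magnitude a blob must reach.  See
    :func:`default_thresholds` for the calibrated defaults.
    """

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t1 < 0 or self.t2 < 0:
            raise ValueError("thresholds must be non-negative")


def orientation_angles(n_orientations: int) -> np.ndarray:
    """Return the sampled filter orientations ``2*pi*p/P, p = 0..P-1``."""
    return 2.0 * np.pi * np.arange(n_orientations) / n_orientations


def build_directional_kernel(
    params: FilterParams, theta: float, order: int
) -> np.ndarray:
    """Sample the order-1/2 anisotropic Gaussian directional-derivative kernel.

    The anisotropic Gaussian steered to ``theta`` is

    ``g(x, y) = 1/(2*pi*sigma^2) * exp(-(rho^2 u^2 + v^2/rho^2)/(2 sigma^2))``

    with ``u = x cos(theta) + y sin(theta)`` the coordinate along the steering
    direction and ``v`` the coordinate across it.  The returned kernel is
    ``d g/d u`` (order 1) or ``d^2 g/d u^2`` (order 2), sampled on the integer
    grid and mean-subtracted so that it sums exactly to zero (constant images
    then respond with exactly zero).

    Grid convention: row-major arrays, ``x`` along columns, ``y`` pointing up
    (i.e. ``y = -row`` offset), ``theta`` counterclockwise from +x.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    r = params.support_radius
    rows, cols = np.mgrid[-r : r + 1, -r : r + 1]
    x = cols.astype(float)
    y = -rows.astype(float)  # image rows grow downward; flip to y-up Cartesian
    ct, st = math.cos(theta), math.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    sig2 = params.sigma**2
    rho2 = params.rho**2
    g = np.exp(-(rho2 * u**2 + v**2 / rho2) / (2.0 * sig2)) / (2.0 * np.pi * sig2)
    if order == 1:
        kernel = -(rho2 * u / sig2) * g
    else:
        kernel = (rho2 / sig2) * (rho2 * u**2 / sig2 - 1.0) * g
    kernel -= kernel.mean()
    return kernel


def _as_gray(image: np.ndarray) -> np.ndarray:
    """Channel-average a (H, W) or (H, W, C) array to a float gray image."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image.mean(axis=2)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D or (H, W, C) image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def directional_response(
    image: np.ndarray,
    location: tuple[int, int],
    params: FilterParams,
    order: int,
) -> OrientationProfile:
    """Orientation profile of the directional derivative at one pixel.

    ``responses[p]`` is the correlation of the image patch centered at
    ``location`` (row, col) with the kernel steered to ``theta_p``.  The
    location must be at least ``support_radius`` from every border: point
    analysis uses no implicit padding.
    """
    image = _as_gray(image)
    r = params.support_radius
    row, col = location
    h, w = image.shape
    if not (r <= row < h - r and r <= col < w - r):
        raise ValueError(
            f"location {location} closer than support_radius={r} to the border "
            f"of a {h}x{w} image"
        )
    patch = image[row - r : row + r + 1, col - r : col + r + 1]
    responses = np.empty(params.n_orientations)
    for p, theta in enumerate(orientation_angles(params.n_orientations)):
        responses[p] = float(np.sum(patch * build_directional_kernel(params, theta, order)))
    return OrientationProfile(responses=responses, order=order, location=(row, col))


def count_circular_extrema(
    profile: OrientationProfile | np.ndarray, eps: float | None = None
) -> tuple[int, int]:
    """Count strict circular local maxima and minima of a profile.

    Runs of circularly adjacent samples whose consecutive differences are
    within ``eps`` are collapsed to a single representative before comparison,
    so a flat-topped peak counts once.  ``eps`` defaults to
    ``1e-3 * max|responses|``.  An (effectively) constant profile has no
    extrema and returns ``(0, 0)``.
    """
    values = np.asarray(
        profile.responses if isinstance(profile, OrientationProfile) else profile,
        dtype=float,
    )
    n = len(values)
    if n < 8:
        raise ValueError(f"profile must have at least 8 samples, got {n}")
    if eps is None:
        eps = 1e-3 * float(np.max(np.abs(values))) if np.any(values) else 0.0
    if np.ptp(values) <= eps:
        return (0, 0)
    # circular plateau merging: split at indices where the wrap-around
    # neighbour differs by more than eps, average each run
    breaks = [i for i in range(n) if abs(values[i] - values[i - 1]) > eps]
    if not breaks:  # slow drift: every step small but range large -> one plateau
        return (0, 0)
    reps = []
    for b, start in enumerate(breaks):
        stop = breaks[(b + 1) % len(breaks)]
        idx = np.arange(start, stop if stop > start else stop + n) % n
        reps.append(values[idx].mean())
    reps_arr = np.asarray(reps)
    m = len(reps_arr)
    if m == 1:
        return (0, 0)
    left = np.roll(reps_arr, 1)
    right = np.roll(reps_arr, -1)
    n_max = int(np.sum((reps_arr > left) & (reps_arr > right)))
    n_min = int(np.sum((reps_arr < left) & (reps_arr < right)))
    return (n_max, n_min)


def classify_structure(
    profile1: OrientationProfile,
    profile2: OrientationProfile,
    thresholds: DetectionThresholds,
) -> StructureLabel:
    """Label a point as corner / edge / blob / none from its two profiles.

    Decision rule (fixed): if the first-order peak magnitude is below ``t1``
    and the second-order peak magnitude at least ``t2``, the point is a blob
    (flat to first order, curved to second).  Otherwise the count of circular
    maxima of the first-order profile decides: >= 2 -> corner, == 1 -> edge,
    else none.
    """
    if profile1.order != 1 or profile2.order != 2:
        raise ValueError("classify_structure expects (order-1, order-2) profiles")
    if profile1.location != profile2.location:
        raise ValueError(
            f"profiles are for different locations: "
            f"{profile1.location} vs {profile2.location}"
        )
    peak1 = float(np.max(np.abs(profile1.responses)))
    peak2 = float(np.max(np.abs(profile2.responses)))
    n_max, n_min = count_circular_extrema(profile1)
    if peak1 < thresholds.t1 and peak2 >= thresholds.t2:
        category = "blob"
    elif n_max >= 2:
        category = "corner"
    elif n_max == 1:
        category = "edge"
    else:
        category = "none"
    return StructureLabel(
        category=category, n_maxima=n_max, n_minima=n_min, blob_score=peak2
    )


def default_thresholds(params: FilterParams | None = None) -> DetectionThresholds:
    """Thresholds calibrated on the canonical synthetic fixtures.

    ``t1`` is 10% of the first-order peak response of the canonical step-edge
    fixture, ``t2`` 50% of the second-order peak response at the center of the
    canonical blob fixture, both at the given filter parameters.
    """
    from .synthetic import make_blob, make_step_edge  # local import: no cycle at load

    params = params or FilterParams()
    edge = make_step_edge()
    blob = make_blob()
    p_edge = directional_response(edge.image, edge.feature_point, params, order=1)
    p_blob = directional_response(blob.image, blob.feature_point, params, order=2)
    t1 = 0.1 * float(np.max(np.abs(p_edge.responses)))
    t2 = 0.5 * float(np.max(np.abs(p_blob.responses)))
    return DetectionThresholds(t1=t1, t2=t2)


def response_map(
    image: np.ndarray,
    params: FilterParams,
    order: int,
    border: str = "reflect",
) -> np.ndarray:
    """Whole-image directional-derivative stack, shape ``(P, H, W)``.

    ``result[p]`` is the correlation of the image with the kernel at
    ``theta_p``.  Border handling: ``"reflect"`` pads by mirror reflection;
    ``"valid"`` computes with reflection but masks the border band of width
    ``support_radius`` with NaN so only fully supported pixels remain.
    Interior pixels agree with :func:`directional_response` to round-off.
    """
    image = _as_gray(image)
    r = params.support_radius
    h, w = image.shape
    if h < 2 * r + 1 or w < 2 * r + 1:
        raise ValueError(
            f"image {h}x{w} smaller than kernel support {2 * r + 1}x{2 * r + 1}"
        )
    if border not in ("reflect", "valid"):
        raise ValueError(f"unknown border policy {border!r}")
    stack = np.empty((params.n_orientations, h, w))
    for p, theta in enumerate(orientation_angles(params.n_orientations)):
        kernel = build_directional_kernel(params, theta, order)
        stack[p] = ndimage.correlate(image, kernel, mode="reflect")
    if border == "valid":
        stack[:, :r, :] = np.nan
        stack[:, -r:, :] = np.nan
        stack[:, :, :r] = np.nan
        stack[:, :, -r:] = np.nan
    return stack
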