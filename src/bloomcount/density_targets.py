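"""Point annotations, Gaussian density targets, and training augmentation.

Coordinates are 0-based ``(row, col)`` continuous pixel-center positions,
half-open in ``[0, H) x [0, W)``. A density target places one normalized
isotropic 2-D Gaussian of unit mass per annotated point, truncated at
``truncation_radius * sigma``, so integrating the map recovers the count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PointAnnotationSet",
    "DensityMap",
    "KernelConfig",
    "gaussian_density_map",
    "augment",
    "split_into_tiles",
]


@dataclass
class PointAnnotationSet:
    """The annotated object centers of one image."""

    image_id: str
    points: np.ndarray  # (N, 2) float, (row, col)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"{self.image_id}: non-finite point coordinates")
        self.points = pts

    @property
    def count(self) -> int:
        return len(self.points)

    def validate_bounds(self, shape) -> None:
        h, w = shape[:2]
        for r, c in self.points:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(
                    f"{self.image_id}: point ({r}, {c}) outside "
                    f"[0, {h}) x [0, {w})")


@dataclass
class DensityMap:
    """Nonnegative per-pixel density grid; sums to ~ the object count."""

    values: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("density map values must be nonnegative")

    @property
    def shape(self):
        return self.values.shape

    def sum(self) -> float:
        return float(self.values.sum())

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def as_density_array(density) -> np.ndarray:
    """Accept a DensityMap or a bare 2-D array."""
    if isinstance(density, DensityMap):
        return density.values
    arr = np.asarray(density)
    if arr.ndim != 2:
        raise ValueError("density must be a 2-D array")
    return arr


@dataclass
class KernelConfig:
    """Isotropic Gaussian smoothing kernel for target generation."""

    sigma: float = 6.0
    truncation_radius: float = 4.0  # in multiples of sigma

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.truncation_radius < 3:
            raise ValueError("truncation_radius must be >= 3 sigma")


def gaussian_density_map(annotations: PointAnnotationSet, shape,
                         kernel: KernelConfig | None = None, *,
                         legacy_prefactor: bool = False) -> DensityMap:
    """Superpose one unit-mass truncated Gaussian per annotated point.

    Each point contributes ``1/(2*pi*sigma^2) * exp(-d^2 / (2*sigma^2))``
    inside a disc of radius ``truncation_radius * sigma`` around it.
    ``legacy_prefactor=True`` switches to a ``1/(2*pi*sigma)`` prefactor
    (a non-normalized variant kept for comparison); the default keeps unit
    mass per point so the map integrates to the count.
    """
    if kernel is None:
        kernel = KernelConfig()
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"shape must be positive, got {(h, w)}")
    annotations.validate_bounds((h, w))
    out = np.zeros((h, w), dtype=np.float64)
    sigma = float(kernel.sigma)
    rad = kernel.truncation_radius * sigma
    iR = int(math.ceil(rad))
    if legacy_prefactor:
        norm = 1.0 / (2.0 * math.pi * sigma)
    else:
        norm = 1.0 / (2.0 * math.pi * sigma * sigma)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for r, c in annotations.points:
        r0 = max(0, int(math.floor(r)) - iR)
        r1 = min(h, int(math.ceil(r)) + iR + 1)
        c0 = max(0, int(math.floor(c)) - iR)
        c1 = min(w, int(math.ceil(c)) + iR + 1)
        rr = np.arange(r0, r1, dtype=np.float64)[:, None]
        cc = np.arange(c0, c1, dtype=np.float64)[None, :]
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        g = norm * np.exp(-d2 * inv2s2)
        g[d2 > rad * rad] = 0.0
        out[r0:r1, c0:c1] += g
    return DensityMap(out)


def _rotate_points(points: np.ndarray, angle_deg: float,
                   center: tuple[float, float]) -> np.ndarray:
    """Rigid rotation of (row, col) points matching scipy.ndimage.rotate.

    In (row, col) coordinates a source point p maps to R(a) @ (p - c) + c
    with R = [[cos, -sin], [sin, cos]]; verified against a rotated
    single-pixel indicator image.
    """
    a = math.radians(angle_deg)
    cosa, sina = math.cos(a), math.sin(a)
    rot = np.array([[cosa, -sina], [sina, cosa]])
    return (points - center) @ rot.T + center


def augment(rgb_image: np.ndarray, annotations: PointAnnotationSet,
            crop_size: int, rng: np.random.Generator, *,
            rotate: bool = True, angle: float | None = None,
            crop_origin: tuple[int, int] | None = None):
    """Random rotation about the image center plus a random valid crop.

    The image is rotated by a uniform angle (bilinear resampling), point
    coordinates are transformed by the same rigid rotation, and a
    ``crop_size`` window fully inside the rotated image's valid region is
    sampled. Points falling outside the crop are dropped; survivors are
    returned in crop-relative coordinates. Density targets should be
    regenerated from the returned points, never interpolated.
    """
    h, w = rgb_image.shape[:2]
    if crop_size > h or crop_size > w:
        raise ValueError(f"crop_size {crop_size} exceeds image {h}x{w}")
    if angle is None:
        angle = float(rng.uniform(0.0, 360.0)) if rotate else 0.0
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    if angle % 360.0 == 0.0:
        img = rgb_image
        pts = annotations.points.copy()
        half_h, half_w = h / 2.0, w / 2.0
    else:
        img = ndimage.rotate(rgb_image, angle, reshape=False, order=1,
                             mode="nearest")
        pts = _rotate_points(annotations.points, angle, center)
        # largest centered axis-aligned box guaranteed inside the rotated
        # frame: shrink each half-extent by |cos|+|sin|
        a = math.radians(angle)
        s = abs(math.cos(a)) + abs(math.sin(a))
        half_h, half_w = h / (2.0 * s), w / (2.0 * s)
        if crop_size > 2 * half_h or crop_size > 2 * half_w:
            raise ValueError(
                f"crop_size {crop_size} does not fit inside the valid "
                f"region of a {angle:.1f} deg rotation of {h}x{w}")

    if crop_origin is None:
        r_lo = int(math.ceil(center[0] - half_h))
        r_hi = int(math.floor(center[0] + half_h)) - crop_size + 1
        c_lo = int(math.ceil(center[1] - half_w))
        c_hi = int(math.floor(center[1] + half_w)) - crop_size + 1
        r0 = int(rng.integers(r_lo, max(r_lo, r_hi) + 1))
        c0 = int(rng.integers(c_lo, max(c_lo, c_hi) + 1))
    else:
        r0, c0 = crop_origin
    patch = img[r0:r0 + crop_size, c0:c0 + crop_size]

    if len(pts):
        rel = pts - [r0, c0]
        keep = ((rel[:, 0] >= 0) & (rel[:, 0] < crop_size)
                & (rel[:, 1] >= 0) & (rel[:, 1] < crop_size))
        rel = rel[keep]
    else:
        rel = pts
    return patch, PointAnnotationSet(annotations.image_id, rel)


def split_into_tiles(image_or_map: np.ndarray, tile_size: int):
    """Cut an array into non-overlapping tiles covering it exactly.

    Returns a row-major list of ``(tile, (row_offset, col_offset))``. Both
    spatial dimensions must be divisible by ``tile_size``; for ragged
    inputs use ``mosaic_inference.plan_tiling``, which pads first.
    """
    arr = np.asarray(image_or_map)
    h, w = arr.shape[:2]
    if h % tile_size or w % tile_size:
        raise ValueError(
            f"dimensions {h}x{w} not divisible by tile_size {tile_size}; "
            "use mosaic_inference.plan_tiling to pad ragged inputs")
    tiles = []
    for r in range(0, h, tile_size):
        for c in range(0, w, tile_size):
            tiles.append((arr[r:r + tile_size, c:c + tile_size], (r, c)))
    return tiles
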