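"""Spatial filters for 8-bit grayscale radiographs.

Three windowed operators: the mean filter used before binarization in the
segmentation front end, and the median + bilateral pair that opens the
tooth-edge enhancement chain.  All three share the same conventions:

* images are 2-D ``uint8`` arrays, row-major, ``y`` = row, ``x`` = column;
* borders are handled by edge replication, so a filter never drags dark
  "outside" values into the frame (which would corrupt projection profiles);
* floating-point accumulation, then round-half-up back to ``uint8``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError

__all__ = [
    "KernelSpec",
    "BilateralParams",
    "mean_filter",
    "median_filter",
    "bilateral_filter",
]


def as_gray_image(img) -> np.ndarray:
    """Validate and return a 2-D uint8 grayscale image."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ParameterError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ParameterError(f"expected uint8 intensities in [0, 255], got dtype {arr.dtype}")
    return arr


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero toward +inf, as uint8."""
    return np.clip(np.floor(x + 0.5), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class KernelSpec:
    """Odd rectangular window: ``width`` columns (Kw) by ``height`` rows (Kh).

    The half extents a = (Kw-1)/2 and b = (Kh-1)/2 give the neighborhood
    [x-a, x+a] x [y-b, y+b] around each pixel.
    """

    width: int = 3
    height: int = 3

    def __post_init__(self):
        for name, v in (("width", self.width), ("height", self.height)):
            if not isinstance(v, (int, np.integer)) or v < 1 or v % 2 == 0:
                raise ParameterError(f"kernel {name} must be a positive odd integer, got {v!r}")

    @property
    def half_width(self) -> int:
        return (self.width - 1) // 2

    @property
    def half_height(self) -> int:
        return (self.height - 1) // 2


@dataclass(frozen=True)
class BilateralParams:
    """Bilateral-filter parameters.

    ``sigma_spatial`` (pixels) scales the Gaussian spatial kernel GS over
    coordinate distance; ``sigma_range`` (intensity levels) scales the
    Gaussian range kernel Fr over the neighbor-minus-center intensity
    difference.  The window is the square of radius ``window_radius``.
    """

    window_radius: int = 4
    sigma_spatial: float = 2.0
    sigma_range: float = 25.0

    def __post_init__(self):
        if not isinstance(self.window_radius, (int, np.integer)) or self.window_radius < 0:
            raise ParameterError(f"window_radius must be a non-negative integer, got {self.window_radius!r}")
        if self.sigma_spatial <= 0 or self.sigma_range <= 0:
            raise ParameterError(
                f"sigmas must be positive, got sigma_spatial={self.sigma_spatial}, sigma_range={self.sigma_range}"
            )


def mean_filter(img: np.ndarray, kernel: KernelSpec = KernelSpec()) -> np.ndarray:
    """Windowed arithmetic mean: each pixel becomes the average of its
    ``Kw x Kh`` neighborhood (edge-replicated borders), rounded half-up."""
    arr = as_gray_image(img)
    weights = np.full((kernel.height, kernel.width), 1.0 / (kernel.height * kernel.width))
    acc = ndimage.convolve(arr.astype(np.float64), weights, mode="nearest")
    return round_half_up(acc)


def median_filter(img: np.ndarray, kernel: KernelSpec = KernelSpec()) -> np.ndarray:
    """Windowed median: the exact middle order statistic of the odd-sized
    neighborhood (edge-replicated borders)."""
    arr = as_gray_image(img)
    return ndimage.median_filter(arr, size=(kernel.height, kernel.width), mode="nearest")


def bilateral_filter(img: np.ndarray, params: BilateralParams = BilateralParams()) -> np.ndarray:
    """Edge-preserving weighted mean over the window Omega.

    Each neighbor q of center p contributes with weight
    ``Fr(I(q) - I(p)) * GS(q - p)`` where both kernels are Gaussians
    ``exp(-d^2 / (2 sigma^2))``; the sum of weights W normalizes.  Neighbors
    whose intensity differs strongly from the center are discounted, so
    smoothing stops at tooth/background edges.
    """
    arr = as_gray_image(img)
    r = params.window_radius
    if r == 0:
        return arr.copy()
    center = arr.astype(np.float64)
    padded = np.pad(center, r, mode="edge")
    h, w = arr.shape
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    inv2ss = 1.0 / (2.0 * params.sigma_spatial**2)
    inv2sr = 1.0 / (2.0 * params.sigma_range**2)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            neighbor = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            gs = np.exp(-(dy * dy + dx * dx) * inv2ss)
            fr = np.exp(-((neighbor - center) ** 2) * inv2sr)
            wgt = gs * fr
            num += wgt * neighbor
            den += wgt
    return round_half_up(num / den)
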