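"""Binarization and binary mathematical morphology.

Binary images use the radiographic convention {0, 255} on ``uint8`` so they
stay drop-in compatible with the grayscale carriers.  Morphology follows the
set-theoretic definitions on the white (255) set, with everything outside
the frame treated as background (0):

* dilation   A (+) B = union of A translated by each element of B
* erosion    A (-) B = points whose whole B-neighborhood lies in A
* opening    = erosion then dilation  (removes small white specks)
* closing    = dilation then erosion  (fills small black holes)

Structuring elements carry an explicit origin so asymmetric elements behave
predictably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .filters import as_gray_image

__all__ = [
    "StructuringElement",
    "AdaptiveParams",
    "binarize_global",
    "binarize_adaptive",
    "dilate",
    "erode",
    "opening",
    "closing",
]

WHITE = 255


def as_binary_image(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ParameterError(f"expected a non-empty 2-D binary image, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, WHITE))):
        raise ParameterError(f"binary image must contain only {{0, {WHITE}}}, found values {vals[:8]}")
    return arr.astype(np.uint8)


def _cross(size: int) -> np.ndarray:
    m = np.zeros((size, size), dtype=bool)
    m[size // 2, :] = True
    m[:, size // 2] = True
    return m


@dataclass(frozen=True)
class StructuringElement:
    """Small binary mask with an origin cell (row, col) inside the mask."""

    mask: np.ndarray = field(default_factory=lambda: _cross(3))
    origin: tuple[int, int] | None = None  # None -> mask center

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ParameterError("structuring element needs a 2-D mask with at least one active cell")
        object.__setattr__(self, "mask", mask)
        origin = self.origin if self.origin is not None else (mask.shape[0] // 2, mask.shape[1] // 2)
        oy, ox = origin
        if not (0 <= oy < mask.shape[0] and 0 <= ox < mask.shape[1]):
            raise ParameterError(f"origin {origin} outside mask of shape {mask.shape}")
        object.__setattr__(self, "origin", (int(oy), int(ox)))

    @classmethod
    def cross(cls, size: int = 3) -> "StructuringElement":
        return cls(_cross(size))

    @classmethod
    def square(cls, size: int = 3) -> "StructuringElement":
        return cls(np.ones((size, size), dtype=bool))

    def offsets(self) -> np.ndarray:
        """(dy, dx) of each active cell relative to the origin."""
        oy, ox = self.origin
        cells = np.argwhere(self.mask)
        return cells - np.array([oy, ox])

    def reflected(self) -> "StructuringElement":
        """Point reflection through the origin (for the duality identity)."""
        mask = self.mask[::-1, ::-1]
        oy, ox = self.origin
        h, w = self.mask.shape
        return StructuringElement(mask, (h - 1 - oy, w - 1 - ox))


@dataclass(frozen=True)
class AdaptiveParams:
    """Local-mean adaptive threshold: white iff pixel > block mean - offset_C."""

    block_size: int = 15
    offset_C: float = 0.0

    def __post_init__(self):
        b = self.block_size
        if not isinstance(b, (int, np.integer)) or b < 3 or b % 2 == 0:
            raise ParameterError(f"block_size must be an odd integer >= 3, got {b!r}")


def binarize_global(img: np.ndarray, threshold: float = 170) -> np.ndarray:
    """Global threshold: strictly greater than ``threshold`` -> 255, else 0."""
    arr = as_gray_image(img)
    if not 0 <= threshold <= 255:
        raise ParameterError(f"threshold must lie in [0, 255], got {threshold!r}")
    return np.where(arr > threshold, WHITE, 0).astype(np.uint8)


def binarize_adaptive(img: np.ndarray, params: AdaptiveParams = AdaptiveParams()) -> np.ndarray:
    """Local threshold against the block mean, robust to uneven illumination.

    A pixel turns white iff it exceeds the mean of its ``block_size`` square
    neighborhood (edge-replicated) minus ``offset_C``.
    """
    arr = as_gray_image(img)
    local_mean = ndimage.uniform_filter(arr.astype(np.float64), size=params.block_size, mode="nearest")
    return np.where(arr > local_mean - params.offset_C, WHITE, 0).astype(np.uint8)


def _shift(mask: np.ndarray, dy: int, dx: int, fill: bool) -> np.ndarray:
    """Translate a boolean mask by (dy, dx), filling vacated cells with ``fill``."""
    out = np.full_like(mask, fill)
    h, w = mask.shape
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[yd, xd] = mask[ys, xs]
    return out


def dilate(img: np.ndarray, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """Minkowski dilation of the white set by ``se``."""
    white = as_binary_image(img) == WHITE
    out = np.zeros_like(white)
    for dy, dx in se.offsets():
        out |= _shift(white, dy, dx, fill=False)
    return np.where(out, WHITE, 0).astype(np.uint8)


def erode(img: np.ndarray, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """Minkowski erosion of the white set by ``se`` (background outside)."""
    white = as_binary_image(img) == WHITE
    out = np.ones_like(white)
    for dy, dx in se.offsets():
        out &= _shift(white, -dy, -dx, fill=False)
    return np.where(out, WHITE, 0).astype(np.uint8)


def opening(img: np.ndarray, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """Erosion then dilation: removes white specks smaller than ``se``."""
    return dilate(erode(img, se), se)


def closing(img: np.ndarray, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """Dilation then erosion: fills black holes smaller than ``se``."""
    return erode(dilate(img, se), se)
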