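"""Interdental edge-enhancement chain for single-tooth crops.

Calculus deposits present as faint bright protrusions on proximal tooth
surfaces; the chain amplifies exactly those contours:

    median filter -> bilateral filter -> adaptive binarization ->
    binary morphology -> Canny edge detection -> colored overlay

The two filters denoise while keeping edges; adaptive binarization isolates
local structure under uneven exposure; morphology cleans speckle; Canny
thins the remaining contours to one-pixel lines which are painted (default
pure green) back onto the *original* grayscale crop, leaving every non-edge
pixel bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .binmorph import (
    WHITE,
    AdaptiveParams,
    StructuringElement,
    binarize_adaptive,
    closing,
    opening,
)
from .errors import ParameterError
from .filters import BilateralParams, KernelSpec, as_gray_image, bilateral_filter, median_filter
from .segmentation import ToothCrop

__all__ = ["EnhanceConfig", "EnhancedCrop", "canny_edges", "overlay_edges", "enhance_tooth"]


@dataclass(frozen=True)
class EnhanceConfig:
    """Every operator parameter of the enhancement chain, in stage order."""

    median_kernel: KernelSpec = field(default_factory=KernelSpec)
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    # +5 offset keeps flat noisy regions from binarizing to salt-and-pepper
    adaptive: AdaptiveParams = field(default_factory=lambda: AdaptiveParams(offset_C=5.0))
    se: StructuringElement = field(default_factory=StructuringElement)
    morph_order: tuple[str, ...] = ("closing", "opening")
    canny_low: float = 50.0
    canny_high: float = 150.0
    canny_input: str = "morphology"  # or "grayscale" (the bilateral output)
    overlay_color: tuple[int, int, int] = (0, 255, 0)

    def __post_init__(self):
        if not self.canny_low < self.canny_high:
            raise ParameterError(f"canny_low ({self.canny_low}) must be < canny_high ({self.canny_high})")
        if any(op not in ("opening", "closing") for op in self.morph_order):
            raise ParameterError(f"morph_order may contain only opening/closing, got {self.morph_order}")
        if self.canny_input not in ("morphology", "grayscale"):
            raise ParameterError(f"canny_input must be 'morphology' or 'grayscale', got {self.canny_input!r}")


@dataclass
class EnhancedCrop:
    """Overlay result: RGB raster, the edge mask that was painted, provenance."""

    rgb: np.ndarray
    edge_mask: np.ndarray
    source: ToothCrop
    stages: dict[str, np.ndarray] | None = None


# Unit steps for the four quantized gradient directions (0/45/90/135 deg);
# the sign of (gy, gx) picks the forward neighbor along the actual gradient.
_DIR_STEPS = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}


def canny_edges(img: np.ndarray, low: float = 50.0, high: float = 150.0) -> np.ndarray:
    """Canny detector: Sobel gradient, non-maximum suppression along the
    quantized gradient direction, then double-threshold hysteresis.

    Thresholds apply to the 3x3 Sobel gradient magnitude of the 8-bit input
    (a straight full-contrast step edge reaches 4*255 = 1020).  No extra
    Gaussian smoothing: the chain's median + bilateral stages already denoise.
    """
    if not low < high:
        raise ParameterError(f"low ({low}) must be < high ({high})")
    arr = as_gray_image(img).astype(np.float64)
    gx = ndimage.sobel(arr, axis=1, mode="nearest")
    gy = ndimage.sobel(arr, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)

    # quantize direction into 4 bins of 45 degrees
    angle = np.mod(np.arctan2(gy, gx), np.pi)
    dbin = np.mod(np.floor(angle / (np.pi / 4) + 0.5).astype(int), 4)

    h, w = arr.shape
    padded = np.pad(mag, 1, mode="constant")
    keep = np.zeros((h, w), dtype=bool)
    sign = np.where((gx * np.cos(dbin * np.pi / 4) + gy * np.sin(dbin * np.pi / 4)) >= 0, 1, -1)
    for b, (dy, dx) in _DIR_STEPS.items():
        sel = dbin == b
        if not sel.any():
            continue
        sy, sx = sign * dy, sign * dx
        yy, xx = np.mgrid[0:h, 0:w]
        fwd = padded[yy + 1 + sy, xx + 1 + sx]
        bwd = padded[yy + 1 - sy, xx + 1 - sx]
        # strict on the forward side, lax on the backward side: plateau step
        # edges thin to the single pixel on the bright side of the step
        keep |= sel & (mag > fwd) & (mag >= bwd)

    strong = keep & (mag >= high)
    weak = keep & (mag >= low)
    labels, n = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros((h, w), dtype=np.uint8)
    surviving = np.unique(labels[strong])
    edge = weak & np.isin(labels, surviving[surviving > 0])
    return np.where(edge, WHITE, 0).astype(np.uint8)


def overlay_edges(original: np.ndarray, edges: np.ndarray,
                  color: tuple[int, int, int] = (0, 255, 0)) -> np.ndarray:
    """Replicate the grayscale to RGB and paint ``color`` where edges are white.

    Non-edge pixels stay bit-identical to the replicated original.
    """
    gray = as_gray_image(original)
    mask = np.asarray(edges)
    if mask.shape != gray.shape:
        raise ParameterError(f"edge mask shape {mask.shape} != image shape {gray.shape}")
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    rgb[mask == WHITE] = np.array(color, dtype=np.uint8)
    return rgb


def enhance_tooth(crop: ToothCrop, cfg: EnhanceConfig = EnhanceConfig(),
                  keep_stages: bool = False) -> EnhancedCrop:
    """Run the full enhancement chain on one crop, in fixed stage order."""
    gray = as_gray_image(crop.image)
    stages: dict[str, np.ndarray] = {}
    stages["median"] = median_filter(gray, cfg.median_kernel)
    stages["bilateral"] = bilateral_filter(stages["median"], cfg.bilateral)
    stages["adaptive"] = binarize_adaptive(stages["bilateral"], cfg.adaptive)
    # edge-replicate padding: the erode/dilate operators treat everything
    # outside the frame as background, which would carve a ring off shapes
    # touching the border and hand Canny a spurious frame contour
    pad = 2 * max(1, len(cfg.morph_order)) * max(cfg.se.mask.shape)
    morphed = np.pad(stages["adaptive"], pad, mode="edge")
    for op in cfg.morph_order:
        morphed = (closing if op == "closing" else opening)(morphed, cfg.se)
    stages["morphology"] = morphed[pad:-pad, pad:-pad]
    canny_src = stages["morphology"] if cfg.canny_input == "morphology" else stages["bilateral"]
    stages["canny"] = canny_edges(canny_src, cfg.canny_low, cfg.canny_high)
    rgb = overlay_edges(gray, stages["canny"], cfg.overlay_color)
    return EnhancedCrop(rgb, stages["canny"], crop, stages if keep_stages else None)
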