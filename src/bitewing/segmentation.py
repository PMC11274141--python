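"""Projection-profile single-tooth segmentation.

A bitewing is cut into single-tooth crops with no learned model at all:

1. mean-filter the grayscale image, then threshold it globally at 170
   (strictly greater -> white) to isolate the bright crowns;
2. the *horizontal* projection (per-row sum of the binary image) dips to its
   minimum inside the dark occlusal band — that row splits upper from lower
   jaw;
3. within each jaw, the *vertical* projection (per-column sum) falls below a
   valley threshold (default 400 accumulated intensity) in the dark
   interdental gaps; each sub-threshold run collapses to one cut column;
4. consecutive cuts bound a tooth; boxes are padded by a 50 px margin on
   both x sides (so proximal edges — where calculus sits — survive the
   crop) and pixels are taken from the ORIGINAL unfiltered grayscale;
5. each crop is finally halved vertically, because calculus presents on the
   left or right proximal surface and half-crops sharpen the downstream
   classification signal.

Coordinates are 0-based, half-open, x = column, y = row throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .binmorph import binarize_global
from .errors import ParameterError, SegmentationError
from .filters import KernelSpec, as_gray_image, mean_filter

__all__ = [
    "BoundingBox",
    "ProjectionProfile",
    "ToothCrop",
    "SegmentConfig",
    "projection_profile",
    "find_jaw_split",
    "find_gap_cuts",
    "cuts_to_boxes",
    "halve_crop",
    "segment_bitewing",
]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ParameterError(f"degenerate box ({self.x0},{self.y0},{self.x1},{self.y1})")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def clipped(self, width: int, height: int) -> "BoundingBox":
        return BoundingBox(max(0, self.x0), max(0, self.y0), min(width, self.x1), min(height, self.y1))


@dataclass(frozen=True)
class ProjectionProfile:
    """Accumulated pixel sums along one axis.

    ``horizontal``: values[i] = sum of row i (length = image rows).
    ``vertical``:   values[j] = sum of column j (length = image columns).
    """

    axis: Literal["horizontal", "vertical"]
    values: np.ndarray
    source_dims: tuple[int, int]  # (rows, cols)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        expected = self.source_dims[0] if self.axis == "horizontal" else self.source_dims[1]
        if len(self.values) != expected:
            raise ParameterError(
                f"{self.axis} profile length {len(self.values)} != expected {expected} "
                f"for dims {self.source_dims}"
            )


@dataclass
class ToothCrop:
    """A segmented sub-image with provenance back into the source bitewing."""

    image: np.ndarray
    source_box: BoundingBox
    jaw: Literal["upper", "lower"]
    side: Literal["left", "right", "whole"] = "whole"


@dataclass(frozen=True)
class SegmentConfig:
    """Operator parameters of the segmentation chain (paper defaults)."""

    mean_kernel: KernelSpec = field(default_factory=KernelSpec)
    binarize_threshold: int = 170
    valley_threshold: int = 400
    margin: int = 50
    central_band_fraction: float = 0.5  # jaw-split search window around mid-image
    halve: bool = True


def projection_profile(img: np.ndarray, axis: Literal["horizontal", "vertical"]) -> ProjectionProfile:
    """Sum intensities per row (horizontal) or per column (vertical)."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ParameterError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if axis not in ("horizontal", "vertical"):
        raise ParameterError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    sums = arr.sum(axis=1 if axis == "horizontal" else 0, dtype=np.int64)
    return ProjectionProfile(axis, sums, arr.shape)


def find_jaw_split(profile: ProjectionProfile, central_band_fraction: float = 0.5) -> int:
    """Row of the lowest accumulated sum, searched in the central band.

    The search window covers the middle ``central_band_fraction`` of rows so
    dark frame borders cannot masquerade as the occlusal band.  Ties resolve
    to the midmost tied index.
    """
    if profile.axis != "horizontal":
        raise ParameterError("jaw split requires a horizontal (per-row) profile")
    n = len(profile.values)
    if n == 0:
        raise ParameterError("empty profile")
    half_excluded = (1.0 - central_band_fraction) / 2.0
    lo = int(np.floor(n * half_excluded))
    hi = max(lo + 1, int(np.ceil(n * (1.0 - half_excluded))))
    window = profile.values[lo:hi]
    ties = np.flatnonzero(window == window.min())
    return lo + int(ties[len(ties) // 2])


def find_gap_cuts(profile: ProjectionProfile, valley_threshold: float = 400) -> list[int]:
    """Collapse each maximal sub-threshold run of columns to its center.

    Runs touching either image border are discarded — the dark margins of a
    radiograph are not interdental gaps.  Returns strictly increasing column
    indices; empty when nothing falls below the threshold.
    """
    if profile.axis != "vertical":
        raise ParameterError("gap cuts require a vertical (per-column) profile")
    if valley_threshold < 0:
        raise ParameterError(f"valley_threshold must be >= 0, got {valley_threshold}")
    below = profile.values < valley_threshold
    cuts: list[int] = []
    n = len(below)
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if i > 0 and j < n - 1:  # interior run only
                cuts.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return cuts


def cuts_to_boxes(cuts: list[int], jaw_rows: tuple[int, int], margin: int,
                  image_width: int) -> list[BoundingBox]:
    """Turn n interdental cuts into n+1 margin-padded tooth boxes.

    Consecutive boundaries (image left edge, cuts..., image right edge)
    bound each tooth; ``margin`` px are subtracted from the left boundary
    and added to the right one, then clipped to the image.
    """
    if any(b >= a for a, b in zip(cuts[1:], cuts)):
        raise ParameterError(f"cuts must be strictly increasing, got {cuts}")
    y0, y1 = jaw_rows
    bounds = [0, *cuts, image_width]
    return [
        BoundingBox(max(0, bounds[i] - margin), y0, min(image_width, bounds[i + 1] + margin), y1)
        for i in range(len(bounds) - 1)
    ]


def halve_crop(crop: ToothCrop) -> tuple[ToothCrop, ToothCrop]:
    """Split a crop into left/right halves at floor(width/2), losslessly."""
    w = crop.image.shape[1]
    if w < 2:
        raise ParameterError(f"cannot halve a crop of width {w}")
    mid = w // 2
    b = crop.source_box
    left = ToothCrop(crop.image[:, :mid], BoundingBox(b.x0, b.y0, b.x0 + mid, b.y1), crop.jaw, "left")
    right = ToothCrop(crop.image[:, mid:], BoundingBox(b.x0 + mid, b.y0, b.x1, b.y1), crop.jaw, "right")
    return left, right


def segment_bitewing(img: np.ndarray, config: SegmentConfig = SegmentConfig()) -> list[ToothCrop]:
    """Full projection-profile chain: filter, binarize, split jaws, cut gaps,
    box, crop from the original grayscale, and (by default) halve.

    Raises :class:`SegmentationError` naming the failing stage when the
    image defeats a step (e.g. a blank image yields no interdental cuts).
    """
    original = as_gray_image(img)
    smoothed = mean_filter(original, config.mean_kernel)
    binary = binarize_global(smoothed, config.binarize_threshold)

    split = find_jaw_split(projection_profile(binary, "horizontal"), config.central_band_fraction)
    rows = original.shape[0]
    if not 0 < split < rows - 1:
        raise SegmentationError("jaw_split", f"split row {split} is not interior to the image")

    crops: list[ToothCrop] = []
    for jaw, (y0, y1) in (("upper", (0, split)), ("lower", (split, rows))):
        vp = projection_profile(binary[y0:y1, :], "vertical")
        cuts = find_gap_cuts(vp, config.valley_threshold)
        if not cuts:
            raise SegmentationError(
                "gap_cuts", f"no interdental valley below {config.valley_threshold} in the {jaw} jaw"
            )
        for box in cuts_to_boxes(cuts, (y0, y1), config.margin, original.shape[1]):
            whole = ToothCrop(original[box.y0:box.y1, box.x0:box.x1], box, jaw, "whole")
            if config.halve:
                crops.extend(halve_crop(whole))
            else:
                crops.append(whole)
    return crops
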