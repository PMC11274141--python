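"""Synthetic bitewing phantom generator with exhaustive ground truth.

Clinical bitewing databases are IRB-restricted, so the toolkit ships a
deterministic generator of bitewing-*like* rasters: two horizontal rows of
bright tooth-shaped blobs (the upper and lower crowns) on a dark background,
separated by a dark occlusal band, with dark interdental gaps between
neighbors, optional bright proximal crescents emulating calculus deposits,
and additive Gaussian noise.  Every random choice flows from one seeded
generator, so a spec maps to exactly one raster, byte for byte.

The shapes are superellipses (rounded rectangles), chosen because all the
downstream algorithms care about is the valley structure they induce in
projection profiles — not anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .segmentation import BoundingBox

__all__ = ["PhantomSpec", "PhantomTruth", "generate_bitewing", "generate_tooth_crop"]

# Calculus deposits image brighter than enamel; fixed offsets keep the
# contrast hierarchy background < tooth < crescent at any tooth intensity.
CALCULUS_EXTRA = 45
CRESCENT_WIDTH_FRACTION = 0.30   # of tooth width
CRESCENT_HEIGHT_FRACTION = 0.45  # of tooth height


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and photometry of one synthetic bitewing."""

    image_width: int = 640
    image_height: int = 480
    teeth_per_jaw: int = 8
    tooth_width_range: tuple[int, int] = (42, 58)
    tooth_height_range: tuple[int, int] = (120, 160)
    gap_width_range: tuple[int, int] = (8, 16)
    jaw_band_height: int = 40
    tooth_intensity: int = 200
    background_intensity: int = 60
    noise_sigma: float = 6.0
    calculus_probability: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.teeth_per_jaw < 1:
            raise ParameterError(f"teeth_per_jaw must be >= 1, got {self.teeth_per_jaw}")
        for name in ("tooth_width_range", "tooth_height_range", "gap_width_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ParameterError(f"{name} must satisfy 0 < min <= max, got ({lo}, {hi})")
        if not self.tooth_intensity > self.background_intensity:
            raise ParameterError(
                f"tooth_intensity ({self.tooth_intensity}) must exceed "
                f"background_intensity ({self.background_intensity})"
            )
        if not (0 <= self.background_intensity and self.tooth_intensity <= 255):
            raise ParameterError("intensities must lie in [0, 255]")
        if not 0.0 <= self.calculus_probability <= 1.0:
            raise ParameterError(f"calculus_probability must lie in [0, 1], got {self.calculus_probability}")
        if self.noise_sigma < 0:
            raise ParameterError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


@dataclass
class PhantomTruth:
    """Generator-known ground truth for one phantom."""

    jaw_split_row: int
    gap_centers_upper: list[int]
    gap_centers_lower: list[int]
    tooth_boxes: list[BoundingBox]      # upper teeth left->right, then lower
    jaw_of_box: list[str]               # "upper" | "lower", parallel to tooth_boxes
    calculus_flags: list[bool]          # parallel to tooth_boxes


def _superellipse_mask(height: int, width: int, cy: float, cx: float,
                       ry: float, rx: float, exponent: float = 4.0) -> np.ndarray:
    """Rounded-rectangle mask |x/rx|^n + |y/ry|^n <= 1 on an image grid."""
    yy, xx = np.mgrid[0:height, 0:width]
    return (np.abs((xx - cx) / rx) ** exponent + np.abs((yy - cy) / ry) ** exponent) <= 1.0


def _layout_row(rng: np.random.Generator, spec: PhantomSpec) -> tuple[list[tuple[int, int]], list[int]]:
    """Draw tooth widths and gaps for one jaw; return ([(x0, x1)...], gap centers)."""
    n = spec.teeth_per_jaw
    widths = rng.integers(spec.tooth_width_range[0], spec.tooth_width_range[1] + 1, size=n)
    gaps = rng.integers(spec.gap_width_range[0], spec.gap_width_range[1] + 1, size=max(n - 1, 0))
    total = int(widths.sum() + gaps.sum())
    if total > spec.image_width - 2:
        raise GeometryError(
            f"{n} teeth ({int(widths.sum())} px) plus gaps ({int(gaps.sum())} px) "
            f"exceed image width {spec.image_width}"
        )
    x = (spec.image_width - total) // 2
    spans: list[tuple[int, int]] = []
    centers: list[int] = []
    for i in range(n):
        spans.append((x, x + int(widths[i])))
        x += int(widths[i])
        if i < n - 1:
            centers.append(x + int(gaps[i]) // 2)
            x += int(gaps[i])
    return spans, centers


def _draw_tooth(canvas: np.ndarray, box: BoundingBox, intensity: int,
                calculus_side: str | None, calculus_intensity: int) -> None:
    """Paint one superellipse tooth; optionally a proximal crescent outside it."""
    h, w = canvas.shape
    cy, cx = (box.y0 + box.y1 - 1) / 2.0, (box.x0 + box.x1 - 1) / 2.0
    ry, rx = (box.y1 - box.y0) / 2.0, (box.x1 - box.x0) / 2.0
    body = _superellipse_mask(h, w, cy, cx, ry, rx)
    canvas[body] = intensity
    if calculus_side is not None:
        crx = max(2.0, (box.x1 - box.x0) * CRESCENT_WIDTH_FRACTION / 2.0)
        cry = max(3.0, (box.y1 - box.y0) * CRESCENT_HEIGHT_FRACTION / 2.0)
        edge_x = box.x0 if calculus_side == "left" else box.x1 - 1
        deposit = _superellipse_mask(h, w, cy, edge_x, cry, crx, exponent=2.0)
        canvas[deposit & ~body] = calculus_intensity


def generate_bitewing(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render one phantom bitewing and its ground truth.

    Teeth sit in two rows flanking a dark occlusal band of height
    ``jaw_band_height`` centered on the recorded ``jaw_split_row``; the band
    is dark simply because no tooth is drawn there.  Identical specs produce
    bit-identical rasters.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width

    band_top = (H - spec.jaw_band_height) // 2
    band_bottom = band_top + spec.jaw_band_height
    jaw_split_row = (band_top + band_bottom) // 2

    canvas = np.full((H, W), float(spec.background_intensity))
    calc_val = min(255, spec.tooth_intensity + CALCULUS_EXTRA)

    boxes: list[BoundingBox] = []
    jaws: list[str] = []
    flags: list[bool] = []
    gap_centers: dict[str, list[int]] = {}

    for jaw in ("upper", "lower"):
        spans, centers = _layout_row(rng, spec)
        gap_centers[jaw] = centers
        heights = rng.integers(spec.tooth_height_range[0], spec.tooth_height_range[1] + 1,
                               size=spec.teeth_per_jaw)
        for (x0, x1), th in zip(spans, heights):
            th = int(min(th, band_top - 2))  # keep crowns inside the frame
            if jaw == "upper":
                y0, y1 = band_top - th, band_top
            else:
                y0, y1 = band_bottom, band_bottom + th
            box = BoundingBox(x0, y0, x1, y1)
            has_calc = bool(rng.random() < spec.calculus_probability)
            side = rng.choice(("left", "right")) if has_calc else None
            _draw_tooth(canvas, box, spec.tooth_intensity, side, calc_val)
            boxes.append(box)
            jaws.append(jaw)
            flags.append(has_calc)

    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, size=canvas.shape)
    image = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)

    truth = PhantomTruth(
        jaw_split_row=jaw_split_row,
        gap_centers_upper=gap_centers["upper"],
        gap_centers_lower=gap_centers["lower"],
        tooth_boxes=boxes,
        jaw_of_box=jaws,
        calculus_flags=flags,
    )
    return image, truth


def generate_tooth_crop(width: int, height: int, with_calculus: bool,
                        seed: int, noise_sigma: float = 3.0,
                        ) -> tuple[np.ndarray, bool]:
    """Render a single centered tooth on its own canvas (a segmented crop).

    The tooth fills ~70% of the canvas; when ``with_calculus`` a bright
    crescent (intensity ``tooth + CALCULUS_EXTRA``) sits on one proximal
    side, chosen uniformly.  Returns the raster and the calculus flag.
    """
    if width < 16 or height < 16:
        raise ParameterError(f"crop must be at least 16x16, got {width}x{height}")
    rng = np.random.default_rng(seed)
    background, tooth = 60, 200
    canvas = np.full((height, width), float(background))
    tw, th = int(width * 0.55), int(height * 0.78)
    box = BoundingBox((width - tw) // 2, (height - th) // 2,
                      (width - tw) // 2 + tw, (height - th) // 2 + th)
    side = str(rng.choice(("left", "right"))) if with_calculus else None
    _draw_tooth(canvas, box, tooth, side, min(255, tooth + CALCULUS_EXTRA))
    if noise_sigma > 0:
        canvas += rng.normal(0.0, noise_sigma, size=canvas.shape)
    image = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    return image, with_calculus


def crescent_region(width: int, height: int, seed: int) -> np.ndarray:
    """Boolean mask of where the calculus crescent would be drawn for the
    given ``generate_tooth_crop`` call (truth helper for tests/evaluation)."""
    rng = np.random.default_rng(seed)
    background, tooth = 60, 200
    canvas = np.full((height, width), float(background))
    tw, th = int(width * 0.55), int(height * 0.78)
    box = BoundingBox((width - tw) // 2, (height - th) // 2,
                      (width - tw) // 2 + tw, (height - th) // 2 + th)
    side = str(rng.choice(("left", "right")))
    plain = canvas.copy()
    _draw_tooth(plain, box, tooth, None, 0)
    _draw_tooth(canvas, box, tooth, side, min(255, tooth + CALCULUS_EXTRA))
    return canvas != plain
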