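"""Image and annotation I/O.

Rasters travel as 8-bit grayscale.  Color inputs collapse by the Rec. 601
luma weights (0.299 R + 0.587 G + 0.114 B, rounded half-up); 16-bit inputs
rescale by 255/65535.  Bounding-box annotations use the plain-text YOLO
format: one ``class cx cy w h`` line per box, center/size normalized to the
image dimensions.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ParameterError
from .filters import round_half_up
from .segmentation import BoundingBox

__all__ = [
    "load_gray_image",
    "save_image",
    "read_yolo_annotations",
    "write_yolo_annotations",
]

LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def load_gray_image(path: str | os.PathLike) -> np.ndarray:
    """Read PNG/TIFF/BMP as 2-D uint8 grayscale."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = np.tensordot(arr.astype(np.float64), LUMA_WEIGHTS, axes=([2], [0]))
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image shape {arr.shape} in {path}")
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    return round_half_up(arr.astype(np.float64))


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2-D grayscale or HxWx3 RGB uint8 raster (PNG round-trips
    bit-exactly)."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8 or arr.ndim not in (2, 3):
        raise ParameterError(f"expected a uint8 2-D or HxWx3 raster, got {arr.dtype} {arr.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        iio.imwrite(path, arr)
    except Exception as exc:
        raise FormatError(f"cannot write image {path}: {exc}") from exc


def _parse_yolo_line(parts: list[str], width: int, height: int,
                     path: Path, lineno: int, line: str,
                     with_confidence: bool) -> tuple[int, BoundingBox, float]:
    try:
        n_expected = (5, 6) if with_confidence else (5,)
        if len(parts) not in n_expected:
            raise ValueError(f"expected {' or '.join(map(str, n_expected))} fields, got {len(parts)}")
        cls = int(parts[0])
        cx, cy, w, h = map(float, parts[1:5])
        conf = float(parts[5]) if len(parts) == 6 else 1.0
        if cls < 0:
            raise ValueError(f"negative class id {cls}")
        if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
            raise ValueError(f"center ({cx}, {cy}) outside the unit square")
        if not (0.0 < w <= 1.0 and 0.0 < h <= 1.0):
            raise ValueError(f"size ({w}, {h}) outside (0, 1]")
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"confidence {conf} outside [0, 1]")
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: malformed YOLO line {line!r}: {exc}") from exc
    x0 = (cx - w / 2.0) * width
    y0 = (cy - h / 2.0) * height
    box = BoundingBox(
        int(round(x0)), int(round(y0)),
        int(round(x0 + w * width)), int(round(y0 + h * height)),
    ).clipped(width, height)
    return cls, box, conf


def _read_yolo_file(path: str | os.PathLike, image_dims: tuple[int, int],
                    with_confidence: bool) -> list[tuple[int, BoundingBox, float]]:
    width, height = image_dims
    if width <= 0 or height <= 0:
        raise ParameterError(f"image dims must be positive, got {image_dims}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    out = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line:
            out.append(_parse_yolo_line(line.split(), width, height, path, lineno, line,
                                        with_confidence))
    return out


def read_yolo_annotations(path: str | os.PathLike,
                          image_dims: tuple[int, int]) -> list[tuple[int, BoundingBox]]:
    """Parse YOLO txt lines (``class cx cy w h``, normalized) into
    (class_id, pixel BoundingBox) pairs.

    ``image_dims`` is (width, height).  Malformed lines raise with their
    1-based line number.
    """
    return [(cls, box) for cls, box, _ in _read_yolo_file(path, image_dims, False)]


def read_yolo_predictions(path: str | os.PathLike,
                          image_dims: tuple[int, int],
                          ) -> list[tuple[int, BoundingBox, float]]:
    """Like :func:`read_yolo_annotations` but with an optional trailing
    confidence field per line (missing -> 1.0)."""
    return _read_yolo_file(path, image_dims, True)


def write_yolo_annotations(items: list[tuple[int, BoundingBox]],
                           image_dims: tuple[int, int],
                           path: str | os.PathLike) -> None:
    """Write (class_id, pixel box) pairs as normalized YOLO txt lines."""
    width, height = image_dims
    if width <= 0 or height <= 0:
        raise ParameterError(f"image dims must be positive, got {image_dims}")
    lines = []
    for cls, box in items:
        cx = (box.x0 + box.x1) / 2.0 / width
        cy = (box.y0 + box.y1) / 2.0 / height
        w = box.width / width
        h = box.height / height
        lines.append(f"{cls} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
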