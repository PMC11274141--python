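"""Brute-force reference implementations used as independent oracles.

Everything here is written as directly as possible from the mathematical
definitions — explicit loops, explicit sets — and stays independent of the
package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np


def replicate_pad(img: np.ndarray, ry: int, rx: int) -> np.ndarray:
    return np.pad(img, ((ry, ry), (rx, rx)), mode="edge")


def mean_filter_oracle(img: np.ndarray, kw: int, kh: int) -> np.ndarray:
    """Double-loop window average with edge replication, round half-up."""
    a, b = (kw - 1) // 2, (kh - 1) // 2
    padded = replicate_pad(img.astype(np.float64), b, a)
    out = np.zeros_like(img, dtype=np.float64)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dy in range(-b, b + 1):
                for dx in range(-a, a + 1):
                    acc += padded[y + b + dy, x + a + dx]
            out[y, x] = acc / (kw * kh)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def median_filter_oracle(img: np.ndarray, kw: int, kh: int) -> np.ndarray:
    """Sort-and-pick-middle per window with edge replication."""
    a, b = (kw - 1) // 2, (kh - 1) // 2
    padded = replicate_pad(img, b, a)
    out = np.zeros_like(img)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            window = sorted(
                padded[y + b + dy, x + a + dx]
                for dy in range(-b, b + 1) for dx in range(-a, a + 1)
            )
            out[y, x] = window[len(window) // 2]
    return out


def bilateral_filter_oracle(img: np.ndarray, radius: int,
                            sigma_spatial: float, sigma_range: float) -> np.ndarray:
    """Per-pixel direct sum of the bilateral definition."""
    padded = replicate_pad(img.astype(np.float64), radius, radius)
    h, w = img.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            center = float(img[y, x])
            num = den = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    v = padded[y + radius + dy, x + radius + dx]
                    gs = np.exp(-(dy * dy + dx * dx) / (2 * sigma_spatial**2))
                    fr = np.exp(-((v - center) ** 2) / (2 * sigma_range**2))
                    num += gs * fr * v
                    den += gs * fr
            out[y, x] = num / den
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def spatial_gaussian_mean_oracle(img: np.ndarray, radius: int, sigma_spatial: float) -> np.ndarray:
    """Pure spatial-Gaussian-weighted mean (the flat-range bilateral limit)."""
    padded = replicate_pad(img.astype(np.float64), radius, radius)
    h, w = img.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            num = den = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    gs = np.exp(-(dy * dy + dx * dx) / (2 * sigma_spatial**2))
                    num += gs * padded[y + radius + dy, x + radius + dx]
                    den += gs
            out[y, x] = num / den
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def dilate_oracle(white: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Set-theoretic Minkowski dilation: union of translates."""
    h, w = white.shape
    out = np.zeros_like(white, dtype=bool)
    for y, x in np.argwhere(white):
        for dy, dx in offsets:
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                out[yy, xx] = True
    return out


def erode_oracle(white: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Point is kept iff every structuring-element cell lands on white
    (outside the frame counts as background)."""
    h, w = white.shape
    out = np.zeros_like(white, dtype=bool)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy, dx in offsets:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w and white[yy, xx]):
                    ok = False
                    break
            out[y, x] = ok
    return out


def local_mean_threshold_oracle(img: np.ndarray, block: int, offset_c: float) -> np.ndarray:
    """Brute-force adaptive threshold: white iff pixel > block mean - C."""
    r = block // 2
    padded = replicate_pad(img.astype(np.float64), r, r)
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            m = padded[y:y + block, x:x + block].mean()
            out[y, x] = 255 if img[y, x] > m - offset_c else 0
    return out


def average_precision_oracle(scored: list[tuple[float, bool]], n_truth: int) -> float:
    """AP by enumerating every confidence cut-point.

    ``scored`` holds (confidence, is_true_positive) per detection.  At each
    cut-point the (recall, precision) pair is computed from scratch; the
    area uses the all-point precision envelope.
    """
    ordered = sorted(scored, key=lambda t: -t[0])
    points = []
    for k in range(1, len(ordered) + 1):
        kept = ordered[:k]
        tp = sum(1 for _, good in kept if good)
        points.append((tp / n_truth, tp / k))
    area = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r > prev_r:
            p_env = max(p for rr, p in points if rr >= r)
            area += (r - prev_r) * p_env
            prev_r = r
    return area
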