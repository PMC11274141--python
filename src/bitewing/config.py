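"""Structured configuration shared by the library and the CLI.

One YAML file with sections mirroring the module names; anything omitted
falls back to the documented default, and CLI flags override the file.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Any

import yaml

from .binmorph import AdaptiveParams, StructuringElement
from .enhancement import EnhanceConfig
from .errors import ParameterError
from .filters import BilateralParams, KernelSpec
from .phantom import PhantomSpec
from .segmentation import SegmentConfig

__all__ = ["default_config", "load_config", "build_phantom_spec",
           "build_segment_config", "build_enhance_config"]


def default_config() -> dict[str, Any]:
    """The full default configuration tree, serializable as YAML."""
    return {
        "phantom": {
            "image_width": 640, "image_height": 480, "teeth_per_jaw": 8,
            "tooth_width_range": [42, 58], "tooth_height_range": [120, 160],
            "gap_width_range": [8, 16], "jaw_band_height": 40,
            "tooth_intensity": 200, "background_intensity": 60,
            "noise_sigma": 6.0, "calculus_probability": 0.3, "seed": 0,
        },
        "filters": {
            "mean_kernel": [3, 3],     # [width, height]
            "median_kernel": [3, 3],
            "bilateral": {"window_radius": 4, "sigma_spatial": 2.0, "sigma_range": 25.0},
        },
        "adaptive": {"block_size": 15, "offset_C": 5.0},
        "morphology": {"se_shape": "cross", "se_size": 3, "order": ["closing", "opening"]},
        "segmentation": {
            "binarize_threshold": 170, "valley_threshold": 400,
            "margin": 50, "central_band_fraction": 0.5, "halve": True,
        },
        "enhancement": {
            "canny_low": 50.0, "canny_high": 150.0,
            "canny_input": "morphology", "overlay_color": [0, 255, 0],
        },
        "dataset": {"holdout_fraction": 0.2, "train_fraction_of_rest": 0.7, "target": None},
        "metrics": {"iou_threshold": 0.5, "ap_mode": "all_point"},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ParameterError(f"unknown config key {key!r} (known: {sorted(base)})")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | os.PathLike | None = None) -> dict[str, Any]:
    """Defaults overlaid with a YAML file (unknown keys rejected loudly)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(Path(path)) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ParameterError(f"config root in {path} must be a mapping")
    return _merge(cfg, user)


def build_phantom_spec(cfg: dict[str, Any], seed: int | None = None) -> PhantomSpec:
    p = dict(cfg["phantom"])
    if seed is not None:
        p["seed"] = seed
    for key in ("tooth_width_range", "tooth_height_range", "gap_width_range"):
        p[key] = tuple(p[key])
    return PhantomSpec(**p)


def _build_se(cfg: dict[str, Any]) -> StructuringElement:
    m = cfg["morphology"]
    if m["se_shape"] == "cross":
        return StructuringElement.cross(m["se_size"])
    if m["se_shape"] == "square":
        return StructuringElement.square(m["se_size"])
    raise ParameterError(f"se_shape must be 'cross' or 'square', got {m['se_shape']!r}")


def build_segment_config(cfg: dict[str, Any]) -> SegmentConfig:
    s = cfg["segmentation"]
    kw, kh = cfg["filters"]["mean_kernel"]
    return SegmentConfig(
        mean_kernel=KernelSpec(kw, kh),
        binarize_threshold=s["binarize_threshold"],
        valley_threshold=s["valley_threshold"],
        margin=s["margin"],
        central_band_fraction=s["central_band_fraction"],
        halve=s["halve"],
    )


def build_enhance_config(cfg: dict[str, Any]) -> EnhanceConfig:
    f, e, a, m = cfg["filters"], cfg["enhancement"], cfg["adaptive"], cfg["morphology"]
    kw, kh = f["median_kernel"]
    return EnhanceConfig(
        median_kernel=KernelSpec(kw, kh),
        bilateral=BilateralParams(**f["bilateral"]),
        adaptive=AdaptiveParams(block_size=a["block_size"], offset_C=a["offset_C"]),
        se=_build_se(cfg),
        morph_order=tuple(m["order"]),
        canny_low=e["canny_low"],
        canny_high=e["canny_high"],
        canny_input=e["canny_input"],
        overlay_color=tuple(e["overlay_color"]),
    )


def dump_config(cfg: dict[str, Any]) -> str:
    return yaml.safe_dump(cfg, sort_keys=False)
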