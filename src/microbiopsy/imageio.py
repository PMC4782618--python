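"""Shared image I/O: 8-bit PNG/TIFF rasters and binary / label masks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])  # ITU-R BT.601


def load_rgb(path: str | Path) -> np.ndarray:
    """Load an image as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def load_gray(path: str | Path) -> np.ndarray:
    """Load an image as an (H, W) uint8 luminance array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask stored as 0/255 single-channel PNG -> bool array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def save_rgb(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 0/255 8-bit PNG."""
    Image.fromarray((np.asarray(mask).astype(np.uint8) * 255), mode="L").save(path)


def save_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label raster as 8-bit PNG, labels spread over 0..255."""
    labels = np.asarray(labels)
    top = max(int(labels.max()), 1)
    scaled = np.round(labels * (255.0 / top)).astype(np.uint8)
    Image.fromarray(scaled, mode="L").save(path)


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luminance of an (H, W, 3) uint8 image, rounded back to uint8."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {rgb.shape}")
    return np.round(rgb.astype(np.float64) @ LUMA_WEIGHTS).clip(0, 255).astype(np.uint8)
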