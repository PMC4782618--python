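"""Contrast-limited adaptive histogram equalization (CLAHE).

CLAHE equalizes contrast locally: the image is divided into a grid of
tiles, each tile's histogram is clipped at a limit proportional to the
tile's pixel count (excess mass redistributed uniformly over all bins in
a single pass), a per-tile equalization mapping is built from the clipped
CDF, and per-pixel output is bilinearly interpolated between the mappings
of the four surrounding tile centers.  With a single tile and an infinite
clip limit the procedure reduces exactly to global histogram equalization.

For RGB images the luminance channel of a full-range YCbCr representation
is equalized and the chroma channels are left untouched, which preserves
hue — important because downstream HSV color features would otherwise be
corrupted.  A per-channel variant is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE configuration.

    clip_limit is a fraction of the tile pixel count: a bin is clipped at
    ``clip_limit * tile_pixels`` counts.  ``math.inf`` disables clipping.
    """

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 0.01
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.tile_grid[0] < 1 or self.tile_grid[1] < 1:
            raise ValueError("tile_grid rows and cols must be >= 1")
        if not self.clip_limit > 0:
            raise ValueError("clip_limit must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def _tile_mapping(tile: np.ndarray, params: ClaheParams) -> np.ndarray:
    """Equalization lookup table (256 entries) for one tile of uint8 values."""
    n_bins = params.n_bins
    bins = (tile.astype(np.int64) * n_bins) >> 8
    hist = np.bincount(bins.ravel(), minlength=n_bins).astype(np.float64)
    npix = float(tile.size)

    if math.isfinite(params.clip_limit):
        clip = params.clip_limit * npix
        excess = np.maximum(hist - clip, 0.0).sum()
        hist = np.minimum(hist, clip) + excess / n_bins

    cdf = np.cumsum(hist)
    nonzero = np.nonzero(hist)[0]
    cdf_min = cdf[nonzero[0]] if nonzero.size else npix
    denom = cdf[-1] - cdf_min
    lut_bins = np.arange(256, dtype=np.int64) * n_bins >> 8
    if denom <= 0:
        # Degenerate (all mass in one bin): identity mapping.
        return np.arange(256, dtype=np.float64)
    return (cdf[lut_bins] - cdf_min) / denom * 255.0


def clahe(img: np.ndarray, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """Apply CLAHE to a single-channel uint8 image.

    Raises ValueError if the image is smaller than the tile grid in either
    dimension.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("clahe expects a single-channel (H, W) image")
    if img.dtype != np.uint8:
        raise ValueError("clahe expects uint8 input")
    h, w = img.shape
    tr, tc = params.tile_grid
    if h < tr or w < tc:
        raise ValueError(f"image {h}x{w} smaller than tile grid {tr}x{tc}")

    row_edges = np.linspace(0, h, tr + 1).astype(int)
    col_edges = np.linspace(0, w, tc + 1).astype(int)
    luts = np.empty((tr, tc, 256), dtype=np.float64)
    for i in range(tr):
        for j in range(tc):
            tile = img[row_edges[i]:row_edges[i + 1],
                       col_edges[j]:col_edges[j + 1]]
            luts[i, j] = _tile_mapping(tile, params)

    centers_r = (row_edges[:-1] + row_edges[1:]) / 2.0 - 0.5
    centers_c = (col_edges[:-1] + col_edges[1:]) / 2.0 - 0.5

    def _interp_coords(coords: np.ndarray, centers: np.ndarray):
        """Clamped linear interpolation indices/weights along one axis."""
        i1 = np.clip(np.searchsorted(centers, coords) - 1, 0, len(centers) - 1)
        i2 = np.minimum(i1 + 1, len(centers) - 1)
        span = centers[i2] - centers[i1]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(span > 0, (coords - centers[i1]) / np.where(span > 0, span, 1.0), 0.0)
        return i1, i2, np.clip(frac, 0.0, 1.0)

    r1, r2, wr = _interp_coords(np.arange(h, dtype=np.float64), centers_r)
    c1, c2, wc = _interp_coords(np.arange(w, dtype=np.float64), centers_c)

    v = img.astype(np.int64)
    wr_col = wr[:, None]
    wc_row = wc[None, :]
    out = ((1 - wr_col) * (1 - wc_row) * luts[r1[:, None], c1[None, :], v]
           + (1 - wr_col) * wc_row * luts[r1[:, None], c2[None, :], v]
           + wr_col * (1 - wc_row) * luts[r2[:, None], c1[None, :], v]
           + wr_col * wc_row * luts[r2[:, None], c2[None, :], v])
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# Full-range (JPEG) YCbCr conversion constants.
def _rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    rgb = rgb.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 + (b - y) * 0.564
    cr = 128.0 + (r - y) * 0.713
    return np.stack([y, cb, cr], axis=-1)


def _ycbcr_to_rgb(ycc: np.ndarray) -> np.ndarray:
    y, cb, cr = ycc[..., 0], ycc[..., 1], ycc[..., 2]
    r = y + 1.403 * (cr - 128.0)
    b = y + 1.773 * (cb - 128.0)
    g = (y - 0.299 * r - 0.114 * b) / 0.587
    return np.stack([r, g, b], axis=-1)


def enhance_rgb(img: np.ndarray, params: ClaheParams = ClaheParams(),
                per_channel: bool = False) -> np.ndarray:
    """CLAHE for RGB images.

    Default: equalize the YCbCr luminance only (chroma untouched).  With
    ``per_channel=True`` each RGB channel is equalized independently
    (may distort hue; provided for comparison).

    Note CLAHE is not idempotent: a second application may change the
    image again.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("enhance_rgb expects an (H, W, 3) image")
    if img.dtype != np.uint8:
        raise ValueError("enhance_rgb expects uint8 input")
    if per_channel:
        return np.stack([clahe(img[..., c], params) for c in range(3)], axis=-1)
    ycc = _rgb_to_ycbcr(img)
    y8 = np.clip(np.round(ycc[..., 0]), 0, 255).astype(np.uint8)
    ycc[..., 0] = clahe(y8, params)
    rgb = _ycbcr_to_rgb(ycc)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)
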