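"""Tamura perceptual texture features: coarseness, contrast, directionality.

* Coarseness — for each pixel, average intensities over windows of size
  2^k (k = 1..5) are compared between opposite neighborhoods at distance
  2^(k-1) horizontally and vertically; the scale k* maximizing the
  response is selected per pixel and coarseness is the mean of 2^k*.
  Large values mean large dominant pattern scale.
* Contrast — sigma / kurtosis^(1/4), where sigma is the intensity
  standard deviation and kurtosis = mu4 / sigma^4 (0 for a constant
  image).
* Directionality — concentration of the gradient-orientation histogram:
  16 unsigned orientation bins over pixels whose gradient magnitude
  exceeds the 10th percentile; the score is 1 minus the normalized mean
  squared (wrapped) bin distance from the histogram peak, so an image
  with one dominant edge orientation scores near 1 and isotropic noise
  near 0.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

N_TAMURA = 3
TAMURA_NAMES = ("coarseness", "contrast", "directionality")
_MAX_K = 5
_N_DIR_BINS = 16


def coarseness(gray: np.ndarray) -> float:
    g = np.asarray(gray, dtype=np.float64)
    if min(g.shape) < 2 ** _MAX_K:
        raise ValueError(f"image must be at least {2 ** _MAX_K} px per side")
    h, w = g.shape
    stack = np.zeros((_MAX_K, h, w))
    for k in range(1, _MAX_K + 1):
        size = 2 ** k
        half = 2 ** (k - 1)
        avg = uniform_filter(g, size=size, mode="reflect")
        eh = np.zeros((h, w))
        ev = np.zeros((h, w))
        eh[:, half:w - half] = np.abs(avg[:, 2 * half:] - avg[:, :w - 2 * half])
        ev[half:h - half, :] = np.abs(avg[2 * half:, :] - avg[:h - 2 * half, :])
        stack[k - 1] = np.maximum(eh, ev)
    # Responses far below the image's strongest scale response are filter
    # alignment / boundary residue, not texture; ignoring them keeps the
    # per-pixel best scale from drifting to spuriously large windows.
    stack[stack < 0.1 * stack.max()] = 0.0
    # argmax picks the first (smallest) scale on ties; all-zero pixels get
    # the finest scale.
    best_k = np.argmax(stack, axis=0)
    sizes = 2.0 ** (best_k + 1)
    sizes[stack.max(axis=0) == 0] = 2.0
    return float(sizes.mean())


def tamura_contrast(gray: np.ndarray) -> float:
    g = np.asarray(gray, dtype=np.float64)
    sigma = g.std()
    if sigma == 0:
        return 0.0
    kurt = ((g - g.mean()) ** 4).mean() / sigma ** 4
    return float(sigma / kurt ** 0.25)


def directionality(gray: np.ndarray) -> float:
    g = np.asarray(gray, dtype=np.float64)
    gy, gx = np.gradient(g)
    mag = np.hypot(gx, gy)
    thresh = np.percentile(mag, 10.0)
    sel = mag > max(thresh, 1e-12)
    if not sel.any():
        return 0.0
    theta = np.mod(np.arctan2(gy[sel], gx[sel]), np.pi)   # unsigned
    bins = np.minimum((theta / np.pi * _N_DIR_BINS).astype(int), _N_DIR_BINS - 1)
    hist = np.bincount(bins, minlength=_N_DIR_BINS).astype(np.float64)
    p = hist / hist.sum()
    peak = int(np.argmax(hist))
    d = np.arange(_N_DIR_BINS) - peak
    d = np.minimum(np.abs(d), _N_DIR_BINS - np.abs(d))    # wrapped distance
    # Normalize by the uniform-histogram expectation so the score is ~0
    # for isotropic orientations and 1 for a single-bin histogram.
    uniform_msd = float((np.minimum(np.arange(_N_DIR_BINS),
                                    _N_DIR_BINS - np.arange(_N_DIR_BINS)) ** 2).mean())
    return float(1.0 - (p * d.astype(np.float64) ** 2).sum() / uniform_msd)


def tamura_features(gray: np.ndarray) -> np.ndarray:
    """(coarseness, contrast, directionality) for a grayscale image."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("tamura_features expects a single-channel image")
    if min(gray.shape) < 32:
        raise ValueError("tamura_features requires an image of at least 32x32")
    return np.array([coarseness(gray), tamura_contrast(gray),
                     directionality(gray)])
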