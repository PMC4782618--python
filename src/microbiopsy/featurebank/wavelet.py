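"""Two-level Daubechies-4 wavelet subband statistics (32 values).

The image is decomposed with two successive single-level 2-D DWTs
(orthonormal db4, periodization mode, so Parseval's identity holds
exactly up to float error).  Eight subbands are kept — approximation and
the three detail orientations at each level — and each contributes four
statistics: mean absolute coefficient, Shannon entropy (bits) of the
normalized absolute-coefficient distribution, energy (sum of squares),
and the plain coefficient sum.  8 x 4 = 32 values in fixed order.
"""

from __future__ import annotations

import numpy as np
import pywt

WAVELET = "db4"
MODE = "periodization"
SUBBAND_NAMES = ("ll1", "lh1", "hl1", "hh1", "ll2", "lh2", "hl2", "hh2")
STAT_NAMES = ("meanabs", "entropy", "energy", "sum")
N_WAVELET = 32


_ZERO_ATOL = 1e-8    # intensity units; subbands below this are numerically zero


def _subband_stats(c: np.ndarray) -> list[float]:
    c = np.asarray(c, dtype=np.float64).ravel()
    a = np.abs(c)
    total = a.sum()
    if a.max() > _ZERO_ATOL:
        p = a[a > 0] / total
        entropy = float(-(p * np.log2(p)).sum())
    else:
        # Numerically zero subband: the normalized |c| distribution is
        # round-off noise, not signal; its entropy is defined as 0.
        entropy = 0.0
    return [float(a.mean()), entropy, float((c ** 2).sum()), float(c.sum())]


def wavelet_features(gray: np.ndarray) -> np.ndarray:
    """32 db4 subband statistics for a grayscale image."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("wavelet_features expects a single-channel image")
    min_len = 2 * pywt.Wavelet(WAVELET).dec_len
    if min(gray.shape) < min_len:
        raise ValueError(f"image too small for a 2-level {WAVELET} transform")
    ll1, (lh1, hl1, hh1) = pywt.dwt2(gray, WAVELET, mode=MODE)
    ll2, (lh2, hl2, hh2) = pywt.dwt2(ll1, WAVELET, mode=MODE)
    out: list[float] = []
    for band in (ll1, lh1, hl1, hh1, ll2, lh2, hl2, hh2):
        out.extend(_subband_stats(band))
    return np.array(out)
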