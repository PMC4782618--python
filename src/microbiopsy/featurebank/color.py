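"""HSV color statistics of the region of interest (6 values).

ROI pixels are converted to HSV (H in [0, 1), S and V in [0, 1]) and the
mean and population standard deviation of each component are reported:
(mean H, sd H, mean S, sd S, mean V, sd V).
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv

COLOR_NAMES = ("h_mean", "h_sd", "s_mean", "s_sd", "v_mean", "v_sd")
N_COLOR = 6


def color_features(rgb: np.ndarray, roi: np.ndarray | None = None) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("color_features expects an (H, W, 3) RGB image")
    if roi is None:
        pixels = rgb.reshape(-1, 3)
    else:
        roi = np.asarray(roi).astype(bool)
        if roi.shape != rgb.shape[:2]:
            raise ValueError("roi and image are not aligned")
        if not roi.any():
            raise ValueError("empty ROI")
        pixels = rgb[roi]
    hsv = rgb2hsv(pixels.reshape(-1, 1, 3).astype(np.float64) / 255.0).reshape(-1, 3)
    out = np.empty(6)
    out[0::2] = hsv.mean(axis=0)
    out[1::2] = hsv.std(axis=0)
    return out
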