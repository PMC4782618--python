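"""Laws texture energy measures (6 values).

5x5 separable masks are built as outer products of the level, edge,
spot and ripple vectors L5 = [1,4,6,4,1], E5 = [-1,-2,0,2,1],
S5 = [-1,0,2,0,-1], R5 = [1,-4,6,-4,1].  The local mean (15x15 average)
is removed first so that the level component does not dominate, each
mask response is converted to a texture energy image (15x15 moving
average of |response|), and the image-wide mean energy is reported.
Orientation is factored out by averaging transpose pairs, giving six
outputs: L5E5/E5L5, L5S5/S5L5, E5S5/S5E5, E5E5, S5S5 and R5R5.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve, uniform_filter

N_LAWS = 6
LAWS_NAMES = ("l5e5", "l5s5", "e5s5", "e5e5", "s5s5", "r5r5")

_L5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
_E5 = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])
_S5 = np.array([-1.0, 0.0, 2.0, 0.0, -1.0])
_R5 = np.array([1.0, -4.0, 6.0, -4.0, 1.0])
_WINDOW = 15


def _energy(img: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    response = convolve(img, np.outer(row, col), mode="reflect")
    return uniform_filter(np.abs(response), size=_WINDOW, mode="reflect")


def laws_features(gray: np.ndarray) -> np.ndarray:
    """Six Laws texture energies of :data:`LAWS_NAMES`, in order."""
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("laws_features expects a single-channel image")
    if min(g.shape) < _WINDOW:
        raise ValueError(f"image must be at least {_WINDOW}x{_WINDOW}")
    g = g - uniform_filter(g, size=_WINDOW, mode="reflect")

    def pair(u: np.ndarray, v: np.ndarray) -> float:
        return float(((_energy(g, u, v) + _energy(g, v, u)) / 2.0).mean())

    def single(u: np.ndarray) -> float:
        return float(_energy(g, u, u).mean())

    return np.array([
        pair(_L5, _E5),
        pair(_L5, _S5),
        pair(_E5, _S5),
        single(_E5),
        single(_S5),
        single(_R5),
    ])
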