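"""The fixed, versioned 115-feature schema.

Families and widths: texture (GLCM) 22, shape 10, HOG 36, wavelet 32,
HSV color 6, Tamura 3, Laws texture energy 6 — 115 in total.  Names are
``F{index:03d}_{family-specific name}`` and their order never changes.
"""

from __future__ import annotations

from .color import COLOR_NAMES
from .glcm import TEXTURE_NAMES
from .hog import HOG_ORIENTATIONS
from .laws import LAWS_NAMES
from .shape import SHAPE_NAMES
from .tamura import TAMURA_NAMES
from .wavelet import STAT_NAMES, SUBBAND_NAMES

SCHEMA_VERSION = 1

FAMILY_SIZES = {
    "texture": 22,
    "shape": 10,
    "hog": 36,
    "wavelet": 32,
    "color": 6,
    "tamura": 3,
    "lte": 6,
}

N_FEATURES = 115


def _base_names() -> list[str]:
    names: list[str] = []
    names += list(TEXTURE_NAMES)
    names += list(SHAPE_NAMES)
    names += [f"hog_c{cell}_b{b}" for cell in range(4)
              for b in range(HOG_ORIENTATIONS)]
    names += [f"wav_{band}_{stat}" for band in SUBBAND_NAMES
              for stat in STAT_NAMES]
    names += [f"hsv_{n}" for n in COLOR_NAMES]
    names += [f"tamura_{n}" for n in TAMURA_NAMES]
    names += [f"lte_{n}" for n in LAWS_NAMES]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(
    f"F{i + 1:03d}_{name}" for i, name in enumerate(_base_names())
)

assert len(FEATURE_NAMES) == N_FEATURES
assert sum(FAMILY_SIZES.values()) == N_FEATURES


def family_slices() -> dict[str, slice]:
    """Start/stop slice of each family within the 115-vector."""
    out: dict[str, slice] = {}
    start = 0
    for fam, size in FAMILY_SIZES.items():
        out[fam] = slice(start, start + size)
        start += size
    return out
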