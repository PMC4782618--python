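"""Fixed 36-value histogram-of-oriented-gradients descriptor.

The ROI bounding box is resampled to a 64x64 patch; gradients are taken
by centered differences; unsigned orientations (0-180 degrees) are
binned into 9 bins per cell over a 2x2 grid of 32x32-px cells, and the
single resulting block is L2-normalized.  4 cells x 9 bins = 36 values;
a constant patch yields the all-zero descriptor.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import hog as _sk_hog
from skimage.transform import resize

HOG_PATCH = 64
HOG_ORIENTATIONS = 9
HOG_CELL = 32
N_HOG = 36


def hog_features(gray: np.ndarray, bbox: tuple[int, int, int, int] | None = None
                 ) -> np.ndarray:
    """36 HOG values for the (optionally cropped) grayscale image.

    ``bbox`` is (row_min, col_min, row_max, col_max), exclusive on the
    max side, e.g. from the ROI's extent.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("hog_features expects a single-channel image")
    if bbox is not None:
        r0, c0, r1, c1 = bbox
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"degenerate bounding box {bbox!r}")
        gray = gray[r0:r1, c0:c1]
    if gray.size == 0:
        raise ValueError("empty patch")
    patch = resize(gray, (HOG_PATCH, HOG_PATCH), order=1,
                   preserve_range=True, anti_aliasing=False)
    vec = _sk_hog(patch, orientations=HOG_ORIENTATIONS,
                  pixels_per_cell=(HOG_CELL, HOG_CELL),
                  cells_per_block=(2, 2), block_norm="L2",
                  feature_vector=True)
    assert vec.shape == (N_HOG,)
    return vec


def roi_bbox(roi: np.ndarray) -> tuple[int, int, int, int]:
    """Tight (r0, c0, r1, c1) bounding box of a boolean mask."""
    ys, xs = np.nonzero(np.asarray(roi).astype(bool))
    if ys.size == 0:
        raise ValueError("empty ROI")
    return int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1
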