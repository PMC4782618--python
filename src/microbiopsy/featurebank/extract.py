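"""Assembly of the full 115-dimensional feature vector and feature matrices.

Region conventions: GLCM texture, shape and HSV color features are
computed on the segmented nucleus ROI; HOG on the ROI bounding box; the
wavelet, Tamura and Laws families describe the tissue as a whole and are
computed on the full grayscale image.  The grayscale channel is the
BT.601 luminance of the (typically CLAHE-enhanced) RGB input.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ..imageio import load_mask, load_rgb, to_gray
from .color import color_features
from .glcm import glcm, glcm_stats
from .hog import hog_features, roi_bbox
from .laws import laws_features
from .schema import FEATURE_NAMES, N_FEATURES
from .shape import shape_features
from .tamura import tamura_features
from .wavelet import wavelet_features

logger = logging.getLogger(__name__)


class FeatureError(RuntimeError):
    """A feature family failed; carries the family name."""

    def __init__(self, family: str, cause: Exception):
        super().__init__(f"feature family {family!r} failed: {cause}")
        self.family = family


def extract_all(rgb: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """The 115-value feature vector for one image and its nucleus ROI."""
    rgb = np.asarray(rgb)
    roi = np.asarray(roi).astype(bool)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("extract_all expects an (H, W, 3) RGB image")
    if roi.shape != rgb.shape[:2]:
        raise ValueError("roi and image are not aligned")
    gray = to_gray(rgb)

    parts: list[np.ndarray] = []
    families = (
        ("texture", lambda: glcm_stats(glcm(gray, roi))),
        ("shape", lambda: shape_features(roi)),
        ("hog", lambda: hog_features(gray, roi_bbox(roi))),
        ("wavelet", lambda: wavelet_features(gray)),
        ("color", lambda: color_features(rgb, roi)),
        ("tamura", lambda: tamura_features(gray)),
        ("lte", lambda: laws_features(gray)),
    )
    for name, fn in families:
        try:
            parts.append(np.asarray(fn(), dtype=np.float64))
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise FeatureError(name, exc) from exc
    vec = np.concatenate(parts)
    if vec.shape != (N_FEATURES,):
        raise AssertionError(f"feature vector length {vec.shape} != {N_FEATURES}")
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[i] for i in np.nonzero(~np.isfinite(vec))[0]]
        raise ValueError(f"non-finite features: {bad}")
    return vec


def build_feature_matrix(manifest: pd.DataFrame | str | Path,
                         image_dir: str | Path | None = None,
                         out_csv: str | Path | None = None) -> pd.DataFrame:
    """One feature row per manifest image, plus the class label column.

    The manifest needs columns ``filename``, ``mask`` and ``label`` (as
    written by the synthetic generator).  Unreadable or failing rows are
    skipped with a logged warning.  The mask column is used as the ROI;
    pass masks produced by segmentation to emulate the full pipeline, or
    ground-truth masks to isolate the feature stage.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if image_dir is None:
            image_dir = manifest_path.parent
        manifest = pd.read_csv(manifest_path)
    if image_dir is None:
        raise ValueError("image_dir is required with a DataFrame manifest")
    image_dir = Path(image_dir)

    rows: list[np.ndarray] = []
    labels: list[str] = []
    for rec in manifest.itertuples(index=False):
        try:
            rgb = load_rgb(image_dir / rec.filename)
            roi = load_mask(image_dir / rec.mask)
            rows.append(extract_all(rgb, roi))
            labels.append(rec.label)
        except Exception as exc:  # noqa: BLE001 - row-level robustness
            logger.warning("skipping %s: %s", rec.filename, exc)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df["label"] = labels
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
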