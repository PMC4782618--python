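"""Gray-level co-occurrence matrix and its 22 texture statistics.

The GLCM P(i, j) is the joint distribution of quantized intensities of
pixel pairs at fixed offsets, restricted to pairs that lie entirely
inside the region of interest.  Counts are symmetrized (transpose added)
and normalized to sum 1; several offsets are averaged after
normalization.  From P derive the extended Haralick statistic set:
autocorrelation, contrast, two correlation variants, cluster prominence,
cluster shade, difference variance, dissimilarity, energy, entropy,
homogeneity, maximum probability, sum of squares (variance), sum
average, sum variance, sum entropy, difference entropy, the two
information measures of correlation, inverse difference, inverse
difference normalized and inverse difference moment normalized.

Entropies use log base 2 with the convention 0 * log 0 = 0.  Gray levels
are indexed 1..L in the moment-type statistics, matching the common
MATLAB-style formulation.  The two correlation variants are two textbook
presentations of the same normalized covariance; for a symmetric
normalized GLCM they coincide, which keeps the canonical 22-slot layout
without inventing an undocumented statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_LEVELS = 32
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

TEXTURE_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation",
    "correlation2",
    "cluster_prominence",
    "cluster_shade",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "sum_of_squares",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)


@dataclass(frozen=True)
class Glcm:
    p: np.ndarray                       # (L, L), >= 0, sums to 1
    offsets: tuple[tuple[int, int], ...]
    levels: int


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of uint8 intensities into `levels` bins."""
    return (np.asarray(gray).astype(np.int64) * levels) >> 8


def glcm(gray: np.ndarray, roi: np.ndarray | None = None,
         levels: int = DEFAULT_LEVELS,
         offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS) -> Glcm:
    """Masked, symmetrized, normalized co-occurrence matrix.

    Only pixel pairs with both members inside ``roi`` contribute.  Raises
    ValueError when the ROI admits no co-occurring pair at any offset.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("glcm expects a single-channel image")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    roi = np.ones(gray.shape, dtype=bool) if roi is None else np.asarray(roi).astype(bool)
    if roi.shape != gray.shape:
        raise ValueError("roi and image are not aligned")
    q = quantize(gray, levels)

    acc = np.zeros((levels, levels), dtype=np.float64)
    n_used = 0
    h, w = gray.shape
    for dy, dx in offsets:
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        ys2 = slice(max(0, dy), min(h, h + dy))
        xs2 = slice(max(0, dx), min(w, w + dx))
        valid = roi[ys, xs] & roi[ys2, xs2]
        if not valid.any():
            continue
        a = q[ys, xs][valid]
        b = q[ys2, xs2][valid]
        counts = np.bincount(a * levels + b, minlength=levels * levels)
        c = counts.reshape(levels, levels).astype(np.float64)
        c = c + c.T                      # symmetrize
        acc += c / c.sum()               # normalize per offset, then average
        n_used += 1
    if n_used == 0:
        raise ValueError("ROI contains no co-occurring pixel pair at any offset")
    return Glcm(p=acc / n_used, offsets=tuple(offsets), levels=levels)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) + 0.0   # normalize -0.0


def glcm_stats(g: Glcm) -> np.ndarray:
    """The 22 texture statistics of :data:`TEXTURE_NAMES`, in order."""
    p = np.asarray(g.p, dtype=np.float64)
    L = p.shape[0]
    if p.shape != (L, L) or not np.isclose(p.sum(), 1.0):
        raise ValueError("glcm_stats expects a normalized square GLCM")
    idx = np.arange(1, L + 1, dtype=np.float64)
    i = idx[:, None] * np.ones((1, L))
    j = np.ones((L, 1)) * idx[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2L and p_{x-y}(k), k = 0..L-1
    sums = (i + j).astype(int)
    diffs = np.abs(i - j).astype(int)
    p_sum = np.bincount(sums.ravel(), weights=p.ravel(), minlength=2 * L + 1)[2:]
    p_diff = np.bincount(diffs.ravel(), weights=p.ravel(), minlength=L)
    k_sum = np.arange(2, 2 * L + 1, dtype=np.float64)
    k_diff = np.arange(0, L, dtype=np.float64)

    autocorrelation = float((i * j * p).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = (autocorrelation - mu_x * mu_y) / (sd_x * sd_y)
        correlation2 = float((((i - mu_x) * (j - mu_y) * p).sum()) / (sd_x * sd_y))
    else:
        correlation = correlation2 = 0.0   # constant region: no variation
    cluster_prominence = float(((i + j - mu_x - mu_y) ** 4 * p).sum())
    cluster_shade = float(((i + j - mu_x - mu_y) ** 3 * p).sum())
    dissimilarity = float((np.abs(i - j) * p).sum())
    energy = float((p ** 2).sum())
    entropy = _entropy2(p.ravel())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    maximum_probability = float(p.max())
    sum_of_squares = float(((i - mu_x) ** 2 * p).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy2(p_sum)
    difference_entropy = _entropy2(p_diff)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())

    hxy = entropy
    pxy = np.outer(px, py)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    hx = _entropy2(px)
    hy = _entropy2(py)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    inverse_difference = float((p / (1.0 + np.abs(i - j))).sum())
    inn = float((p / (1.0 + np.abs(i - j) / L)).sum())
    idmn = float((p / (1.0 + (i - j) ** 2 / L ** 2)).sum())

    return np.array([
        autocorrelation, contrast, correlation, correlation2,
        cluster_prominence, cluster_shade, difference_variance,
        dissimilarity, energy, entropy, homogeneity, maximum_probability,
        sum_of_squares, sum_average, sum_variance, sum_entropy,
        difference_entropy, imc1, imc2, inverse_difference, inn, idmn,
    ])
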