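"""Clustering-based segmentation of biopsy images and nucleus ROI selection.

Pixels are clustered in color space (RGB, or CIE L*a*b* for the "color
k-means" variant) with Lloyd's algorithm under squared Euclidean distance,
or with fuzzy c-means.  Labels are canonicalized by descending cluster
size so that a given (image, k, seed) always yields the identical mask.
The nucleus region of interest is then selected from the clusters by a
simple rule — in H&E images the hematoxylin-stained nuclei are the
blue-dominant (and darkest) cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab

from .imageio import LUMA_WEIGHTS

MAX_ITER = 300
FCM_TOL = 1e-5


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel cluster labels in {0..k-1}."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.size and (labels.min() < 0 or labels.max() >= self.k):
            raise ValueError("labels must lie in {0..k-1}")


@dataclass(frozen=True)
class FcmResult:
    mask: LabelMask
    memberships: np.ndarray  # (H, W, k), rows sum to 1
    converged: bool

    def __iter__(self):  # allow (mask, memberships) unpacking
        return iter((self.mask, self.memberships))


def _canonicalize(assign: np.ndarray, k: int) -> np.ndarray:
    """Renumber labels by descending cluster size (ties: lower old label first)."""
    counts = np.bincount(assign.ravel(), minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=np.int32)
    remap[order] = np.arange(k, dtype=np.int32)
    return remap[assign]


def _pixel_features(img: np.ndarray, color_space: str) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if color_space == "rgb":
        return img.reshape(-1, 3).astype(np.float64)
    if color_space == "lab":
        return rgb2lab(img).reshape(-1, 3)
    raise ValueError(f"unknown color_space {color_space!r}")


def lloyd_kmeans(x: np.ndarray, k: int, seed: int,
                 max_iter: int = MAX_ITER) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd's k-means on row vectors.

    Initialization picks k points with distinct coordinates uniformly at
    random (seeded).  An emptied cluster is re-seeded at the point
    farthest from its assigned center, keeping k fixed.  Returns
    (assignments, centers, within-cluster-SSQ history).
    """
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty input")
    uniq = np.unique(x, axis=0)
    if k < 1 or k > uniq.shape[0]:
        raise ValueError(f"k={k} must be in [1, number of distinct points "
                         f"({uniq.shape[0]})]")
    rng = np.random.default_rng(seed)
    centers = uniq[rng.choice(uniq.shape[0], size=k, replace=False)].astype(np.float64)

    assign = np.full(n, -1, dtype=np.int32)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1).astype(np.int32)
        nearest_d2 = d2[np.arange(n), new_assign]
        for c in range(k):
            if not np.any(new_assign == c):
                far = int(np.argmax(nearest_d2))
                centers[c] = x[far]
                new_assign[far] = c
                nearest_d2[far] = 0.0
        history.append(float(nearest_d2.sum()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            members = x[assign == c]
            if members.size:
                centers[c] = members.mean(axis=0)
    return assign, centers, history


def kmeans_segment(img: np.ndarray, k: int = 3, seed: int = 0,
                   color_space: str = "rgb") -> LabelMask:
    """Segment an RGB image into k clusters by color k-means."""
    x = _pixel_features(img, color_space)
    assign, _, _ = lloyd_kmeans(x, k, seed)
    labels = _canonicalize(assign, k).reshape(img.shape[:2])
    return LabelMask(labels=labels, k=k)


def fcm_segment(img: np.ndarray, k: int = 3, m: float = 2.0, seed: int = 0,
                max_iter: int = MAX_ITER, tol: float = FCM_TOL) -> FcmResult:
    """Fuzzy c-means segmentation in RGB space.

    Standard alternating updates: memberships u_ic proportional to
    d_ic^(-2/(m-1)), centers as u^m-weighted means.  The hard mask is the
    per-pixel argmax membership.  If centers have not moved by less than
    ``tol`` after ``max_iter`` iterations the best iterate is returned
    with ``converged=False``.
    """
    if k < 2:
        raise ValueError("fcm_segment requires k >= 2")
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")
    x = _pixel_features(img, "rgb")
    n = x.shape[0]
    uniq = np.unique(x, axis=0)
    if k > uniq.shape[0]:
        raise ValueError(f"k={k} exceeds distinct colors ({uniq.shape[0]})")
    rng = np.random.default_rng(seed)
    centers = uniq[rng.choice(uniq.shape[0], size=k, replace=False)].astype(np.float64)

    power = -2.0 / (m - 1.0)
    converged = False
    u = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-12
        with np.errstate(divide="ignore"):
            w = np.where(zero, np.inf, d2) ** (power / 2.0)
        u = w / w.sum(axis=1, keepdims=True)
        # Zero-distance convention: full membership to the coincident center.
        hit = zero.any(axis=1)
        if hit.any():
            u[hit] = 0.0
            u[hit, np.argmax(zero[hit], axis=1)] = 1.0
        um = u ** m
        new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break
    assign = np.argmax(u, axis=1).astype(np.int32)
    remap_src = _canonicalize(assign, k)
    # Reorder membership columns consistently with the canonical labels.
    counts = np.bincount(assign, minlength=k)
    order = np.argsort(-counts, kind="stable")
    u = u[:, order]
    labels = remap_src.reshape(img.shape[:2])
    return FcmResult(mask=LabelMask(labels=labels, k=k),
                     memberships=u.reshape(*img.shape[:2], k),
                     converged=converged)


def select_roi(mask: LabelMask, img: np.ndarray, rule: str = "most_blue",
               index: int | None = None) -> np.ndarray:
    """Pick the nucleus cluster from a segmentation; return a boolean ROI mask.

    Rules: ``darkest`` — minimum mean luminance; ``most_blue`` — maximum
    blue-channel dominance mean(B) - mean(R+G)/2 (hematoxylin); ``by_index``
    — the explicit cluster label.
    """
    labels = np.asarray(mask.labels)
    img = np.asarray(img)
    if labels.shape != img.shape[:2]:
        raise ValueError("mask and image are not aligned")
    if rule == "by_index":
        if index is None:
            raise ValueError("by_index rule requires an index")
        roi = labels == index
        if not roi.any():
            raise ValueError(f"cluster {index} is empty")
        return roi
    scores = []
    for c in range(mask.k):
        sel = labels == c
        if not sel.any():
            scores.append(np.inf if rule == "darkest" else -np.inf)
            continue
        pix = img[sel].astype(np.float64)
        if rule == "darkest":
            scores.append(float((pix @ LUMA_WEIGHTS).mean()))
        elif rule == "most_blue":
            scores.append(float(pix[:, 2].mean() - (pix[:, 0].mean() + pix[:, 1].mean()) / 2.0))
        else:
            raise ValueError(f"unknown ROI rule {rule!r}")
    best = int(np.argmin(scores)) if rule == "darkest" else int(np.argmax(scores))
    return labels == best
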