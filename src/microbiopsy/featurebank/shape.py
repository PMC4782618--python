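"""Region shape descriptors and per-nucleus morphology.

Two views of the same geometry are provided:

* :func:`shape_features` — the 10-value shape family of the feature
  vector (area, perimeter, major/minor axis lengths, equivalent
  diameter, orientation, convex area, filled area, solidity,
  eccentricity), computed on the ROI as a single region (largest
  connected component if fragmented).
* :func:`nucleus_descriptors` — per-nucleus clinically named
  descriptors: area, brightness, longest/shortest diameter, elongation,
  perimeter, roundness, solidity, eccentricity and compactness.

Perimeter uses the chain-code weighting: axis-parallel boundary steps
count 1, diagonal steps count sqrt(2).  Diameters come from the image
second moments with the 1/12-per-pixel extent correction, so a
single-pixel-wide bar still has a finite shortest diameter (~1 px).
Eccentricity here is the major/minor axis-length ratio (>= 1), not the
standard ellipse eccentricity; the name is kept because it is the
convention of the morphology literature this feature set follows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

SHAPE_NAMES = (
    "area", "perimeter", "major_axis_length", "minor_axis_length",
    "equivalent_diameter", "orientation", "convex_area", "filled_area",
    "solidity", "eccentricity",
)

# Moore neighborhood in clockwise order starting East; even chain codes
# are axis moves (length 1), odd are diagonal (length sqrt(2)).
_MOORE = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


@dataclass(frozen=True)
class NucleusShape:
    area: float
    brightness: float
    nld: float            # nucleus longest diameter
    nsd: float            # nucleus shortest diameter
    elongation: float     # NSD / NLD, in (0, 1]
    perimeter: float
    roundness: float      # 4*pi*A / P^2
    solidity: float
    eccentricity: float   # NLD / NSD, >= 1
    compactness: float    # A / P^2


def chain_code_perimeter(mask: np.ndarray) -> float:
    """Boundary length of a single 8-connected region by Moore tracing.

    Returns the number of even (axis) chain moves plus sqrt(2) times the
    odd (diagonal) moves.  A single-pixel region has perimeter 1.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty region")
    if mask.sum() == 1:
        return 1.0
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    start = tuple(np.argwhere(padded)[0])      # first foreground in raster order

    even = odd = 0
    current = start
    # Pretend we arrived at the start pixel moving East (its West neighbor
    # is background because raster order scans left to right).
    prev_dir = 0
    first_move = None
    while True:
        # Search the Moore neighborhood clockwise, starting just after the
        # backtrack direction.
        found = None
        for step in range(8):
            d = (prev_dir + 5 + step) % 8
            ny, nx = current[0] + _MOORE[d][0], current[1] + _MOORE[d][1]
            if padded[ny, nx]:
                found = (d, (ny, nx))
                break
        if found is None:       # isolated pixel (handled above, defensive)
            return 1.0
        d, nxt = found
        if d % 2 == 0:
            even += 1
        else:
            odd += 1
        if first_move is None:
            first_move = (current, d)
        elif (current, d) == first_move:
            # Jacob's stopping criterion: re-entered the start move.
            if d % 2 == 0:
                even -= 1
            else:
                odd -= 1
            break
        current = nxt
        prev_dir = d
    return float(even + math.sqrt(2.0) * odd)


def moment_axes(mask: np.ndarray) -> tuple[float, float]:
    """(major, minor) axis lengths from second moments with pixel-extent
    correction (+1/12 per coordinate)."""
    ys, xs = np.nonzero(np.asarray(mask).astype(bool))
    if ys.size == 0:
        raise ValueError("empty region")
    y = ys - ys.mean()
    x = xs - xs.mean()
    cov = np.array([[np.mean(x * x) + 1.0 / 12.0, np.mean(x * y)],
                    [np.mean(x * y), np.mean(y * y) + 1.0 / 12.0]])
    eig = np.linalg.eigvalsh(cov)
    minor, major = 4.0 * np.sqrt(np.maximum(eig, 0.0))
    return float(major), float(minor)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = cc_label(mask, connectivity=2)
    if lab.max() == 0:
        raise ValueError("empty ROI")
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


def shape_features(roi: np.ndarray) -> np.ndarray:
    """The 10 shape features of :data:`SHAPE_NAMES` for the ROI region."""
    region_mask = _largest_component(np.asarray(roi).astype(bool))
    props = regionprops(region_mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = chain_code_perimeter(region_mask)
    major, minor = moment_axes(region_mask)
    equiv_d = math.sqrt(4.0 * area / math.pi)
    orientation = math.degrees(float(props.orientation))
    convex_area = float(props.area_convex)
    filled_area = float(props.area_filled)
    solidity = area / convex_area
    eccentricity = major / max(minor, 1e-12)
    return np.array([area, perimeter, major, minor, equiv_d, orientation,
                     convex_area, filled_area, solidity, eccentricity])


def nucleus_descriptors(nucleus_labels: np.ndarray,
                        gray: np.ndarray) -> list[NucleusShape]:
    """Per-nucleus morphology from an integer label mask (0 = background).

    A binary mask is accepted too, in which case connected components are
    treated as individual nuclei.
    """
    labels = np.asarray(nucleus_labels)
    gray = np.asarray(gray)
    if labels.shape != gray.shape:
        raise ValueError("label mask and image are not aligned")
    if labels.dtype == bool or labels.max() <= 1:
        labels = cc_label(labels > 0, connectivity=2)
    out: list[NucleusShape] = []
    for idx in np.unique(labels):
        if idx == 0:
            continue
        m = labels == idx
        area = float(m.sum())
        brightness = float(gray[m].mean())
        nld, nsd = moment_axes(m)
        per = chain_code_perimeter(m)
        convex_area = float(regionprops(m.astype(np.uint8))[0].area_convex)
        out.append(NucleusShape(
            area=area,
            brightness=brightness,
            nld=nld,
            nsd=nsd,
            elongation=nsd / nld,
            perimeter=per,
            roundness=4.0 * math.pi * area / per ** 2,
            solidity=area / convex_area,
            eccentricity=nld / nsd,
            compactness=area / per ** 2,
        ))
    return out
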