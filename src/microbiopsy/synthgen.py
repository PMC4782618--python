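"""Seeded generator of synthetic H&E-like biopsy scenes with ground truth.

Real H&E microscopy shows blue-purple hematoxylin-stained nuclei on a pink
eosin-stained cytoplasm background.  The generator renders each scene as a
flat cytoplasm field with non-overlapping elliptical nuclei whose radii are
log-normal, whose orientation is uniform, and whose boundary is perturbed
by a low-order sinusoidal radial modulation.  Two documented parameter sets
emulate the classic normal-vs-cancerous morphology contrasts: cancerous
scenes have larger and more variably sized nuclei, more irregular nuclear
boundaries, a more variable cell count per unit area, and stronger
chromatin mottling (a smooth intra-nuclear intensity texture).

Every output is a pure function of the scene specification (including its
seed): regenerating with the same spec reproduces the scene byte-for-byte.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .imageio import save_mask, save_rgb

#: Approximate H&E stain colors (8-bit RGB).
NUCLEUS_COLOR = (70, 50, 150)     # hematoxylin: blue-purple
CYTOPLASM_COLOR = (235, 170, 200)  # eosin: pink

#: Documented per-class morphology constants.  The qualitative contrasts
#: (larger, more variable, more irregular nuclei in cancer; more variable
#: cellularity) are standard histopathology; the numeric values are
#: synthetic stand-ins chosen to give a clean but non-trivial two-class
#: problem at 160x160 px.
CLASS_PARAMS = {
    "normal": dict(
        nucleus_radius_mean=7.0,
        nucleus_radius_cv=0.08,
        boundary_irregularity=0.05,
        chromatin_mottle_sd=2.0,
        n_nuclei_range=(9, 11),
    ),
    "cancerous": dict(
        nucleus_radius_mean=10.0,
        nucleus_radius_cv=0.30,
        boundary_irregularity=0.30,
        chromatin_mottle_sd=12.0,
        n_nuclei_range=(6, 10),
    ),
}

DEFAULT_IMAGE_SIZE = (160, 160)
DEFAULT_NOISE_SD = 12.0

_MAX_PLACEMENT_RETRIES = 500


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails (over-dense spec)."""


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of one synthetic biopsy scene."""

    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    n_nuclei: int = 10
    nucleus_radius_mean: float = 7.0
    nucleus_radius_cv: float = 0.08
    boundary_irregularity: float = 0.05
    nucleus_color: tuple[int, int, int] = NUCLEUS_COLOR
    cytoplasm_color: tuple[int, int, int] = CYTOPLASM_COLOR
    color_noise_sd: float = DEFAULT_NOISE_SD
    chromatin_mottle_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius_cv < 0:
            raise ValueError("nucleus_radius_cv must be >= 0")
        if not 0.0 <= self.boundary_irregularity <= 1.0:
            raise ValueError("boundary_irregularity must lie in [0, 1]")
        for color in (self.nucleus_color, self.cytoplasm_color):
            if len(color) != 3 or any(not 0 <= c <= 255 for c in color):
                raise ValueError(f"invalid 8-bit RGB triple: {color!r}")
        if self.color_noise_sd < 0:
            raise ValueError("color_noise_sd must be >= 0")
        if self.chromatin_mottle_sd < 0:
            raise ValueError("chromatin_mottle_sd must be >= 0")


@dataclass(frozen=True)
class Nucleus:
    """Ground-truth geometry of one rendered nucleus."""

    center: tuple[float, float]      # (row, col)
    semi_major: float                # pixels
    semi_minor: float                # pixels
    orientation: float               # radians
    wobble_amp: float                # fractional radial amplitude
    wobble_harmonic: int             # sinusoid order (cycles per revolution)
    wobble_phase: float              # radians


@dataclass(frozen=True)
class LabeledScene:
    """A rendered scene plus its per-pixel ground truth."""

    image: np.ndarray                # (H, W, 3) uint8
    nucleus_mask: np.ndarray         # (H, W) bool
    per_nucleus_labels: np.ndarray   # (H, W) int32, 0 = background
    class_label: str
    nuclei: tuple[Nucleus, ...] = field(default=())
    spec: SceneSpec | None = None


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and coefficient of variation."""
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def nucleus_membership(nuc: Nucleus, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Boolean membership of pixel centers inside the perturbed ellipse.

    A point is inside when its elliptical radius s = sqrt((x'/a)^2 + (y'/b)^2)
    in the nucleus frame satisfies s <= 1 + amp * sin(h*theta + phase).
    """
    dy = rows - nuc.center[0]
    dx = cols - nuc.center[1]
    c, s = math.cos(nuc.orientation), math.sin(nuc.orientation)
    x = c * dx + s * dy
    y = -s * dx + c * dy
    radial = np.sqrt((x / nuc.semi_major) ** 2 + (y / nuc.semi_minor) ** 2)
    theta = np.arctan2(y, x)
    boundary = 1.0 + nuc.wobble_amp * np.sin(nuc.wobble_harmonic * theta + nuc.wobble_phase)
    return radial <= boundary


def generate_scene(spec: SceneSpec, class_label: str = "normal") -> LabeledScene:
    """Render one scene: place nuclei by rejection sampling, then add noise.

    Raises :class:`PlacementError` if a nucleus cannot be placed without
    overlap after a bounded number of retries.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    rr, cc = np.mgrid[0:h, 0:w]

    mu, sigma = _lognormal_params(max(spec.nucleus_radius_mean, 1e-9),
                                  spec.nucleus_radius_cv)
    # Draw all nucleus geometries first, then place largest-first: the
    # tightest constraints are resolved while the scene is still empty,
    # which makes rejection placement far more reliable.
    geoms = []
    for _ in range(spec.n_nuclei):
        radius = float(rng.lognormal(mu, sigma)) if spec.nucleus_radius_cv > 0 \
            else spec.nucleus_radius_mean
        # Area-preserving aspect ratio; more irregular classes are also
        # more anisotropic ("variably shaped nuclei").
        aspect = 1.0 + abs(rng.normal(0.0, 0.10 + 0.5 * spec.boundary_irregularity))
        a = radius * math.sqrt(aspect)
        b = radius / math.sqrt(aspect)
        orientation = float(rng.uniform(0.0, math.pi))
        harmonic = int(rng.integers(2, 5))          # low-order: 2..4 lobes
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        geoms.append((a, b, orientation, harmonic, phase))
    order = sorted(range(len(geoms)), key=lambda g: -geoms[g][0])

    placed: list[Nucleus] = []
    for rank, gi in enumerate(order):
        a, b, orientation, harmonic, phase = geoms[gi]
        bound = a * (1.0 + spec.boundary_irregularity) + 1.0
        if 2 * bound >= min(h, w):
            raise PlacementError(
                f"nucleus semi-major axis {a:.1f} px does not fit a "
                f"{h}x{w} scene: {spec}")
        for _ in range(_MAX_PLACEMENT_RETRIES):
            cy = float(rng.uniform(bound, h - bound))
            cx = float(rng.uniform(bound, w - bound))
            ok = all(
                math.hypot(cy - p.center[0], cx - p.center[1])
                > bound + p.semi_major * (1.0 + p.wobble_amp) + 1.0
                for p in placed
            )
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place nucleus {rank + 1}/{spec.n_nuclei} after "
                f"{_MAX_PLACEMENT_RETRIES} retries; spec too dense: {spec}")
        nuc = Nucleus((cy, cx), a, b, orientation,
                      spec.boundary_irregularity, harmonic, phase)
        placed.append(nuc)
        inside = nucleus_membership(nuc, rr, cc)
        labels[inside] = len(placed)

    mask = labels > 0
    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = np.asarray(spec.cytoplasm_color, dtype=np.float64)
    image[mask] = np.asarray(spec.nucleus_color, dtype=np.float64)
    if spec.chromatin_mottle_sd > 0 and mask.any():
        # Chromatin mottling: a smooth zero-mean luminance field added to
        # nucleus pixels only (all channels equally, like absorbance).
        # Cancerous nuclei get a coarser, stronger chromatin pattern.
        field = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 2.0)
        sd = field.std()
        if sd > 0:
            image[mask] += (field[mask] / sd * spec.chromatin_mottle_sd)[:, None]
    if spec.color_noise_sd > 0:
        image += rng.normal(0.0, spec.color_noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return LabeledScene(image=image, nucleus_mask=mask,
                        per_nucleus_labels=labels, class_label=class_label,
                        nuclei=tuple(placed), spec=spec)


def class_spec(label: str, base_seed: int) -> SceneSpec:
    """Deterministic per-class scene specification.

    The per-scene nucleus count is drawn (seeded) from a class-specific
    range; the cancerous range is wider, so cellularity varies more
    between cancerous scenes.
    """
    if label not in CLASS_PARAMS:
        raise ValueError(f"unknown class label {label!r}; "
                         f"expected one of {sorted(CLASS_PARAMS)}")
    params = CLASS_PARAMS[label]
    code = sorted(CLASS_PARAMS).index(label)
    seed = int(np.random.SeedSequence([int(base_seed), code])
               .generate_state(1)[0] % (2 ** 31))
    lo, hi = params["n_nuclei_range"]
    n_nuclei = int(np.random.default_rng(seed).integers(lo, hi + 1))
    return SceneSpec(
        n_nuclei=n_nuclei,
        nucleus_radius_mean=params["nucleus_radius_mean"],
        nucleus_radius_cv=params["nucleus_radius_cv"],
        boundary_irregularity=params["boundary_irregularity"],
        chromatin_mottle_sd=params["chromatin_mottle_sd"],
        seed=seed,
    )


def generate_class_scene(label: str, base_seed: int, **overrides) -> LabeledScene:
    """Convenience: class_spec + generate_scene, with optional field overrides."""
    spec = class_spec(label, base_seed)
    if overrides:
        spec = replace(spec, **overrides)
    return generate_scene(spec, class_label=label)


@dataclass(frozen=True)
class ManifestRecord:
    filename: str
    mask: str
    label: str
    seed: int


def generate_dataset(n_per_class: int, seed: int, out_dir: str | Path,
                     ) -> list[ManifestRecord]:
    """Write a balanced two-class PNG dataset plus a CSV manifest.

    The manifest (``manifest.csv``) has header ``filename,mask,label,seed``;
    per-image seeds are derived deterministically from the master seed, so
    regeneration with the same arguments reproduces every file.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[ManifestRecord] = []
    for code, label in enumerate(sorted(CLASS_PARAMS)):
        for i in range(n_per_class):
            base = int(np.random.SeedSequence([int(seed), code, i])
                       .generate_state(1)[0] % (2 ** 31))
            scene = generate_class_scene(label, base)
            img_name = f"{label}_{i:04d}.png"
            mask_name = f"{label}_{i:04d}_mask.png"
            save_rgb(scene.image, out_dir / img_name)
            save_mask(scene.nucleus_mask, out_dir / mask_name)
            records.append(ManifestRecord(img_name, mask_name, label,
                                          scene.spec.seed))
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "mask", "label", "seed"])
        for rec in records:
            writer.writerow([rec.filename, rec.mask, rec.label, rec.seed])
    return records
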