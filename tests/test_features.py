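"""HOG, wavelet, color, Tamura, Laws families and full-vector assembly."""

import numpy as np
import pytest

from microbiopsy.featurebank import (
    FAMILY_SIZES,
    FEATURE_NAMES,
    N_FEATURES,
    build_feature_matrix,
    color_features,
    extract_all,
    family_slices,
    hog_features,
    laws_features,
    tamura_features,
    wavelet_features,
)
from microbiopsy.featurebank.extract import FeatureError


# ------------------------------------------------------------------ HOG
def test_hog_constant_patch_all_zero():
    assert np.allclose(hog_features(np.full((50, 50), 9.0)), 0.0)


def test_hog_length_and_stripe_concentration(rng):
    vec = hog_features(rng.integers(0, 256, (40, 60)).astype(np.uint8))
    assert vec.shape == (36,)
    stripes = np.tile(((np.arange(64) // 4) % 2) * 255.0, (64, 1))
    sv = hog_features(stripes).reshape(4, 9)
    # All gradient mass lies in one orientation bin, in every cell.
    for cell in sv:
        if cell.sum() > 0:
            assert cell.max() / cell.sum() > 0.99


def test_hog_degenerate_bbox_rejected(rng):
    img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    with pytest.raises(ValueError):
        hog_features(img, (4, 10, 4, 20))


# -------------------------------------------------------------- wavelet
def test_wavelet_length_and_constant_image():
    vec = wavelet_features(np.full((64, 64), 9, dtype=np.uint8))
    assert vec.shape == (32,)
    names = [f"{band}_{stat}" for band in
             ("ll1", "lh1", "hl1", "hh1", "ll2", "lh2", "hl2", "hh2")
             for stat in ("meanabs", "entropy", "energy", "sum")]
    d = dict(zip(names, vec))
    # level-1 approximation of a constant c: every coefficient is 2c
    # (db4 lowpass gain sqrt(2) per axis), so the sum is 2*c*H*W/4.
    assert d["ll1_sum"] == pytest.approx(2 * 9 * 64 * 64 / 4, rel=1e-9)
    for band in ("lh1", "hl1", "hh1", "lh2", "hl2", "hh2"):
        for stat in ("meanabs", "entropy", "energy"):
            assert d[f"{band}_{stat}"] == pytest.approx(0.0, abs=1e-8)


def test_wavelet_parseval(rng):
    img = rng.normal(0, 1, (64, 64))
    vec = wavelet_features(img)
    energy_idx = [4 * i + 2 for i in range(8)]          # per-subband energies
    energies = dict(zip(("ll1", "lh1", "hl1", "hh1", "ll2", "lh2", "hl2", "hh2"),
                        vec[energy_idx]))
    # ll1 splits into the four level-2 subbands; sum the leaves only.
    total = sum(energies[b] for b in ("lh1", "hl1", "hh1",
                                      "ll2", "lh2", "hl2", "hh2"))
    assert total == pytest.approx((img ** 2).sum(), rel=1e-6)


def test_wavelet_too_small_rejected():
    with pytest.raises(ValueError):
        wavelet_features(np.zeros((8, 8)))


# ---------------------------------------------------------------- color
def test_color_pure_red_roi():
    img = np.zeros((4, 4, 3), dtype=np.uint8)
    img[..., 0] = 255
    vec = color_features(img, np.ones((4, 4), dtype=bool))
    assert np.allclose(vec, [0, 0, 1, 0, 1, 0])


def test_color_grayscale_roi_zero_saturation(rng):
    g = rng.integers(1, 255, (6, 6)).astype(np.uint8)
    img = np.stack([g, g, g], axis=-1)
    vec = color_features(img, np.ones((6, 6), dtype=bool))
    assert vec[2] == pytest.approx(0.0)     # mean S
    assert vec[3] == pytest.approx(0.0)     # sd S


def test_color_vs_per_pixel_conversion_oracle(rng):
    import colorsys

    img = rng.integers(0, 256, (5, 5, 3)).astype(np.uint8)
    roi = rng.random((5, 5)) > 0.4
    hsv = np.array([colorsys.rgb_to_hsv(*(img[i, j] / 255.0))
                    for i in range(5) for j in range(5)
                    if roi[i, j]])
    ref = np.empty(6)
    ref[0::2] = hsv.mean(axis=0)
    ref[1::2] = hsv.std(axis=0)
    assert np.allclose(color_features(img, roi), ref, atol=1e-9)


def test_color_empty_roi_rejected(rng):
    img = rng.integers(0, 256, (4, 4, 3)).astype(np.uint8)
    with pytest.raises(ValueError):
        color_features(img, np.zeros((4, 4), dtype=bool))


# --------------------------------------------------------------- tamura
def test_tamura_constant_contrast_zero():
    vec = tamura_features(np.full((32, 32), 7, dtype=np.uint8))
    assert vec[1] == 0.0


def test_tamura_coarseness_ordering():
    def checker(cell, n=64):
        i, j = np.indices((n, n))
        return (((i // cell + j // cell) % 2) * 255).astype(np.uint8)

    coarse8 = tamura_features(checker(8))[0]
    coarse2 = tamura_features(checker(2))[0]
    assert coarse8 > coarse2


def test_tamura_directionality_ordering(rng):
    stripes = np.tile(((np.arange(64) // 4) % 2) * 255, (64, 1)).astype(np.uint8)
    noise = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    assert tamura_features(stripes)[2] > tamura_features(noise)[2]


def test_tamura_too_small_rejected():
    with pytest.raises(ValueError):
        tamura_features(np.zeros((16, 16), dtype=np.uint8))


# ----------------------------------------------------------------- laws
def test_laws_constant_zero_and_length():
    vec = laws_features(np.full((32, 32), 50.0))
    assert vec.shape == (6,)
    assert np.allclose(vec, 0.0)


def test_laws_vertical_edges_ordering():
    vert = np.tile(((np.arange(64) % 8) < 4) * 200.0, (64, 1))
    vec = laws_features(vert)
    l5e5, s5s5, r5r5 = vec[0], vec[4], vec[5]
    assert l5e5 > s5s5
    assert l5e5 > r5r5


def test_laws_too_small_rejected():
    with pytest.raises(ValueError):
        laws_features(np.zeros((10, 10)))


# ------------------------------------------------------------- assembly
def test_extract_all_schema(enhanced_roi):
    enhanced, roi = enhanced_roi
    vec = extract_all(enhanced, roi)
    assert vec.shape == (N_FEATURES,) == (115,)
    assert np.isfinite(vec).all()
    sizes = tuple(FAMILY_SIZES.values())
    assert sizes == (22, 10, 36, 32, 6, 3, 6)
    slices = family_slices()
    assert slices["texture"] == slice(0, 22)
    assert slices["lte"] == slice(109, 115)
    assert len(FEATURE_NAMES) == 115
    assert FEATURE_NAMES[0].startswith("F001_autocorrelation")
    assert FEATURE_NAMES[-1] == "F115_lte_r5r5"


def test_extract_all_deterministic(enhanced_roi):
    enhanced, roi = enhanced_roi
    assert (extract_all(enhanced, roi) == extract_all(enhanced, roi)).all()


def test_extract_all_family_error_labeled(cancer_scene):
    roi = np.zeros(cancer_scene.image.shape[:2], dtype=bool)
    roi[0, 0] = True    # one pixel: GLCM has no co-occurring pair
    with pytest.raises(FeatureError) as err:
        extract_all(cancer_scene.image, roi)
    assert err.value.family == "texture"


def test_class_signal_in_area_and_contrast():
    """Mean ROI area and GLCM contrast separate the two classes by at
    least one pooled SD (on ground-truth ROIs)."""
    from microbiopsy.featurebank import glcm, glcm_stats
    from microbiopsy.imageio import to_gray
    from microbiopsy.synthgen import generate_class_scene

    area = {"normal": [], "cancerous": []}
    contrast = {"normal": [], "cancerous": []}
    for seed in range(100):
        for label in area:
            sc = generate_class_scene(label, seed)
            per_nuc = np.bincount(sc.per_nucleus_labels.ravel())[1:]
            area[label].append(per_nuc.mean())
            g = glcm(to_gray(sc.image), sc.nucleus_mask)
            contrast[label].append(glcm_stats(g)[1])
    for coll in (area, contrast):
        a, b = np.array(coll["normal"]), np.array(coll["cancerous"])
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert abs(a.mean() - b.mean()) >= pooled


def test_build_feature_matrix_roundtrip(tmp_path):
    from microbiopsy.synthgen import generate_dataset

    generate_dataset(2, seed=6, out_dir=tmp_path)
    df = build_feature_matrix(tmp_path / "manifest.csv",
                              out_csv=tmp_path / "features.csv")
    assert df.shape == (4, 116)
    assert list(df.columns[:-1]) == list(FEATURE_NAMES)
    assert df.columns[-1] == "label"
    first = (tmp_path / "features.csv").read_bytes()
    build_feature_matrix(tmp_path / "manifest.csv",
                         out_csv=tmp_path / "features.csv")
    assert (tmp_path / "features.csv").read_bytes() == first
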