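"""Co-occurrence matrix construction and the 22 texture statistics."""

import numpy as np
import pytest

from microbiopsy.featurebank import Glcm, glcm, glcm_stats, quantize
from microbiopsy.featurebank.glcm import TEXTURE_NAMES


def stats_dict(g):
    return dict(zip(TEXTURE_NAMES, glcm_stats(g)))


def test_constant_roi_all_mass_on_diagonal():
    g = glcm(np.full((8, 8), 100, dtype=np.uint8), levels=4)
    assert g.p.sum() == pytest.approx(1.0)
    level = quantize(np.array([[100]]), 4)[0, 0]
    assert g.p[level, level] == pytest.approx(1.0)


def test_two_level_checkerboard_hand_count():
    """[[0,1],[0,1]] columns, offset (0,1): both pairs are (0,1); the
    symmetrized matrix is [[0,.5],[.5,0]] with contrast 1."""
    img = np.array([[0, 128], [0, 128]], dtype=np.uint8)
    g = glcm(img, levels=2, offsets=((0, 1),))
    assert np.allclose(g.p, [[0.0, 0.5], [0.5, 0.0]])
    st = stats_dict(g)
    assert st["contrast"] == pytest.approx(1.0)
    assert st["energy"] == pytest.approx(0.5)
    assert st["entropy"] == pytest.approx(1.0)


def test_against_double_loop_counting_oracle(rng):
    img = rng.integers(0, 256, (6, 6)).astype(np.uint8)
    roi = rng.random((6, 6)) > 0.3
    levels = 4
    offsets = ((0, 1), (1, 1))
    q = quantize(img, levels)
    acc = np.zeros((levels, levels))
    used = 0
    for dy, dx in offsets:
        counts = np.zeros((levels, levels))
        for y in range(6):
            for x in range(6):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < 6 and 0 <= x2 < 6 and roi[y, x] and roi[y2, x2]:
                    counts[q[y, x], q[y2, x2]] += 1
        if counts.sum() == 0:
            continue
        counts = counts + counts.T
        acc += counts / counts.sum()
        used += 1
    ours = glcm(img, roi, levels=levels, offsets=offsets)
    assert np.allclose(ours.p, acc / used, atol=1e-12)


def test_matches_skimage_graycomatrix(rng):
    """Independent library cross-check on a full ROI, single offset."""
    from skimage.feature import graycomatrix

    img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
    q = quantize(img, 8).astype(np.uint8)
    ours = glcm(img, levels=8, offsets=((0, 1),)).p
    ref = graycomatrix(q, [1], [0], levels=8, symmetric=True,
                       normed=True)[:, :, 0, 0]
    assert np.allclose(ours, ref, atol=1e-12)


def test_roi_too_small_rejected():
    roi = np.zeros((6, 6), dtype=bool)
    roi[2, 2] = True        # one pixel: no pair at any offset
    with pytest.raises(ValueError):
        glcm(np.zeros((6, 6), dtype=np.uint8), roi)


def test_degenerate_distribution_stats():
    g = glcm(np.full((8, 8), 10, dtype=np.uint8), levels=8)
    st = stats_dict(g)
    assert st["energy"] == pytest.approx(1.0)
    assert st["entropy"] == pytest.approx(0.0)
    assert st["contrast"] == pytest.approx(0.0)
    assert st["maximum_probability"] == pytest.approx(1.0)
    assert st["homogeneity"] == pytest.approx(1.0)


def _oracle_stats(p):
    """Independent direct-summation formulas (explicit loops)."""
    L = p.shape[0]
    out = {}
    idx = np.arange(1, L + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx = sum(i * px[i - 1] for i in idx)
    my = sum(j * py[j - 1] for j in idx)
    sx = np.sqrt(sum((i - mx) ** 2 * px[i - 1] for i in idx))
    sy = np.sqrt(sum((j - my) ** 2 * py[j - 1] for j in idx))
    out["autocorrelation"] = sum(i * j * p[i - 1, j - 1] for i in idx for j in idx)
    out["contrast"] = sum((i - j) ** 2 * p[i - 1, j - 1] for i in idx for j in idx)
    corr = sum((i - mx) * (j - my) * p[i - 1, j - 1] for i in idx for j in idx)
    out["correlation"] = corr / (sx * sy)
    out["correlation2"] = corr / (sx * sy)
    out["cluster_prominence"] = sum((i + j - mx - my) ** 4 * p[i - 1, j - 1]
                                    for i in idx for j in idx)
    out["cluster_shade"] = sum((i + j - mx - my) ** 3 * p[i - 1, j - 1]
                               for i in idx for j in idx)
    out["dissimilarity"] = sum(abs(i - j) * p[i - 1, j - 1]
                               for i in idx for j in idx)
    out["energy"] = (p ** 2).sum()
    out["entropy"] = -sum(v * np.log2(v) for v in p.ravel() if v > 0)
    out["homogeneity"] = sum(p[i - 1, j - 1] / (1 + (i - j) ** 2)
                             for i in idx for j in idx)
    out["maximum_probability"] = p.max()
    out["sum_of_squares"] = sum((i - mx) ** 2 * p[i - 1, j - 1]
                                for i in idx for j in idx)
    psum = {k: 0.0 for k in range(2, 2 * L + 1)}
    pdiff = {k: 0.0 for k in range(L)}
    for i in idx:
        for j in idx:
            psum[i + j] += p[i - 1, j - 1]
            pdiff[abs(i - j)] += p[i - 1, j - 1]
    out["sum_average"] = sum(k * v for k, v in psum.items())
    out["sum_variance"] = sum((k - out["sum_average"]) ** 2 * v
                              for k, v in psum.items())
    out["sum_entropy"] = -sum(v * np.log2(v) for v in psum.values() if v > 0)
    out["difference_entropy"] = -sum(v * np.log2(v) for v in pdiff.values() if v > 0)
    dmean = sum(k * v for k, v in pdiff.items())
    out["difference_variance"] = sum((k - dmean) ** 2 * v
                                     for k, v in pdiff.items())
    hxy = out["entropy"]
    hxy1 = -sum(p[i - 1, j - 1] * np.log2(px[i - 1] * py[j - 1])
                for i in idx for j in idx if p[i - 1, j - 1] > 0)
    hxy2 = -sum(px[i - 1] * py[j - 1] * np.log2(px[i - 1] * py[j - 1])
                for i in idx for j in idx if px[i - 1] * py[j - 1] > 0)
    hx = -sum(v * np.log2(v) for v in px if v > 0)
    hy = -sum(v * np.log2(v) for v in py if v > 0)
    out["imc1"] = (hxy - hxy1) / max(hx, hy)
    out["imc2"] = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    out["inverse_difference"] = sum(p[i - 1, j - 1] / (1 + abs(i - j))
                                    for i in idx for j in idx)
    out["inverse_difference_normalized"] = sum(
        p[i - 1, j - 1] / (1 + abs(i - j) / L) for i in idx for j in idx)
    out["inverse_difference_moment_normalized"] = sum(
        p[i - 1, j - 1] / (1 + (i - j) ** 2 / L ** 2) for i in idx for j in idx)
    return out


def test_all_22_stats_vs_formula_oracle(rng):
    for _ in range(5):
        raw = rng.random((4, 4))
        p = raw + raw.T
        p /= p.sum()
        ours = stats_dict(Glcm(p=p, offsets=((0, 1),), levels=4))
        ref = _oracle_stats(p)
        assert set(ours) == set(ref)
        for name in ref:
            assert ours[name] == pytest.approx(ref[name], abs=1e-10), name


def test_texture_schema_has_22_names():
    assert len(TEXTURE_NAMES) == 22
    assert len(set(TEXTURE_NAMES)) == 22
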