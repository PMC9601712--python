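"""Color moments, HSV means, PCA images and mask-aware GLCM texture."""

import warnings

import numpy as np
import pytest
from skimage.feature import graycomatrix

from hsidry.hsi_calibration import HyperCube, RoiMask
from hsidry.image_features import (FEATURE_NAMES, _glcm_stats, color_moments,
                                   extract_image_features, glcm_features,
                                   glcm_matrix, hsv_means, pca_images,
                                   synthesize_rgb, _quantize, _ANGLES)

WL = np.linspace(400, 1000, 224)


def _cube(data):
    return HyperCube(data=np.asarray(data, float), wavelengths=WL, state="corrected")


def full_roi(shape):
    return RoiMask(np.ones(shape, dtype=bool))


# ------------------------------------------------------------------ RGB

def test_rgb_constant_cube_is_uniform_gray():
    rgb = synthesize_rgb(_cube(np.full((4, 5, 224), 0.5)))
    np.testing.assert_allclose(rgb, 0.5)


def test_rgb_uses_nearest_bands():
    data = np.zeros((2, 2, 224))
    idx = {nm: int(np.argmin(np.abs(WL - nm))) for nm in (647.0, 550.0, 460.0)}
    for k, nm in enumerate((647.0, 550.0, 460.0)):
        data[:, :, idx[nm]] = 0.1 * (k + 1)
    rgb = synthesize_rgb(_cube(data))
    np.testing.assert_allclose(rgb[0, 0], [0.1, 0.2, 0.3])


def test_rgb_band_swap_swaps_channels(rng):
    data = rng.random((3, 4, 224))
    cube = _cube(data)
    i_r = cube.band_index(647.0)
    i_b = cube.band_index(460.0)
    swapped = data.copy()
    swapped[:, :, [i_r, i_b]] = swapped[:, :, [i_b, i_r]]
    a = synthesize_rgb(cube)
    b = synthesize_rgb(_cube(swapped))
    np.testing.assert_allclose(a[..., 0], b[..., 2])
    np.testing.assert_allclose(a[..., 2], b[..., 0])


def test_rgb_requires_visible_coverage():
    cube = HyperCube(data=np.zeros((2, 2, 10)),
                     wavelengths=np.linspace(700, 1000, 10), state="corrected")
    with pytest.raises(ValueError):
        synthesize_rgb(cube)


# ------------------------------------------------------------------ color moments / HSV

def test_color_moments_uniform_and_two_pixel():
    rgb = np.full((3, 3, 3), 0.4)
    first, second = color_moments(rgb, full_roi((3, 3)))
    np.testing.assert_allclose(first, 0.4)
    np.testing.assert_allclose(second, 0.0, atol=1e-12)

    rgb2 = np.zeros((2, 1, 3))
    rgb2[1, 0] = 1.0
    first, second = color_moments(rgb2, full_roi((2, 1)))
    np.testing.assert_allclose(first, 0.5)
    np.testing.assert_allclose(second, 0.5)  # population sd convention


def test_color_moments_equal_brute_force(rng):
    rgb = rng.random((6, 7, 3))
    mask = rng.random((6, 7)) > 0.4
    first, second = color_moments(rgb, RoiMask(mask))
    pix = [rgb[i, j] for i in range(6) for j in range(7) if mask[i, j]]
    pix = np.array(pix)
    np.testing.assert_allclose(first, pix.mean(axis=0), atol=1e-12)
    np.testing.assert_allclose(second, pix.std(axis=0), atol=1e-12)


@pytest.mark.parametrize("color,expected", [
    ((1.0, 0.0, 0.0), (0.0, 1.0, 1.0)),     # pure red
    ((0.3, 0.3, 0.3), (0.0, 0.0, 0.3)),     # gray: zero saturation
    ((0.0, 1.0, 0.0), (1 / 3, 1.0, 1.0)),   # pure green hue
])
def test_hsv_reference_colors(color, expected):
    rgb = np.tile(np.array(color), (2, 2, 1))
    np.testing.assert_allclose(hsv_means(rgb, full_roi((2, 2))), expected, atol=1e-12)


# ------------------------------------------------------------------ PCA images

def test_pca_rank_one_cube():
    spatial = np.outer(np.linspace(1, 2, 6), np.linspace(1, 3, 5))
    loading = np.linspace(0.2, 1.0, 224)
    cube = _cube(spatial[:, :, None] * loading[None, None, :])
    pcs = pca_images(cube, full_roi((6, 5)), n_components=3)
    assert pcs.explained_fraction[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_scores_orthogonal_and_match_eigendecomposition(rng):
    cube = _cube(rng.random((8, 9, 224)))
    roi = full_roi((8, 9))
    pcs = pca_images(cube, roi, n_components=3)
    scores = np.stack([img[roi.mask] for img in pcs.pc_images])
    gram = scores @ scores.T
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8 * np.diag(gram).max()

    pix = cube.data[roi.mask]
    cov = np.cov(pix, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(pcs.explained_fraction, eig[:3] / eig.sum(), atol=1e-10)


def test_pca_degenerate_errors():
    with pytest.raises(ValueError):
        pca_images(_cube(np.full((4, 4, 224), 0.3)), full_roi((4, 4)))


# ------------------------------------------------------------------ GLCM

def test_glcm_constant_image():
    img = np.full((6, 6), 2.0)
    roi = full_roi((6, 6))
    with pytest.raises(ValueError):
        glcm_features(img, roi, levels=8, strict=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tex = glcm_features(img, roi, levels=8, strict=False)
    assert tex.contrast == pytest.approx(0.0)
    assert tex.energy == pytest.approx(1.0)
    assert tex.homogeneity == pytest.approx(1.0)
    assert tex.correlation == 0.0


def test_glcm_checkerboard_horizontal():
    board = np.indices((4, 4)).sum(axis=0) % 2
    roi = full_roi((4, 4))
    q = _quantize(board.astype(float), roi, 2)
    p = glcm_matrix(q, roi, 2, (0, 1))
    contrast, corr, energy, homog = _glcm_stats(p, strict=True)
    assert contrast == pytest.approx(1.0)
    assert energy == pytest.approx(0.5)
    assert corr == pytest.approx(-1.0)


def _brute_glcm_stats(img, mask, levels):
    """Exhaustive pair enumeration over all pixels and the four orientations."""
    lo, hi = img[mask].min(), img[mask].max()
    q = np.clip(np.floor((img - lo) / (hi - lo) * levels), 0, levels - 1).astype(int)
    rows, cols = img.shape
    stats = []
    for dr, dc in _ANGLES:
        counts = np.zeros((levels, levels))
        for i in range(rows):
            for j in range(cols):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < rows and 0 <= j2 < cols and mask[i, j] and mask[i2, j2]:
                    counts[q[i, j], q[i2, j2]] += 1
        counts = counts + counts.T
        p = counts / counts.sum()
        stats.append(_glcm_stats(p, strict=True))
    return np.mean(stats, axis=0)


def test_glcm_features_equal_brute_force(rng):
    img = rng.random((12, 14))
    mask = rng.random((12, 14)) > 0.3
    tex = glcm_features(img, RoiMask(mask), levels=8)
    expected = _brute_glcm_stats(img, mask, 8)
    np.testing.assert_allclose(
        [tex.contrast, tex.correlation, tex.energy, tex.homogeneity],
        expected, atol=1e-12)


def test_glcm_matches_skimage_on_rectangular_roi(rng):
    img = rng.random((16, 16))
    roi = full_roi((16, 16))
    levels = 8
    q = _quantize(img, roi, levels)
    # skimage pairs our (-1,1) offset with its 135-degree angle and vice versa
    for (dr, dc), angle in zip(_ANGLES, (0, 3 * np.pi / 4, np.pi / 2, np.pi / 4)):
        mine = glcm_matrix(q, roi, levels, (dr, dc))
        ref = graycomatrix(q.astype(np.uint8), [1], [angle], levels=levels,
                           symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(mine, ref, atol=1e-12)


def test_glcm_offset_invariance(rng):
    img = rng.random((10, 10))
    mask = rng.random((10, 10)) > 0.2
    a = glcm_features(img, RoiMask(mask), levels=16)
    b = glcm_features(img + 5.0, RoiMask(mask), levels=16)
    np.testing.assert_allclose(
        [a.contrast, a.correlation, a.energy, a.homogeneity],
        [b.contrast, b.correlation, b.energy, b.homogeneity], atol=1e-12)


def test_glcm_energy_bounds(rng):
    img = rng.random((9, 9))
    tex = glcm_features(img, full_roi((9, 9)), levels=8)
    assert 0 < tex.energy <= 1
    assert 0 < tex.homogeneity <= 1
    assert -1 <= tex.correlation <= 1
    assert tex.contrast >= 0


# ------------------------------------------------------------------ full vector

def test_feature_vector_layout_and_composition(one_sample):
    _, cube, roi = one_sample
    vec = extract_image_features(cube, roi)
    assert vec.shape == (13,)
    assert len(FEATURE_NAMES) == 13

    rgb = synthesize_rgb(cube, roi)
    first, second = color_moments(rgb, roi)
    hsv = hsv_means(rgb, roi)
    pcs = pca_images(cube, roi, n_components=3)
    tex = np.mean([[t.contrast, t.correlation, t.energy, t.homogeneity]
                   for t in (glcm_features(img, roi, strict=False)
                             for img in pcs.pc_images)], axis=0)
    np.testing.assert_allclose(vec, [*first, *second, *hsv, *tex], atol=1e-12)


def test_feature_vector_uniform_cube_degenerate_path():
    cube = _cube(np.full((8, 10, 224), 0.3))
    roi = full_roi((8, 10))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vec = extract_image_features(cube, roi)
    assert vec.shape == (13,)
    np.testing.assert_allclose(vec[9:], [0.0, 0.0, 1.0, 1.0])  # texture slots
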