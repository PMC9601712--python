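"""Color and texture features from hyperspectral cubes.

Thirteen image features per sample: RGB first-order moments (channel means
over the ROI) and second-order moments (population standard deviations),
mean H, S, V after RGB->HSV conversion, and four gray-level co-occurrence
matrix (GLCM) statistics — contrast, correlation, energy, homogeneity — at
pixel distance 1, averaged over the 0/45/90/135 degree orientations and over
the top three principal-component images of the cube.

The GLCM here is mask-aware: a pixel pair contributes only when both pixels
lie inside the ROI, which a rectangular-image co-occurrence routine cannot
express; the matrix is symmetrized and normalized before the statistics are
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from sklearn.decomposition import PCA

from .hsi_calibration import HyperCube, RoiMask

RGB_TARGET_NM = (647.0, 550.0, 460.0)

FEATURE_NAMES = (
    "mom1_R", "mom1_G", "mom1_B",
    "mom2_R", "mom2_G", "mom2_B",
    "hsv_H", "hsv_S", "hsv_V",
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
)

_ANGLES = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees as (drow, dcol)


@dataclass
class ColorFeatures:
    first_moments: tuple[float, float, float]
    second_moments: tuple[float, float, float]
    hsv_means: tuple[float, float, float]


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float


@dataclass
class PcImageSet:
    pc_images: np.ndarray          # (n_components, rows, cols), background 0
    explained_fraction: np.ndarray
    cumulative: float


def synthesize_rgb(cube: HyperCube, roi: RoiMask | None = None) -> np.ndarray:
    """RGB image from the bands nearest 647/550/460 nm, clipped to [0, 1]."""
    if cube.wavelengths[0] > min(RGB_TARGET_NM) or cube.wavelengths[-1] < max(RGB_TARGET_NM):
        raise ValueError("cube wavelength axis does not cover 460-647 nm")
    idx = [cube.band_index(nm) for nm in RGB_TARGET_NM]
    rgb = np.stack([cube.data[:, :, i] for i in idx], axis=-1).astype(float)
    return np.clip(rgb, 0.0, 1.0)


def color_moments(rgb: np.ndarray, roi: RoiMask) -> tuple[tuple, tuple]:
    """Per-channel ROI mean (first moment) and population sd (second moment)."""
    pix = np.asarray(rgb, dtype=float)[roi.mask]  # (n, 3)
    first = tuple(pix.mean(axis=0))
    second = tuple(pix.std(axis=0, ddof=0))
    return first, second


def hsv_means(rgb: np.ndarray, roi: RoiMask) -> tuple[float, float, float]:
    """Arithmetic ROI means of H, S, V; hue is on the [0, 1) scale."""
    pix = np.asarray(rgb, dtype=float)[roi.mask][None, :, :]
    hsv = rgb2hsv(pix)[0]
    return tuple(hsv.mean(axis=0))


def pca_images(cube: HyperCube, roi: RoiMask, n_components: int = 3) -> PcImageSet:
    """PCA with ROI pixels as observations and bands as variables.

    Scores are placed back at their pixel locations (background 0); explained
    variance fractions come with the images.
    """
    pix = cube.data[roi.mask, :].astype(float)
    if pix.shape[0] < n_components or cube.n_bands < n_components:
        raise ValueError("too few pixels or bands for the requested components")
    if np.allclose(pix, pix[0]):
        raise ValueError("degenerate cube: all ROI pixels identical")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(pix - pix.mean(axis=0))
    images = np.zeros((n_components, *roi.mask.shape))
    for k in range(n_components):
        images[k][roi.mask] = scores[:, k]
    frac = pca.explained_variance_ratio_
    return PcImageSet(pc_images=images, explained_fraction=frac,
                      cumulative=float(frac.sum()))


def _quantize(image: np.ndarray, roi: RoiMask, levels: int) -> np.ndarray:
    vals = np.asarray(image, dtype=float)
    lo = vals[roi.mask].min()
    hi = vals[roi.mask].max()
    if hi == lo:
        return np.zeros_like(vals, dtype=np.int64)
    q = np.floor((vals - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm_matrix(q: np.ndarray, roi: RoiMask, levels: int, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one (drow, dcol) offset.

    Only pairs with both pixels inside the ROI are counted.
    """
    dr, dc = offset
    rows, cols = q.shape
    r0s, r0e = max(0, -dr), min(rows, rows - dr)
    c0s, c0e = max(0, -dc), min(cols, cols - dc)
    a = q[r0s:r0e, c0s:c0e]
    b = q[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = roi.mask[r0s:r0e, c0s:c0e] & roi.mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    if not valid.any():
        raise ValueError("ROI too small: no pixel pair at this offset")
    pairs = a[valid] * levels + b[valid]
    counts = np.bincount(pairs, minlength=levels * levels).reshape(levels, levels).astype(float)
    counts = counts + counts.T  # symmetrize
    return counts / counts.sum()


def _glcm_stats(p: np.ndarray, strict: bool) -> tuple[float, float, float, float]:
    levels = p.shape[0]
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    energy = float((p ** 2).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    pi = p.sum(axis=1)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    if var == 0:
        if strict:
            raise ValueError("single gray level: GLCM correlation undefined")
        warnings.warn("single gray level: GLCM correlation reported as 0")
        correlation = 0.0
    else:
        correlation = float((p * (ii - mu) * (jj - mu)).sum() / var)
    return contrast, correlation, energy, homogeneity


def glcm_features(image: np.ndarray, roi: RoiMask, levels: int = 64,
                  distance: int = 1, strict: bool = True) -> TextureFeatures:
    """Contrast/correlation/energy/homogeneity averaged over four orientations.

    The image is quantized to ``levels`` gray levels over the ROI min-max
    range.  A constant image has undefined correlation: an error in direct
    calls, a warning + 0 when ``strict`` is off (batch extraction).
    """
    q = _quantize(image, roi, levels)
    stats = []
    for dr, dc in _ANGLES:
        p = glcm_matrix(q, roi, levels, (dr * distance, dc * distance))
        stats.append(_glcm_stats(p, strict))
    c, r, e, h = np.mean(stats, axis=0)
    return TextureFeatures(contrast=float(c), correlation=float(r),
                           energy=float(e), homogeneity=float(h))


def extract_image_features(cube: HyperCube, roi: RoiMask,
                           levels: int = 64) -> np.ndarray:
    """The 13-feature vector: [6 color moments, 3 HSV means, 4 GLCM stats].

    Texture statistics are averaged over the four orientations and over the
    top three principal-component images.  Ordering follows FEATURE_NAMES.
    """
    rgb = synthesize_rgb(cube, roi)
    first, second = color_moments(rgb, roi)
    hsv = hsv_means(rgb, roi)
    try:
        images = pca_images(cube, roi, n_components=3).pc_images
    except ValueError:
        # degenerate (constant) cube: fall back to the gray plane itself
        warnings.warn("degenerate cube: texture computed on a single gray plane")
        images = cube.data[:, :, cube.band_index(550.0)][None, :, :]
    tex = np.mean(
        [
            [t.contrast, t.correlation, t.energy, t.homogeneity]
            for t in (glcm_features(img, roi, levels=levels, strict=False)
                      for img in images)
        ],
        axis=0,
    )
    return np.array([*first, *second, *hsv, *tex], dtype=float)
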