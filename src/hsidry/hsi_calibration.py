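"""Reflectance calibration, ROI segmentation and mean-spectrum extraction.

Raw pushbroom digital numbers are converted to relative reflectance with the
standard black/white correction

    R = (R_o - R_d) / (R_w - R_d)

against a whiteboard and a dark-current frame.  The region of interest (the
shrimp body, excluding head and tail) is found automatically by Otsu
thresholding at a visible band followed by largest-connected-component
selection and a configurable end trim, and per-band mean spectra are averaged
over the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label


@dataclass
class HyperCube:
    """A (rows, cols, bands) reflectance or raw-DN cube with a wavelength axis.

    ``invalid`` marks pixel/band cells where calibration was impossible
    (white == dark); those cells hold 0 and are excluded from statistics.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    state: str = "raw"  # "raw" | "corrected"
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bands)")
        if self.wavelengths.shape != (self.data.shape[2],):
            raise ValueError("wavelength axis length must equal band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.state not in ("raw", "corrected"):
            raise ValueError(f"unknown cube state {self.state!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, nm: float) -> int:
        """Index of the band whose center wavelength is nearest ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))


@dataclass
class RoiMask:
    """Boolean foreground mask over the spatial grid."""

    mask: np.ndarray
    n_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.n_pixels = int(self.mask.sum())
        if self.n_pixels == 0:
            raise ValueError("empty ROI mask")


def reflectance_correct(raw: HyperCube, white: np.ndarray, dark: np.ndarray) -> HyperCube:
    """Black/white correction of a raw cube.

    ``white`` and ``dark`` may be full (rows, cols, bands) frames, per-column
    (cols, bands) scan lines as produced by a pushbroom instrument, or
    per-band (bands,) vectors; anything broadcastable to the cube shape.
    Cells where white equals dark are flagged invalid (value 0, recorded in
    ``HyperCube.invalid``) instead of silently propagating NaN.
    """
    if raw.state != "raw":
        raise ValueError("cube is already corrected")
    white = np.broadcast_to(np.asarray(white, dtype=float), raw.data.shape)
    dark = np.broadcast_to(np.asarray(dark, dtype=float), raw.data.shape)

    denom = white - dark
    invalid = denom == 0
    safe = np.where(invalid, 1.0, denom)
    corrected = (raw.data - dark) / safe
    corrected = np.where(invalid, 0.0, corrected)
    return HyperCube(
        data=corrected.astype(np.float32, copy=False),
        wavelengths=raw.wavelengths,
        state="corrected",
        invalid=invalid if invalid.any() else None,
    )


def segment_roi(
    cube: HyperCube,
    band_nm: float = 550.0,
    threshold_method: str | float = "otsu",
    trim_fraction: float = 0.15,
) -> RoiMask:
    """Segment the bright foreground at one band and trim the object ends.

    Otsu (or a fixed threshold) at the band nearest ``band_nm``, keep the
    largest connected component, then remove ``trim_fraction`` of the
    object's extent along its longer axis at each end — a deterministic
    stand-in for manual head/tail exclusion.
    """
    if cube.state != "corrected":
        raise ValueError("segmentation requires a corrected cube")
    plane = np.asarray(cube.data[:, :, cube.band_index(band_nm)], dtype=float)
    if cube.invalid is not None:
        plane = np.where(cube.invalid[:, :, cube.band_index(band_nm)], 0.0, plane)

    if threshold_method == "otsu":
        thr = threshold_otsu(plane)
    else:
        thr = float(threshold_method)
    fg = plane > thr
    if not fg.any():
        raise ValueError("empty foreground: no pixel above threshold")

    labels = label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))

    if trim_fraction > 0:
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        # trim along the longer spatial extent (the shrimp's body axis)
        if cols.size >= rows.size:
            lo, hi = cols[0], cols[-1]
            cut = int(round(trim_fraction * (hi - lo + 1)))
            mask[:, : lo + cut] = False
            mask[:, hi - cut + 1 :] = False
        else:
            lo, hi = rows[0], rows[-1]
            cut = int(round(trim_fraction * (hi - lo + 1)))
            mask[: lo + cut, :] = False
            mask[hi - cut + 1 :, :] = False
    if not mask.any():
        raise ValueError("trim removed the whole foreground")
    return RoiMask(mask=mask)


def mean_spectrum(cube: HyperCube, roi: RoiMask) -> np.ndarray:
    """Per-band arithmetic mean of reflectance over the ROI pixels.

    Invalid (white == dark) cells are excluded band-wise from the average.
    """
    if cube.state != "corrected":
        raise ValueError("mean spectrum requires a corrected cube")
    if roi.mask.shape != cube.data.shape[:2]:
        raise ValueError("ROI shape does not match cube spatial grid")
    pix = cube.data[roi.mask, :].astype(np.float64)  # (n_pixels, bands)
    if cube.invalid is None:
        return pix.mean(axis=0)
    ok = ~cube.invalid[roi.mask, :]
    n_ok = ok.sum(axis=0)
    if np.any(n_ok == 0):
        raise ValueError("some band has no valid ROI pixel")
    return (pix * ok).sum(axis=0) / n_ok
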