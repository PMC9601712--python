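"""Spectral preprocessing: Savitzky-Golay smoothing and the standard normal
variate (SNV) transform.

SNV standardizes each spectrum to zero mean and unit standard deviation
(n-1 denominator), removing multiplicative scatter and additive baseline
offsets.  Savitzky-Golay smoothing is a local least-squares polynomial fit;
edges are handled by re-evaluating the edge polynomial so the length is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter


@dataclass
class PreprocessConfig:
    """Which transforms to apply to mean spectra, and in what shape.

    Savitzky-Golay is applied before SNV when both are enabled.
    """

    sg_window: int = 11
    sg_polyorder: int = 2
    apply_sg: bool = True
    apply_snv: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")


def savitzky_golay(spectrum: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Least-squares local polynomial smoothing, length preserving.

    Works on a single spectrum or row-wise on a (samples, bands) matrix.
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than the smoothing window")
    return savgol_filter(x, window_length=window, polyorder=polyorder, mode="interp", axis=-1)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate transform: (x - mean) / sd with ddof=1.

    Accepts a single spectrum or a (samples, bands) matrix (row-wise).
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs at least two points per spectrum")
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined (zero standard deviation)")
    return (x - mu) / sd


def preprocess(spectra: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Apply the configured transforms (SG first, then SNV) row-wise."""
    cfg = config or PreprocessConfig()
    out = np.asarray(spectra, dtype=float)
    if cfg.apply_sg:
        out = savitzky_golay(out, cfg.sg_window, cfg.sg_polyorder)
    if cfg.apply_snv:
        out = snv(out)
    return out
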