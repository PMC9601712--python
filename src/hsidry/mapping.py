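"""Pixel-wise quality maps: apply a fitted spectral model to every ROI pixel.

Each ROI pixel's spectrum is pushed through the same preprocessing the model
was trained on (per-pixel Savitzky-Golay and, when enabled, per-pixel SNV)
and scored, giving a spatial distribution of the predicted indicator.  The
rendered pseudo-color map uses a linear blue (low) to red (high) scale;
display clipping at the 1st/99th percentile never alters the stored values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .hsi_calibration import HyperCube, RoiMask
from .spectral_preprocess import PreprocessConfig, preprocess


@dataclass
class QualityMap:
    """Predicted indicator values over the ROI; NaN outside (never a prediction)."""

    values: np.ndarray
    indicator: str
    value_range: tuple[float, float]
    clip_range: tuple[float, float]

    def roi_stats(self) -> dict:
        v = self.values[np.isfinite(self.values)]
        return {"min": float(v.min()), "mean": float(v.mean()), "max": float(v.max())}


def predict_map(cube: HyperCube, roi: RoiMask, model,
                preprocess_config: PreprocessConfig | None = None,
                indicator: str = "", band_indices: np.ndarray | None = None) -> QualityMap:
    """Score every ROI pixel spectrum with a fitted spectral model.

    The model must expose ``predict`` over the same (preprocessed) wavelength
    axis it was trained on; for a characteristic-wavelength model pass the
    selected ``band_indices`` (applied after preprocessing, as in training).
    Fusion models cannot be applied per pixel (image features are
    per-sample), so callers map their spectral-only sibling.
    """
    if cube.state != "corrected":
        raise ValueError("pixel-wise mapping requires a corrected cube")
    spectra = cube.data[roi.mask, :].astype(float)
    feats = preprocess(spectra, preprocess_config)
    if band_indices is not None:
        feats = feats[:, np.asarray(band_indices, dtype=int)]
    n_model = getattr(model, "x_mean", getattr(model, "X_train", np.empty((0, feats.shape[1]))))
    n_features = n_model.shape[-1]
    if n_features != feats.shape[1]:
        raise ValueError(
            f"wavelength-axis mismatch: cube yields {feats.shape[1]} features, "
            f"model expects {n_features}")
    pred = np.asarray(model.predict(feats), dtype=float).ravel()

    values = np.full(roi.mask.shape, np.nan)
    values[roi.mask] = pred
    lo, hi = np.percentile(pred, [1, 99])
    return QualityMap(values=values, indicator=indicator,
                      value_range=(float(pred.min()), float(pred.max())),
                      clip_range=(float(lo), float(hi)))


def render_map(qmap: QualityMap, out_path: str | Path,
               values_path: str | Path | None = None) -> Path:
    """Render a PNG with a linear blue-to-red colorbar; optionally store values.

    The stored CSV keeps unclipped predictions (NaN sentinel outside ROI);
    clipping affects hues only.
    """
    out_path = Path(out_path)
    lo, hi = qmap.clip_range
    degenerate = not (hi > lo)
    if degenerate:
        lo, hi = lo - 0.5, hi + 0.5

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(qmap.values, cmap="jet", vmin=lo, vmax=hi)
    ax.set_title(qmap.indicator or "predicted value")
    ax.axis("off")
    label = f"range [{qmap.value_range[0]:.3g}, {qmap.value_range[1]:.3g}]"
    if degenerate:
        label += " (uniform)"
    fig.colorbar(im, ax=ax, label=label)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)

    if values_path is not None:
        np.savetxt(values_path, qmap.values, delimiter=",")
    return out_path
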