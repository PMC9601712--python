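"""Synthetic study generator: hyperspectral cubes, CPMG decays and quality tables.

Emulates a hot-air shrimp-drying study design of 13 drying levels x 8
replicates = 104 samples.  Each sample carries

* a raw-DN pushbroom cube (rows x cols x 224 bands over 400-1000 nm) with a
  per-column white/dark reference pair, an elliptical "shrimp" foreground on
  a dark background and a brighter head region,
* a CPMG echo train built from a per-level tri-exponential truth (bound /
  immobilized / free water pools, the free pool vanishing late in drying),
* a reference quality record (moisture %, L*, a*, b*, dE, hardness,
  adhesiveness, elasticity, stickiness, chewiness).

The reflectance model is a smooth curved baseline minus Gaussian absorption
features: a carotenoid (astaxanthin) band near 480 nm whose depth is affine
in the sample's a* value, a water band near 960 nm whose depth is affine in
moisture (with a mild left-to-right spatial gradient), and two secondary
pigment nuisance bands (455/530 nm) that confound 3-band color readouts but
are separable at full spectral resolution.  The baseline slope carries the
sample's L* deviation, so spectra and quality are linked by construction and
parameter recovery is testable.  ``noise_sd`` is the master noise switch: at
0 every stochastic component (pixel noise, scatter, pigment nuisances, depth
jitter, replicate scatter, decay noise) is disabled and the generator is
fully deterministic per level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .envi import write_envi
from .hsi_calibration import HyperCube
from .nmr_relaxometry import CPMGDecay
from .reference_quality import QualityRecord, delta_e

# Level anchors: drying level 0 (fresh), 1 (just boiled), 12 (drying endpoint);
# elasticity additionally peaks at level 7.  (mean, sd) per anchor.
QUALITY_ANCHORS: dict[str, tuple[list[float], list[float], list[float]]] = {
    #            anchor levels   anchor means                anchor sds
    "moisture":   ([0, 1, 12], [75.87, 73.02, 35.02], [1.2, 1.2, 1.2]),
    "L":          ([0, 1, 12], [40.71, 63.85, 59.58], [1.22, 1.22, 0.79]),
    "a":          ([0, 1, 12], [1.22, 23.38, 16.08], [0.55, 2.30, 1.31]),
    "b":          ([0, 1, 12], [3.08, 29.03, 20.25], [1.39, 2.46, 2.42]),
    "hardness":   ([0, 1, 12], [127.96, 144.26, 344.78], [15.44, 16.24, 44.22]),
    "adhesiveness": ([0, 1, 12], [1.90, 1.48, 0.20], [0.31, 0.17, 0.02]),
    "elasticity": ([0, 1, 7, 12], [0.83, 1.96, 2.09, 1.56], [0.13, 0.23, 0.20, 0.35]),
    "stickiness": ([0, 1, 12], [2.84, 12.23, 45.01], [0.58, 1.99, 9.78]),
    "chewiness":  ([0, 1, 12], [2.38, 24.37, 116.50], [0.74, 6.85, 34.33]),
}

FRESH_LAB = (40.71, 1.22, 3.08)

# tri-exponential relaxation truth across drying: pool times shrink, the free
# pool (T23) empties for levels past 9
_T21_RANGE = (3.05, 1.52)
_T22_RANGE = (28.48, 14.17)
_T23_RANGE = (320.0, 140.0)
_BOUND_FRACTION = 0.10
_FREE_FRACTION_FRESH = 0.30


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters for the synthetic generator."""

    n_levels: int = 13
    n_replicates: int = 8
    n_bands: int = 224
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    image_shape: tuple[int, int] = (64, 96)
    moisture_fresh: float = 75.87
    moisture_end: float = 35.02
    astaxanthin_center: float = 480.0
    water_center: float = 960.0
    t2_components: list | None = None   # per-level [(T2 ms, amplitude fraction) x 3]
    noise_sd: float = 0.01              # pixel reflectance noise; 0 = deterministic
    scatter_sd: float = 0.04            # per-sample multiplicative scatter
    depth_jitter_sd: float = 0.0015     # nuisance on absorption depths
    pigment_nuisance_sd: float = 0.4    # secondary pigment band variability
    decay_noise_sd: float = 0.001       # CPMG additive noise (scan-averaged SNR)
    n_echoes: int = 2500
    echo_spacing_ms: float = 0.4
    trim_fraction: float = 0.15         # head/tail extent excluded from ROI truth
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_levels, self.n_replicates, self.n_bands, *self.image_shape) <= 0:
            raise ValueError("non-positive design dimension")
        if self.moisture_end > self.moisture_fresh:
            raise ValueError("moisture_end must not exceed moisture_fresh")
        if self.wavelength_range[1] <= self.wavelength_range[0]:
            raise ValueError("wavelength range must be increasing")
        if self.noise_sd < 0:
            raise ValueError("negative noise_sd")
        if self.t2_components is None:
            self.t2_components = [default_t2_components(l, self.n_levels)
                                  for l in range(self.n_levels)]

    @property
    def n_samples(self) -> int:
        return self.n_levels * self.n_replicates

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)

    @property
    def noiseless(self) -> bool:
        return self.noise_sd == 0


@dataclass
class SyntheticSample:
    """One generated sample: raw cube, references, decay, quality, ground truth."""

    cube: HyperCube
    white_frame: np.ndarray   # (cols, bands), per-column pushbroom reference
    dark_frame: np.ndarray
    decay: CPMGDecay
    quality: QualityRecord
    roi_truth: np.ndarray
    level_index: int
    replicate_index: int


def default_t2_components(level: int, n_levels: int = 13) -> list[tuple[float, float]]:
    """Per-level (T2 ms, amplitude fraction) triples for the three water pools."""
    u = level / (n_levels - 1)
    t21 = _T21_RANGE[0] + (_T21_RANGE[1] - _T21_RANGE[0]) * u
    t22 = _T22_RANGE[0] + (_T22_RANGE[1] - _T22_RANGE[0]) * u
    t23 = _T23_RANGE[0] + (_T23_RANGE[1] - _T23_RANGE[0]) * min(level, 9) / 9.0
    f3 = _FREE_FRACTION_FRESH * max(0.0, 1.0 - level / 10.0)
    f1 = _BOUND_FRACTION
    f2 = 1.0 - f1 - f3
    return [(t21, f1), (t22, f2), (t23, f3)]


def level_means(indicator: str, level: int | np.ndarray) -> np.ndarray | float:
    """Piecewise-linear level mean of one indicator through its anchors."""
    xs, means, _ = QUALITY_ANCHORS[indicator]
    return np.interp(level, xs, means)


def level_sds(indicator: str, level: int | np.ndarray) -> np.ndarray | float:
    xs, _, sds = QUALITY_ANCHORS[indicator]
    return np.interp(level, xs, sds)


def simulate_cpmg(components: list[tuple[float, float]], times: np.ndarray,
                  noise_sd: float = 0.0, seed: int | None = None,
                  rng: np.random.Generator | None = None) -> CPMGDecay:
    """Multi-exponential CPMG decay: sum_k A_k exp(-t/T2_k) plus white noise."""
    if not components:
        raise ValueError("empty component list")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative times")
    signal = np.zeros_like(times)
    for t2, amp in components:
        if t2 <= 0:
            raise ValueError("T2 must be positive")
        if amp < 0:
            raise ValueError("amplitudes must be non-negative")
        signal += amp * np.exp(-times / t2)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=times.shape)
    return CPMGDecay(times=times, amplitudes=signal)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((wl - center) ** 2) / (2.0 * width ** 2))


def _foreground_masks(shape: tuple[int, int], trim_fraction: float):
    """Ellipse foreground, brighter head band, and the trimmed ROI truth."""
    rows, cols = shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    ra, ca = rows * 0.32, cols * 0.40
    rr, cc = np.mgrid[0:rows, 0:cols]
    ellipse = ((rr - r0) / ra) ** 2 + ((cc - c0) / ca) ** 2 <= 1.0

    col_idx = np.flatnonzero(ellipse.any(axis=0))
    lo, hi = col_idx[0], col_idx[-1]
    cut = int(round(trim_fraction * (hi - lo + 1)))
    head = ellipse.copy()
    head[:, lo + cut:] = False  # leftmost slab of the body axis

    truth = ellipse.copy()
    truth[:, : lo + cut] = False
    truth[:, hi - cut + 1:] = False
    return ellipse, head, truth


def _white_dark(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    wl = cfg.wavelengths
    cols = cfg.image_shape[1]
    x = (wl - 700.0) / 600.0
    band_curve = 0.90 * (1.0 - 0.10 * x ** 2)
    vignette = 1.0 - 0.05 * ((np.arange(cols) - (cols - 1) / 2) / ((cols - 1) / 2)) ** 2
    white = vignette[:, None] * band_curve[None, :]
    dark = np.full((cols, cfg.n_bands), 0.05) + 0.01 * x[None, :] ** 2
    return white, dark


def _draw_quality(cfg: GeneratorConfig, level: int, rep: int,
                  rng: np.random.Generator) -> QualityRecord:
    vals = {}
    for ind in QUALITY_ANCHORS:
        mu = float(level_means(ind, level))
        sd = 0.0 if cfg.noiseless else float(level_sds(ind, level))
        v = mu if sd == 0 else float(rng.normal(mu, sd))
        if ind == "moisture":
            v = float(np.clip(v, 0.0, 100.0))
        if ind in ("hardness", "chewiness", "stickiness", "adhesiveness", "elasticity"):
            v = max(v, 0.0)
        vals[ind] = v
    # moisture anchors follow the config endpoints (defaults match the study)
    scale = (cfg.moisture_fresh - cfg.moisture_end) / (75.87 - 35.02)
    vals["moisture"] = cfg.moisture_end + (vals["moisture"] - 35.02) * scale
    de = delta_e((vals["L"], vals["a"], vals["b"]), FRESH_LAB)
    return QualityRecord(
        sample_id=f"L{level:02d}R{rep}", level=level, delta_e=de, **vals)


def _render_cube(cfg: GeneratorConfig, level: int, q: QualityRecord,
                 masks, rng: np.random.Generator) -> np.ndarray:
    ellipse, head, _ = masks
    wl = cfg.wavelengths
    rows, cols = cfg.image_shape
    x = (wl - 700.0) / 600.0
    u = level / (cfg.n_levels - 1) if cfg.n_levels > 1 else 0.0

    dev_l = q.L - float(level_means("L", level))
    slope = 0.25 - 0.05 * u + 0.010 * dev_l
    base = 0.62 - 0.20 * u + 0.004 * dev_l
    jit_a = jit_w = 0.0
    scatter = 1.0
    pig1 = pig2 = 1.0
    if not cfg.noiseless:
        jit_a = rng.normal(0.0, cfg.depth_jitter_sd)
        jit_w = rng.normal(0.0, cfg.depth_jitter_sd)
        scatter = max(rng.normal(1.0, cfg.scatter_sd), 0.5)
        pig1 = max(rng.normal(1.0, cfg.pigment_nuisance_sd), 0.0)
        pig2 = max(rng.normal(1.0, cfg.pigment_nuisance_sd), 0.0)
    d_a = max(0.05 + 0.012 * q.a + jit_a, 0.0)
    d_w = max(0.08 + 0.005 * q.moisture + jit_w, 0.0)
    # secondary pigment bands: they straddle the blue and green channels, so
    # 3-band color readouts of the astaxanthin depth are confounded, while the
    # full 224-band spectrum separates the overlapping Gaussians cleanly
    da_level = 0.05 + 0.012 * float(level_means("a", level))
    d_455 = pig1 * 0.5 * da_level
    d_530 = pig2 * 0.6 * da_level

    g455 = _gauss(wl, 455.0, 20.0)
    g480 = _gauss(wl, cfg.astaxanthin_center, 40.0)
    g530 = _gauss(wl, 530.0, 25.0)
    g960 = _gauss(wl, cfg.water_center, 35.0)
    # fixed baseline curvature keeps the shape family non-affine, so the SNV
    # transform remains injective in the planted latent parameters
    shape_fixed = (1.0 + slope * x + 0.15 * x ** 2
                   - d_a * g480 - d_455 * g455 - d_530 * g530)  # (bands,)

    # spatial structure: brighter head, drying speckle, left-right water gradient
    base_map = np.full((rows, cols), base)
    base_map[head] *= 1.25
    if not cfg.noiseless:
        # drying speckle: amplitude rises then falls over the drying course,
        # with strong sample-to-sample variability (texture is a noisy proxy)
        speckle_sd = (0.015 + 0.025 * np.sin(np.pi * u)) * np.exp(rng.normal(0.0, 0.25))
        base_map = base_map * (1.0 + rng.normal(0.0, speckle_sd, size=(rows, cols)))
    col_idx = np.flatnonzero(ellipse.any(axis=0))
    xg = np.zeros(cols)
    xg[col_idx[0]:col_idx[-1] + 1] = (
        np.linspace(-1.0, 1.0, col_idx[-1] - col_idx[0] + 1))
    d_w_map = d_w * (1.0 - 0.06 * xg)[None, :]  # left wet, right dry

    cube = base_map[:, :, None] * (shape_fixed[None, None, :]
                                   - d_w_map[:, :, None] * g960[None, None, :])
    cube *= scatter
    cube = np.where(ellipse[:, :, None], cube, 0.12)
    if not cfg.noiseless:
        cube = cube + rng.normal(0.0, cfg.noise_sd, size=cube.shape)
    return np.clip(cube, 0.0, 1.0).astype(np.float32)


def iter_samples(config: GeneratorConfig | None = None):
    """Yield SyntheticSample objects one at a time (constant memory)."""
    cfg = config or GeneratorConfig()
    masks = _foreground_masks(cfg.image_shape, cfg.trim_fraction)
    white, dark = _white_dark(cfg)
    wl = cfg.wavelengths
    times = cfg.echo_spacing_ms * np.arange(1, cfg.n_echoes + 1)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_samples)

    k = 0
    for level in range(cfg.n_levels):
        for rep in range(cfg.n_replicates):
            rng = np.random.default_rng(streams[k])
            k += 1
            q = _draw_quality(cfg, level, rep, rng)
            refl = _render_cube(cfg, level, q, masks, rng)
            raw = dark[None, :, :] + refl * (white - dark)[None, :, :]
            cube = HyperCube(data=raw.astype(np.float32), wavelengths=wl, state="raw")

            comps = [(t2, amp * q.moisture / cfg.moisture_fresh)
                     for t2, amp in cfg.t2_components[level]]
            if not cfg.noiseless:
                comps = [(t2 * float(np.exp(rng.normal(0.0, 0.02))), amp)
                         for t2, amp in comps]
            decay = simulate_cpmg(
                comps, times,
                noise_sd=0.0 if cfg.noiseless else cfg.decay_noise_sd, rng=rng)
            yield SyntheticSample(cube=cube, white_frame=white, dark_frame=dark,
                                  decay=decay, quality=q, roi_truth=masks[2],
                                  level_index=level, replicate_index=rep)


def generate_dataset(config: GeneratorConfig | None = None) -> list[SyntheticSample]:
    """Generate the full design (104 samples under defaults) as a list."""
    return list(iter_samples(config))


def quality_table(samples) -> pd.DataFrame:
    """Stack per-sample quality records into a tidy DataFrame."""
    return pd.DataFrame([s.quality.as_dict() for s in samples])


def save_dataset(samples, out_dir: str | Path, config: GeneratorConfig | None = None) -> Path:
    """Write ENVI cubes, reference frames, decay CSVs, quality CSV and config YAML."""
    out = Path(out_dir)
    (out / "cubes").mkdir(parents=True, exist_ok=True)
    (out / "decays").mkdir(exist_ok=True)
    rows = []
    for s in samples:
        sid = s.quality.sample_id
        write_envi(out / "cubes" / f"{sid}.hdr", s.cube.data, s.cube.wavelengths)
        np.savetxt(out / "cubes" / f"{sid}_white.csv", s.white_frame, delimiter=",")
        np.savetxt(out / "cubes" / f"{sid}_dark.csv", s.dark_frame, delimiter=",")
        pd.DataFrame({"time_ms": s.decay.times, "signal": s.decay.amplitudes}).to_csv(
            out / "decays" / f"{sid}.csv", index=False)
        rows.append(s.quality.as_dict())
    pd.DataFrame(rows).to_csv(out / "quality.csv", index=False)
    if config is not None:
        cfg = {k: v for k, v in vars(config).items() if k != "t2_components"}
        cfg["image_shape"] = list(config.image_shape)
        cfg["wavelength_range"] = list(config.wavelength_range)
        (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    return out
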