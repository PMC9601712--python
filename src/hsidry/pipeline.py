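"""End-to-end orchestration: generate -> extract -> model -> correlate -> map.

Reproduces the four model families (full-spectrum, characteristic-wavelength,
image-feature, fused) for the six monitored indicators (moisture, L*, a*,
b*, hardness, elasticity) with PLSR and LSSVM, plus the T2-vs-quality
correlation matrix and pixel-wise quality maps, all driven by one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cars_selection import CarsConfig, cars_select
from .chemometric_models import (SplitPlan, evaluate, fuse_features, lssvm_fit,
                                 make_split, plsr_fit, tune_lssvm)
from .hsi_calibration import mean_spectrum, reflectance_correct, segment_roi
from .image_features import FEATURE_NAMES, extract_image_features
from .mapping import predict_map, render_map
from .nmr_relaxometry import correlation_table, invert_t2, summarize_pools
from .spectral_preprocess import PreprocessConfig, preprocess
from .synthetic_data import GeneratorConfig, iter_samples

log = logging.getLogger("hsidry")

INDICATORS = ("moisture", "L", "a", "b", "hardness", "elasticity")


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def add(self, name: str, outputs: list[str], seconds: float) -> None:
        self.stages.append({"stage": name, "outputs": outputs,
                            "wall_seconds": round(seconds, 3), "status": "ok"})

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config_digest": self.config_digest, "seed": self.seed,
             "version": self.version, "stages": self.stages}, indent=2))


@dataclass
class ExtractedTables:
    """Per-sample tables produced by the extraction stage."""

    spectra: pd.DataFrame        # rows = samples, columns = wavelengths (nm)
    image_features: pd.DataFrame | None
    quality: pd.DataFrame
    t2_summaries: pd.DataFrame
    wavelengths: np.ndarray
    exemplar: tuple | None = None  # (corrected cube, roi, sample_id) for maps


def extract_tables(samples, with_image_features: bool = True,
                   with_nmr: bool = True, exemplar_level: int = 6,
                   t2_grid_size: int = 128, t2_lambda: float | None = 0.01,
                   decay_stride: int = 1) -> ExtractedTables:
    """Calibrate, segment and reduce every sample to tabular features."""
    spec_rows, feat_rows, q_rows, t2_rows, ids = [], [], [], [], []
    wavelengths = None
    exemplar = None
    for s in samples:
        cube = reflectance_correct(s.cube, s.white_frame, s.dark_frame)
        roi = segment_roi(cube)
        wavelengths = cube.wavelengths
        ids.append(s.quality.sample_id)
        spec_rows.append(mean_spectrum(cube, roi))
        q_rows.append(s.quality.as_dict())
        if with_image_features:
            feat_rows.append(extract_image_features(cube, roi))
        if with_nmr:
            decay = s.decay
            if decay_stride > 1:
                from .nmr_relaxometry import CPMGDecay
                decay = CPMGDecay(times=decay.times[::decay_stride],
                                  amplitudes=decay.amplitudes[::decay_stride])
            summ = summarize_pools(invert_t2(decay, grid_size=t2_grid_size,
                                             lam=t2_lambda))
            t2_rows.append(summ.as_dict())
        if exemplar is None and s.level_index == exemplar_level:
            exemplar = (cube, roi, s.quality.sample_id)

    spectra = pd.DataFrame(spec_rows, columns=[f"{w:.2f}" for w in wavelengths])
    spectra.insert(0, "sample_id", ids)
    quality = pd.DataFrame(q_rows)
    feats = None
    if with_image_features:
        feats = pd.DataFrame(feat_rows, columns=list(FEATURE_NAMES))
        feats.insert(0, "sample_id", ids)
    t2 = pd.DataFrame(t2_rows) if with_nmr else pd.DataFrame()
    if with_nmr:
        t2.insert(0, "sample_id", ids)
    return ExtractedTables(spectra=spectra, image_features=feats, quality=quality,
                           t2_summaries=t2, wavelengths=wavelengths,
                           exemplar=exemplar)


class _StandardizedLssvm:
    """LSSVM behind a column z-scorer fitted on the calibration rows.

    RBF distances are scale-sensitive, so heterogeneous feature blocks
    (e.g. GLCM contrast vs color moments) must be standardized first.
    """

    def __init__(self, mean, sd, model):
        self.mean, self.sd, self.model = mean, sd, model
        self.X_train = model.X_train

    def predict(self, X):
        return self.model.predict((np.asarray(X, dtype=float) - self.mean) / self.sd)


def _fit_and_evaluate(X, y, split: SplitPlan, model_kind: str, seed: int,
                      indicator: str, feature_set: str, max_pls_components: int = 10):
    ci = split.calibration_indices
    if model_kind == "plsr":
        model = plsr_fit(X[ci], y[ci], max_components=max_pls_components,
                         cv_folds=10, seed=seed)
    else:
        mu = X[ci].mean(axis=0)
        sd = X[ci].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xs = (X[ci] - mu) / sd
        gamma, sigma2 = tune_lssvm(Xs, y[ci], cv_folds=10, seed=seed)
        model = _StandardizedLssvm(mu, sd, lssvm_fit(Xs, y[ci], gamma, sigma2))
    ev = evaluate(model, split, X, y, indicator=indicator, feature_set=feature_set)
    return model, ev


def model_report(tables: ExtractedTables, seed: int = 0,
                 preprocess_config: PreprocessConfig | None = None,
                 cars_runs: int = 60, cars_folds: int = 10,
                 indicators=INDICATORS, max_pls_components: int = 10,
                 feature_sets=("full", "cars", "image", "fusion")):
    """Fit every (feature set x indicator x model) combination.

    Returns ``(report DataFrame, models dict, selections dict, split)`` where
    ``models[(feature_set, indicator, kind)]`` is the fitted model and
    ``selections[indicator]`` the CARS-selected band indices.
    """
    X_full = preprocess(tables.spectra.drop(columns="sample_id").to_numpy(),
                        preprocess_config)
    levels = tables.quality["level"].to_numpy()
    split = make_split(levels, seed=seed)
    F = (tables.image_features.drop(columns="sample_id").to_numpy()
         if tables.image_features is not None else None)
    if F is None:
        feature_sets = tuple(fs for fs in feature_sets if fs not in ("image", "fusion"))

    rows, models, selections = [], {}, {}
    ci = split.calibration_indices
    for ind in indicators:
        y = tables.quality[ind].to_numpy(dtype=float)
        if "cars" in feature_sets or "fusion" in feature_sets:
            cfg = CarsConfig(n_runs=cars_runs, cv_folds=cars_folds, seed=seed)
            sel = cars_select(X_full[ci], y[ci], cfg).selected_indices
            selections[ind] = sel
        for fs in feature_sets:
            if fs == "full":
                X = X_full
            elif fs == "cars":
                X = X_full[:, selections[ind]]
            elif fs == "image":
                X = F
            else:
                X = fuse_features(X_full[:, selections[ind]], F, split).matrix
            for kind in ("plsr", "lssvm"):
                t0 = time.perf_counter()
                model, ev = _fit_and_evaluate(X, y, split, kind, seed, ind, fs,
                                              max_pls_components)
                models[(fs, ind, kind)] = model
                row = ev.as_dict()
                row["model"] = kind
                rows.append(row)
                log.info("fit %s/%s/%s in %.2fs (RPD=%.3f)", fs, ind, kind,
                         time.perf_counter() - t0, ev.RPD)
    report = pd.DataFrame(rows)[
        ["indicator", "feature_set", "model", "R_c", "RMSEC", "R_p", "RMSEP",
         "RPD", "status"]]
    return report, models, selections, split


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Run the full configured analysis; returns the manifest (also on disk).

    ``config`` is a YAML path or an already-parsed dict with optional keys:
    ``seed``, ``out_dir``, ``generator`` (GeneratorConfig overrides),
    ``preprocess``, ``cars: {n_runs, cv_folds}``, ``stages:
    {image_features, nmr, maps}``.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text()) or {}
    else:
        cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "hsidry_run"))
    for sub in ("data", "features", "models", "reports", "maps"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    digest = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]
    manifest = RunManifest(config_digest=digest, seed=seed, version=_version())

    gen_overrides = dict(cfg.get("generator", {}))
    gen_overrides.setdefault("seed", seed)
    if "image_shape" in gen_overrides:
        gen_overrides["image_shape"] = tuple(gen_overrides["image_shape"])
    gcfg = GeneratorConfig(**gen_overrides)
    stages = cfg.get("stages", {})
    with_imgs = bool(stages.get("image_features", True))
    with_nmr = bool(stages.get("nmr", True))
    with_maps = bool(stages.get("maps", True))
    pp = PreprocessConfig(**cfg.get("preprocess", {}))
    cars_cfg = cfg.get("cars", {})

    t0 = time.perf_counter()
    tables = extract_tables(iter_samples(gcfg), with_image_features=with_imgs,
                            with_nmr=with_nmr,
                            exemplar_level=min(6, gcfg.n_levels - 1),
                            decay_stride=int(cfg.get("decay_stride", 1)))
    tables.spectra.to_csv(out / "features" / "spectra.csv", index=False)
    tables.quality.to_csv(out / "data" / "quality.csv", index=False)
    outputs = ["features/spectra.csv", "data/quality.csv"]
    if with_imgs:
        tables.image_features.to_csv(out / "features" / "image_features.csv", index=False)
        outputs.append("features/image_features.csv")
    if with_nmr:
        tables.t2_summaries.to_csv(out / "features" / "t2_summary.csv", index=False)
        outputs.append("features/t2_summary.csv")
    manifest.add("extract", outputs, time.perf_counter() - t0)

    t0 = time.perf_counter()
    report, models, selections, split = model_report(
        tables, seed=seed, preprocess_config=pp,
        cars_runs=int(cars_cfg.get("n_runs", 60)),
        cars_folds=int(cars_cfg.get("cv_folds", 10)))
    report.to_csv(out / "reports" / "evaluation.csv", index=False)
    sel_json = {ind: {"indices": sel.tolist(),
                      "wavelengths_nm": tables.wavelengths[sel].round(2).tolist()}
                for ind, sel in selections.items()}
    (out / "models" / "selected_wavelengths.json").write_text(json.dumps(sel_json, indent=2))
    manifest.add("model", ["reports/evaluation.csv", "models/selected_wavelengths.json"],
                 time.perf_counter() - t0)

    if with_nmr:
        t0 = time.perf_counter()
        corr = correlation_table(tables.t2_summaries, tables.quality)
        corr.to_csv(out / "reports" / "t2_quality_correlation.csv")
        manifest.add("correlate", ["reports/t2_quality_correlation.csv"],
                     time.perf_counter() - t0)

    if with_maps and tables.exemplar is not None:
        t0 = time.perf_counter()
        cube, roi, sid = tables.exemplar
        map_files = []
        for ind in INDICATORS:
            spectral = report[(report.indicator == ind)
                              & (report.feature_set.isin(["full", "cars"]))]
            best = spectral.sort_values("RPD", ascending=False).iloc[0]
            key = (best.feature_set, ind, best.model)
            bands = selections.get(ind) if best.feature_set == "cars" else None
            qmap = predict_map(cube, roi, models[key], preprocess_config=pp,
                               indicator=ind, band_indices=bands)
            png = out / "maps" / f"{sid}_{ind}.png"
            render_map(qmap, png, values_path=out / "maps" / f"{sid}_{ind}.csv")
            map_files.append(f"maps/{png.name}")
        manifest.add("map", map_files, time.perf_counter() - t0)

    manifest.write(out / "manifest.json")
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("hsidry")
    except Exception:  # pragma: no cover
        return "0.0.0"
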