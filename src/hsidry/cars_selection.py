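"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

Each Monte-Carlo iteration fits a PLS model on a random subset of the
calibration samples and ranks wavelengths by the absolute value of their
regression coefficients.  An exponentially decreasing function (EDF) forces
the retained-band count from all N bands down toward 2, and adaptive
reweighted sampling (a weighted draw proportional to normalized |coefficient|)
decides the survivors.  The subset whose 10-fold cross-validated RMSE is
minimal over all iterations is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemometric_models import plsr_cv_rmse, plsr_fit


@dataclass
class CarsConfig:
    """Monte-Carlo schedule and cross-validation settings."""

    n_runs: int = 1000
    cv_folds: int = 10
    mc_sample_fraction: float = 0.8
    max_pls_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mc_sample_fraction < 1:
            raise ValueError("mc_sample_fraction must be in (0, 1)")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


@dataclass
class CarsResult:
    """Selected band subset plus the per-iteration diagnostics."""

    selected_indices: np.ndarray
    rmsecv_curve: np.ndarray
    retained_counts: np.ndarray
    best_iteration: int

    def __post_init__(self) -> None:
        if len(self.selected_indices) == 0:
            raise ValueError("empty selection")


def edf_ratio(iteration: int, total_iterations: int, n_bands: int) -> float:
    """Exponentially decreasing retention fraction r_i = a * exp(-k i).

    The constants are pinned by the boundary conditions r_1 = 1 (all bands)
    and r_M = 2/N (two bands at the last iteration).
    """
    if total_iterations < 2:
        raise ValueError("need at least two iterations")
    if n_bands <= 2:
        raise ValueError("need more than two bands")
    if not 1 <= iteration <= total_iterations:
        raise ValueError("iteration out of range")
    k = math.log(n_bands / 2.0) / (total_iterations - 1)
    a = math.exp(k)
    return a * math.exp(-k * iteration)


def _inner_components(X, y, max_components, rng_seed) -> int:
    """Component count by 5-fold CV on the Monte-Carlo calibration subset."""
    max_a = min(max_components, X.shape[0] - 2, X.shape[1])
    if max_a < 1:
        return 1
    if max_a == 1:
        return 1
    rmse = plsr_cv_rmse(X, y, max_a, cv_folds=min(5, X.shape[0]), seed=rng_seed)
    return int(np.argmin(rmse)) + 1


def cars_select(X: np.ndarray, y: np.ndarray, config: CarsConfig | None = None) -> CarsResult:
    """Run CARS on a preprocessed (samples, bands) matrix against one response."""
    cfg = config or CarsConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_bands = X.shape
    if len(y) != n or n < cfg.cv_folds:
        raise ValueError("need at least cv_folds samples matching y")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if n_bands <= 2:
        raise ValueError("need more than two bands")

    rng = np.random.default_rng(cfg.seed)
    survivors = np.arange(n_bands)
    n_sub = max(int(round(cfg.mc_sample_fraction * n)), cfg.cv_folds)

    rmsecv = np.empty(cfg.n_runs)
    counts = np.empty(cfg.n_runs, dtype=int)
    history: list[np.ndarray] = []

    for i in range(1, cfg.n_runs + 1):
        sub = rng.choice(n, size=n_sub, replace=False)
        Xs, ys = X[np.ix_(sub, survivors)], y[sub]
        a = _inner_components(Xs, ys, cfg.max_pls_components, rng_seed=int(rng.integers(2**31)))
        model = plsr_fit(Xs, ys, max_components=a, cv_folds=0)
        coef = np.abs(model.coefficients)

        n_keep = max(2, int(round(edf_ratio(i, cfg.n_runs, n_bands) * n_bands)))
        n_keep = min(n_keep, len(survivors))
        # forced truncation: top n_keep by |coefficient|, ties to lower index
        order = np.lexsort((survivors, -coef))
        kept_local = np.sort(order[:n_keep])
        kept = survivors[kept_local]
        w = coef[kept_local]

        if w.sum() <= 0:
            survivors = kept
        else:
            # adaptive reweighted sampling: weighted draw with replacement
            draws = rng.choice(kept, size=n_keep, replace=True, p=w / w.sum())
            survivors = np.unique(draws)
            if len(survivors) < 2:
                top2 = kept[np.argsort(-w)[:2]]
                survivors = np.unique(np.concatenate([survivors, top2]))[:2]

        max_a = min(cfg.max_pls_components, len(survivors))
        curve = plsr_cv_rmse(X[:, survivors], y, max_a, cfg.cv_folds,
                             seed=cfg.seed)
        rmsecv[i - 1] = curve.min()
        counts[i - 1] = len(survivors)
        history.append(survivors.copy())

    best = int(np.argmin(rmsecv))
    return CarsResult(selected_indices=history[best], rmsecv_curve=rmsecv,
                      retained_counts=counts, best_iteration=best)
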