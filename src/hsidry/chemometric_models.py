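"""PLSR and LSSVM regression for drying-quality prediction.

Partial least squares (PLS1, NIPALS) projects the wide, collinear spectral
matrix onto a few latent variables chosen by cross-validation; the
per-component regression-coefficient path is kept so one fit scores every
component count.  The least squares support vector machine (LSSVM) with an
RBF kernel K(x, x') = exp(-||x - x'||^2 / sigma2) reduces to one dense linear
system

    [[0, 1^T], [1, Omega + I/gamma]] [b; alpha] = [0; y]

whose solution gives predictions  yhat(x) = sum_i alpha_i K(x, x_i) + b.

Model quality is summarized by the Pearson correlation R and RMSE on the
calibration and prediction partitions and by the residual predictive
deviation RPD = sd(y_prediction-set) / RMSEP (sd with n-1 denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist


# --------------------------------------------------------------------------
# calibration / prediction split
# --------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Disjoint calibration/prediction index lists (3:1 by default)."""

    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    ratio: float = 0.25
    stratified_by_level: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        cal = set(self.calibration_indices.tolist())
        pred = set(self.prediction_indices.tolist())
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")


def make_split(levels: np.ndarray, seed: int = 0, prediction_fraction: float = 0.25) -> SplitPlan:
    """Stratified 3:1 split: per drying level, a seeded draw of prediction samples.

    ``levels`` is the per-sample drying-level label (any hashable values).
    With 8 replicates per level this yields 6 calibration + 2 prediction
    samples per level; uneven replicate counts round to the nearest integer
    (at least one sample stays in each partition per level).
    """
    levels = np.asarray(levels)
    rng = np.random.default_rng(seed)
    cal, pred = [], []
    for lv in np.unique(levels):
        idx = np.flatnonzero(levels == lv)
        n_pred = int(round(len(idx) * prediction_fraction))
        n_pred = min(max(n_pred, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        pred.extend(perm[:n_pred].tolist())
        cal.extend(perm[n_pred:].tolist())
    return SplitPlan(
        calibration_indices=np.array(sorted(cal)),
        prediction_indices=np.array(sorted(pred)),
        ratio=prediction_fraction,
        seed=seed,
    )


# --------------------------------------------------------------------------
# PLS1 (NIPALS) with coefficient path
# --------------------------------------------------------------------------

@dataclass
class PlsrModel:
    """Fitted PLS1 model; ``coef_path[a]`` are the coefficients using a+1 LVs."""

    n_components: int
    coef_path: np.ndarray          # (max_components, n_features)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray            # W (n_features, max_components)
    loadings: np.ndarray           # P (n_features, max_components)
    cv_rmse: np.ndarray | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return self.coef_path[self.n_components - 1]

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ (self.coefficients / self.x_scale))

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        b = self.coef_path[a - 1]
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xs @ b + self.y_mean


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, max_components: int):
    """NIPALS PLS1 on centered data; returns (coef_path, W, P)."""
    n, m = Xc.shape
    E = Xc.copy()
    f = yc.copy()
    W = np.zeros((m, max_components))
    P = np.zeros((m, max_components))
    coef_path = np.zeros((max_components, m))
    beta = np.zeros(m)
    r_basis: list[np.ndarray] = []
    a_done = 0
    for a in range(max_components):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = E.T @ t / tt
        q = float(f @ t) / tt
        E -= np.outer(t, p)
        f -= q * t
        # r_a spans the X-side rotation so that beta_a = sum_j q_j r_j
        r = w - sum((P[:, j] @ w) * r_basis[j] for j in range(a))
        r_basis.append(r)
        W[:, a] = w
        P[:, a] = p
        beta = beta + q * r
        coef_path[a] = beta
        a_done = a + 1
    for a in range(a_done, max_components):  # pad with last attainable solution
        coef_path[a] = coef_path[a_done - 1] if a_done else 0.0
    return coef_path, W[:, :max(a_done, 1)], P[:, :max(a_done, 1)], max(a_done, 1)


def _kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def plsr_cv_rmse(X: np.ndarray, y: np.ndarray, max_components: int,
                 cv_folds: int, seed: int = 0, scale: bool = False) -> np.ndarray:
    """K-fold CV RMSE for every component count 1..max_components (one fit/fold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = min(cv_folds, n)
    folds = _kfold_indices(n, k, seed)
    sq = np.zeros(max_components)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        model = plsr_fit(X[train], y[train], max_components=max_components,
                         cv_folds=0, scale=scale)
        for a in range(1, max_components + 1):
            resid = y[test] - model.predict(X[test], n_components=a)
            sq[a - 1] += float(resid @ resid)
    return np.sqrt(sq / n)


def plsr_fit(X: np.ndarray, y: np.ndarray, max_components: int = 10,
             cv_folds: int = 10, seed: int = 0, scale: bool = False,
             n_components: int | None = None) -> PlsrModel:
    """Fit PLS1; the component count minimizes K-fold CV RMSE unless fixed.

    ``cv_folds=0`` (or a fixed ``n_components``) skips cross-validation and
    uses ``max_components`` latent variables.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (samples, features) matching y")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    max_components = min(max_components, X.shape[0] - 1, X.shape[1])

    x_mean = X.mean(axis=0)
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(X.shape[1])
    Xc = (X - x_mean) / x_scale
    y_mean = float(y.mean())

    coef_path, W, P, attainable = _nipals_path(Xc, y - y_mean, max_components)

    cv_rmse = None
    if n_components is not None:
        a_best = min(n_components, attainable)
    elif cv_folds and cv_folds >= 2:
        cv_rmse = plsr_cv_rmse(X, y, max_components, cv_folds, seed=seed, scale=scale)
        a_best = int(np.argmin(cv_rmse)) + 1
    else:
        a_best = attainable
    return PlsrModel(n_components=a_best, coef_path=coef_path, x_mean=x_mean,
                     x_scale=x_scale, y_mean=y_mean, weights=W, loadings=P,
                     cv_rmse=cv_rmse)


# --------------------------------------------------------------------------
# LSSVM with RBF kernel
# --------------------------------------------------------------------------

@dataclass
class LssvmModel:
    """Fitted LSSVM: support coefficients alpha, bias b, kernel parameters."""

    X_train: np.ndarray
    alpha: np.ndarray
    bias: float
    gamma: float
    sigma2: float

    def kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        d2 = cdist(np.atleast_2d(A), np.atleast_2d(B), metric="sqeuclidean")
        return np.exp(-d2 / self.sigma2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.kernel(X, self.X_train) @ self.alpha + self.bias


def lssvm_fit(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> LssvmModel:
    """Solve the LSSVM equality-constrained system for (bias, alpha)."""
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    d2 = cdist(X, X, metric="sqeuclidean")
    omega = np.exp(-d2 / sigma2)
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = omega + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = solve(A, rhs, assume_a="sym")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(
            "singular LSSVM system; reduce gamma or remove duplicate samples"
        ) from exc
    if not np.all(np.isfinite(sol)) or np.linalg.norm(A @ sol - rhs) > 1e-6 * max(1.0, np.linalg.norm(rhs)):
        raise ValueError("singular LSSVM system; reduce gamma or remove duplicate samples")
    return LssvmModel(X_train=X, alpha=sol[1:], bias=float(sol[0]),
                      gamma=gamma, sigma2=sigma2)


def tune_lssvm(X: np.ndarray, y: np.ndarray,
               gamma_grid=None, sigma2_grid=None,
               cv_folds: int = 10, seed: int = 0) -> tuple[float, float]:
    """Grid search (gamma, sigma2) minimizing K-fold CV RMSE.

    Ties break toward smaller gamma, then larger sigma2.  Default grids are
    gamma in 10^0..10^6 and sigma2 in 10^-2..10^4 (7 x 7 log-spaced).
    """
    gamma_grid = np.logspace(0, 6, 7) if gamma_grid is None else np.asarray(gamma_grid, float)
    sigma2_grid = np.logspace(-2, 4, 7) if sigma2_grid is None else np.asarray(sigma2_grid, float)
    if gamma_grid.size == 0 or sigma2_grid.size == 0:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = _kfold_indices(n, min(cv_folds, n), seed)

    best = None
    # iterate so that earlier entries win ties: gamma ascending, sigma2 descending
    for g in np.sort(gamma_grid):
        for s2 in np.sort(sigma2_grid)[::-1]:
            sq = 0.0
            ok = True
            for test in folds:
                train = np.setdiff1d(np.arange(n), test)
                try:
                    model = lssvm_fit(X[train], y[train], g, s2)
                except ValueError:
                    ok = False
                    break
                resid = y[test] - model.predict(X[test])
                sq += float(resid @ resid)
            if not ok:
                continue
            rmse = np.sqrt(sq / n)
            if best is None or rmse < best[0] - 1e-15:
                best = (rmse, g, s2)
    if best is None:
        raise ValueError("all hyperparameter grid cells degenerate")
    return float(best[1]), float(best[2])


# --------------------------------------------------------------------------
# evaluation and feature fusion
# --------------------------------------------------------------------------

@dataclass
class ModelEvaluation:
    """R/RMSE on both partitions plus RPD for one indicator and feature set."""

    indicator: str
    feature_set: str
    R_c: float
    RMSEC: float
    R_p: float
    RMSEP: float
    RPD: float
    status: str = "ok"

    def as_dict(self) -> dict:
        return {
            "indicator": self.indicator, "feature_set": self.feature_set,
            "R_c": self.R_c, "RMSEC": self.RMSEC, "R_p": self.R_p,
            "RMSEP": self.RMSEP, "RPD": self.RPD, "status": self.status,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate(model, split: SplitPlan, X: np.ndarray, y: np.ndarray,
             indicator: str = "", feature_set: str = "") -> ModelEvaluation:
    """Score a fitted model on a calibration/prediction split.

    RPD uses the n-1 standard deviation of the prediction-set reference
    values.  A zero RMSEP yields an infinite RPD; constant predictions give
    ``status='constant_predictions'`` with R reported as NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ci, pi = split.calibration_indices, split.prediction_indices
    yc_hat = np.asarray(model.predict(X[ci]), dtype=float).ravel()
    yp_hat = np.asarray(model.predict(X[pi]), dtype=float).ravel()

    rmsec = float(np.sqrt(np.mean((y[ci] - yc_hat) ** 2)))
    rmsep = float(np.sqrt(np.mean((y[pi] - yp_hat) ** 2)))
    r_c = _pearson(y[ci], yc_hat)
    r_p = _pearson(y[pi], yp_hat)
    sd_pred = float(np.std(y[pi], ddof=1))
    rpd = float("inf") if rmsep == 0 else sd_pred / rmsep
    status = "ok"
    if np.isnan(r_c) or np.isnan(r_p):
        status = "constant_predictions"
    return ModelEvaluation(indicator=indicator, feature_set=feature_set,
                           R_c=r_c, RMSEC=rmsec, R_p=r_p, RMSEP=rmsep,
                           RPD=rpd, status=status)


@dataclass
class FusedFeatures:
    """Feature-level fusion result with the calibration normalizers retained."""

    matrix: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask over the pre-fusion columns

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x[:, self.kept] - self.mean) / self.sd


def fuse_features(cars_spectra: np.ndarray, image_features: np.ndarray,
                  split: SplitPlan) -> FusedFeatures:
    """Concatenate [selected bands | image features], z-scored column-wise.

    Normalization statistics come from the calibration rows only; columns
    with zero calibration standard deviation are dropped with a warning.
    """
    cars_spectra = np.asarray(cars_spectra, dtype=float)
    image_features = np.asarray(image_features, dtype=float)
    if cars_spectra.shape[0] != image_features.shape[0]:
        raise ValueError("sample counts differ between feature blocks")
    raw = np.hstack([cars_spectra, image_features])
    cal = raw[split.calibration_indices]
    mu = cal.mean(axis=0)
    sd = cal.std(axis=0, ddof=1)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} zero-variance column(s) during fusion")
    fused = (raw[:, kept] - mu[kept]) / sd[kept]
    return FusedFeatures(matrix=fused, mean=mu[kept], sd=sd[kept], kept=kept)


# --------------------------------------------------------------------------
# model serialization (JSON, for the command-line workflow)
# --------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a fitted PLSR or LSSVM model to JSON."""
    import json
    from pathlib import Path

    if isinstance(model, PlsrModel):
        payload = {
            "kind": "plsr",
            "n_components": model.n_components,
            "coef_path": model.coef_path.tolist(),
            "x_mean": model.x_mean.tolist(),
            "x_scale": model.x_scale.tolist(),
            "y_mean": model.y_mean,
        }
    elif isinstance(model, LssvmModel):
        payload = {
            "kind": "lssvm",
            "X_train": model.X_train.tolist(),
            "alpha": model.alpha.tolist(),
            "bias": model.bias,
            "gamma": model.gamma,
            "sigma2": model.sigma2,
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    """Load a model written by :func:`save_model`."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    if payload["kind"] == "plsr":
        coef_path = np.array(payload["coef_path"])
        return PlsrModel(n_components=int(payload["n_components"]),
                         coef_path=coef_path,
                         x_mean=np.array(payload["x_mean"]),
                         x_scale=np.array(payload["x_scale"]),
                         y_mean=float(payload["y_mean"]),
                         weights=np.zeros((coef_path.shape[1], 1)),
                         loadings=np.zeros((coef_path.shape[1], 1)))
    if payload["kind"] == "lssvm":
        return LssvmModel(X_train=np.array(payload["X_train"]),
                          alpha=np.array(payload["alpha"]),
                          bias=float(payload["bias"]),
                          gamma=float(payload["gamma"]),
                          sigma2=float(payload["sigma2"]))
    raise ValueError(f"unknown model kind {payload['kind']!r}")
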