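"""Split plans, PLS1, LSSVM, evaluation metrics and feature fusion."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from hsidry.chemometric_models import (SplitPlan, evaluate, fuse_features,
                                       lssvm_fit, make_split, plsr_fit,
                                       tune_lssvm)


def _levels(n_levels=13, reps=8):
    return np.repeat(np.arange(n_levels), reps)


# ------------------------------------------------------------------ split

def test_split_counts_default_design():
    plan = make_split(_levels(), seed=0)
    assert len(plan.calibration_indices) == 78
    assert len(plan.prediction_indices) == 26
    union = set(plan.calibration_indices) | set(plan.prediction_indices)
    assert union == set(range(104))
    lv = _levels()
    for level in range(13):
        assert (lv[plan.prediction_indices] == level).sum() == 2


def test_split_seeded_determinism():
    a = make_split(_levels(), seed=5)
    b = make_split(_levels(), seed=5)
    np.testing.assert_array_equal(a.prediction_indices, b.prediction_indices)
    c = make_split(_levels(), seed=6)
    assert not np.array_equal(a.prediction_indices, c.prediction_indices)


def test_split_rejects_overlap():
    with pytest.raises(ValueError):
        SplitPlan(calibration_indices=np.array([0, 1]),
                  prediction_indices=np.array([1, 2]))


# ------------------------------------------------------------------ PLS1

def test_plsr_single_latent_direction_noiseless(rng):
    # zero-mean orthogonal columns: one latent variable reproduces y exactly
    A = rng.normal(size=(40, 6))
    Q, _ = np.linalg.qr(A - A.mean(axis=0))
    y = 3.0 * Q[:, 2]
    model = plsr_fit(Q, y, max_components=5, cv_folds=10)
    rmse1 = np.sqrt(np.mean((model.predict(Q, n_components=1) - y) ** 2))
    assert rmse1 < 1e-8


def test_plsr_full_rank_equals_least_squares(rng):
    X = rng.normal(size=(20, 5))
    y = rng.normal(size=20)
    model = plsr_fit(X, y, max_components=5, cv_folds=0)
    A = np.hstack([np.ones((20, 1)), X])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    np.testing.assert_allclose(model.predict(X, n_components=5), A @ beta, atol=1e-9)


def test_plsr_matches_sklearn_path(rng):
    X = rng.normal(size=(30, 12))
    y = rng.normal(size=30)
    model = plsr_fit(X, y, max_components=6, cv_folds=0)
    for a in (1, 3, 6):
        sk = PLSRegression(n_components=a, scale=False).fit(X, y)
        np.testing.assert_allclose(model.predict(X, n_components=a),
                                   sk.predict(X).ravel(), atol=1e-8)


def test_plsr_permutation_invariance(rng):
    X = rng.normal(size=(25, 8))
    y = rng.normal(size=25)
    perm = rng.permutation(25)
    a = plsr_fit(X, y, n_components=4, cv_folds=0)
    b = plsr_fit(X[perm], y[perm], n_components=4, cv_folds=0)
    np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-9)


def test_plsr_input_validation(rng):
    X = rng.normal(size=(10, 4))
    with pytest.raises(ValueError):
        plsr_fit(X, np.ones(10))          # zero-variance response
    with pytest.raises(ValueError):
        plsr_fit(X, rng.normal(size=10), max_components=0)


# ------------------------------------------------------------------ LSSVM

def test_lssvm_interpolates_at_large_gamma(rng):
    X = rng.normal(size=(30, 3))
    y = rng.normal(size=30)
    model = lssvm_fit(X, y, gamma=1e8, sigma2=4.0)
    assert np.abs(model.predict(X) - y).max() < 1e-4


def test_lssvm_kernel_symmetric_unit_diagonal(rng):
    X = rng.normal(size=(12, 5))
    model = lssvm_fit(X, rng.normal(size=12), gamma=10.0, sigma2=2.0)
    K = model.kernel(X, X)
    np.testing.assert_allclose(K, K.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)


def test_lssvm_solution_satisfies_linear_system(rng):
    X = rng.normal(size=(15, 4))
    y = rng.normal(size=15)
    gamma, sigma2 = 50.0, 3.0
    model = lssvm_fit(X, y, gamma, sigma2)
    K = model.kernel(X, X)
    n = len(y)
    A = np.block([[np.zeros((1, 1)), np.ones((1, n))],
                  [np.ones((n, 1)), K + np.eye(n) / gamma]])
    sol = np.concatenate([[model.bias], model.alpha])
    resid = np.linalg.norm(A @ sol - np.concatenate([[0.0], y]))
    assert resid < 1e-8


def test_lssvm_parameter_validation(rng):
    X = rng.normal(size=(5, 2))
    with pytest.raises(ValueError):
        lssvm_fit(X, np.ones(5), gamma=-1.0, sigma2=1.0)
    with pytest.raises(ValueError):
        lssvm_fit(X, np.ones(5), gamma=1.0, sigma2=0.0)


def test_tune_lssvm_recovers_generating_width(rng):
    # smooth function drawn from an RBF kernel with sigma2 = 1
    X = rng.uniform(-2, 2, size=(60, 2))
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / 1.0)
    y = np.linalg.cholesky(K + 1e-8 * np.eye(60)) @ rng.normal(size=60)
    sigma2_grid = np.logspace(-2, 2, 5)  # one grid step = one decade
    gamma, sigma2 = tune_lssvm(X, y, gamma_grid=[10.0, 1000.0],
                               sigma2_grid=sigma2_grid, cv_folds=5)
    assert sigma2 in (0.1, 1.0, 10.0)


def test_tune_lssvm_single_cell_and_argmin(rng):
    X = rng.normal(size=(20, 3))
    y = rng.normal(size=20)
    assert tune_lssvm(X, y, gamma_grid=[7.0], sigma2_grid=[0.5], cv_folds=5) == (7.0, 0.5)
    with pytest.raises(ValueError):
        tune_lssvm(X, y, gamma_grid=[], sigma2_grid=[1.0])


# ------------------------------------------------------------------ evaluation

def _tiny_split():
    return SplitPlan(calibration_indices=np.arange(4),
                     prediction_indices=np.arange(4, 8))


def test_evaluate_hand_fixture():
    y = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])

    class Model:
        def predict(self, X):
            return X[:, 0]

    X = np.array([[1], [2], [3], [4], [1.1], [1.9], [3.2], [3.8]], dtype=float)
    ev = evaluate(Model(), _tiny_split(), X, y)
    assert ev.RMSEC == pytest.approx(0.0, abs=1e-12)
    assert ev.RMSEP == pytest.approx(np.sqrt(0.01 + 0.01 + 0.04 + 0.04) / 2)
    assert ev.RMSEP == pytest.approx(0.158113883, abs=1e-8)


def test_evaluate_offset_and_perfect_models():
    y = np.arange(8, dtype=float)
    X = y[:, None]

    class Offset:
        def predict(self, X):
            return X[:, 0] + 0.7

    ev = evaluate(Offset(), _tiny_split(), X, y)
    assert ev.R_p == pytest.approx(1.0)
    assert ev.RMSEP == pytest.approx(0.7)

    class Perfect:
        def predict(self, X):
            return X[:, 0]

    ev2 = evaluate(Perfect(), _tiny_split(), X, y)
    assert ev2.RMSEP == 0.0 and np.isinf(ev2.RPD)


def test_rpd_rmsep_identity(rng):
    y = rng.normal(size=8)

    class Noisy:
        def predict(self, X):
            return X[:, 0] * 0.9 + 0.1

    X = y[:, None]
    split = _tiny_split()
    ev = evaluate(Noisy(), split, X, y)
    sd = np.std(y[split.prediction_indices], ddof=1)
    assert ev.RPD * ev.RMSEP == pytest.approx(sd, rel=1e-12)


def test_evaluate_constant_predictions_flagged():
    y = np.arange(8, dtype=float)

    class Const:
        def predict(self, X):
            return np.zeros(X.shape[0])

    ev = evaluate(Const(), _tiny_split(), y[:, None], y)
    assert ev.status == "constant_predictions"
    assert np.isnan(ev.R_p)


# ------------------------------------------------------------------ fusion

def test_fusion_zscores_on_calibration_rows(rng):
    spectra = rng.normal(size=(16, 5))
    image = rng.normal(size=(16, 13))
    split = SplitPlan(calibration_indices=np.arange(12),
                      prediction_indices=np.arange(12, 16))
    fused = fuse_features(spectra, image, split)
    assert fused.matrix.shape == (16, 18)
    cal = fused.matrix[split.calibration_indices]
    np.testing.assert_allclose(cal.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(cal.std(axis=0, ddof=1), 1.0, atol=1e-10)

    raw = np.hstack([spectra, image])
    x_new = rng.normal(size=18)
    np.testing.assert_allclose(
        fused.apply(x_new)[0],
        (x_new - raw[:12].mean(axis=0)) / raw[:12].std(axis=0, ddof=1), atol=1e-10)


def test_fusion_drops_zero_variance_columns(rng):
    spectra = rng.normal(size=(12, 3))
    spectra[:, 1] = 2.0
    image = rng.normal(size=(12, 2))
    split = SplitPlan(calibration_indices=np.arange(9),
                      prediction_indices=np.arange(9, 12))
    with pytest.warns(UserWarning):
        fused = fuse_features(spectra, image, split)
    assert fused.matrix.shape == (12, 4)
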