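"""K-OPLS core: kernel algebra, estimation, prediction, fit statistics."""

import numpy as np
import pytest

from koplspa import (
    KernelSpec,
    KOPLSModel,
    center_kernel,
    center_kernel_test,
    classify,
    fit_kopls,
    fit_kopls_xy,
    fit_stats,
    gaussian_kernel,
    predict_kopls,
)
from koplspa.kopls import explained_kernel_fraction


# ---------------------------------------------------------------- kernel

def test_kernel_identical_rows_give_one_and_closed_form():
    x = np.array([[1.0, 2.0, 3.0]])
    assert gaussian_kernel(x, x, 1.0)[0, 0] == 1.0
    # ||x - z|| = 1, sigma = 0.5  ->  exp(-1 / (2 * 0.25)) = exp(-2)
    z = np.array([[1.0, 2.0, 4.0]])
    assert gaussian_kernel(x, z, 0.5)[0, 0] == pytest.approx(np.exp(-2), rel=1e-12)


def test_kernel_positive_semidefinite():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((6, 3))
    K = gaussian_kernel(X, X, 1.3)
    np.testing.assert_allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() >= -1e-10


def test_kernel_input_validation():
    with pytest.raises(ValueError):
        KernelSpec(0.0)
    with pytest.raises(ValueError):
        gaussian_kernel(np.zeros((2, 3)), np.zeros((2, 4)), 1.0)


# -------------------------------------------------------------- centering

def test_centering_of_constant_kernel_is_zero():
    Kc, _ = center_kernel(np.ones((5, 5)))
    np.testing.assert_allclose(Kc, 0.0, atol=1e-12)


def test_centered_kernel_rows_and_columns_sum_to_zero():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((12, 4))
    Kc, _ = center_kernel(gaussian_kernel(X, X, 2.0))
    assert np.abs(Kc.sum(axis=0)).max() < 1e-8
    assert np.abs(Kc.sum(axis=1)).max() < 1e-8


def test_test_centering_of_training_kernel_matches_training_centering():
    """Centering the training kernel through the test-side formula must give
    the double-centered training kernel (matrix identity)."""
    rng = np.random.default_rng(2)
    X = rng.standard_normal((10, 3))
    K = gaussian_kernel(X, X, 1.0)
    Kc, state = center_kernel(K)
    np.testing.assert_allclose(center_kernel_test(K, state), Kc, atol=1e-12)


def test_centering_state_dimension_checked():
    _, state = center_kernel(np.eye(4))
    with pytest.raises(ValueError):
        center_kernel_test(np.zeros((2, 5)), state)


# ---------------------------------------------------------------- fitting

def test_separable_clusters_fit_perfectly(separable_xy):
    X, y = separable_xy
    model = fit_kopls_xy(X, y, sigma=1.0, Ao=1)
    stats = fit_stats(model)
    assert np.all(classify(model, model.yhat) == y)
    assert stats.R2Y >= 0.99
    assert 0.0 <= stats.R2X <= 1.0


def test_ao_zero_predictive_score_is_direct_formula(random_xy):
    """With no orthogonal components Tp collapses to Kc Y Cp Sp^(-1/2); for
    n <= 15 this doubles as the brute-force eigendecomposition oracle since
    Y'KcY is 1x1."""
    X, y = random_xy
    X, y = X[:12], np.r_[y[:6], y[15:21]]
    model = fit_kopls_xy(X, y, sigma=2.0, Ao=0)
    Kc, _ = center_kernel(gaussian_kernel(X, X, 2.0))
    coded = np.where(y == np.unique(y)[1], 1.0, -1.0)
    yc = coded - coded.mean()
    sp = yc @ Kc @ yc
    expected = Kc @ yc / np.sqrt(sp)
    # sign convention may flip both Tp and Bt together
    sign = np.sign(expected @ model.Tp)
    np.testing.assert_allclose(model.Tp, sign * expected, atol=1e-8)


def test_orthogonal_scores_orthogonal_to_predictive(random_xy):
    X, y = random_xy
    model = fit_kopls_xy(X, y, sigma=2.0, Ao=3)
    for t in model.To:
        assert abs(t @ model.Tp) < 1e-8
    for i in range(len(model.To)):
        for j in range(i):
            assert abs(model.To[i] @ model.To[j]) < 1e-8


def test_orthogonality_holds_over_many_random_fits():
    rng = np.random.default_rng(99)
    for _ in range(100):
        n = int(rng.integers(14, 26))
        X = rng.standard_normal((n, int(rng.integers(2, 6))))
        y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
        ao = int(rng.integers(1, 4))
        model = fit_kopls_xy(X, y, sigma=float(rng.uniform(0.5, 4.0)), Ao=ao)
        assert max(abs(t @ model.Tp) for t in model.To) < 1e-8


def test_training_r2y_nondecreasing_in_ao(random_xy):
    X, y = random_xy
    r2 = [fit_stats(fit_kopls_xy(X, y, 2.0, ao)).R2Y for ao in range(5)]
    assert all(np.diff(r2) >= -1e-10)


def test_fit_rejects_degenerate_inputs(random_xy):
    X, y = random_xy
    Kc, _ = center_kernel(gaussian_kernel(X, X, 1.0))
    with pytest.raises(ValueError):
        fit_kopls(Kc, y, Ao=len(y))
    with pytest.raises(ValueError):
        fit_kopls(np.zeros_like(Kc), y, Ao=1)
    with pytest.raises(ValueError):
        fit_kopls(Kc, np.zeros_like(y), Ao=1)  # single class


# ------------------------------------------------------------- prediction

def test_predicting_training_set_reproduces_fitted_values(random_xy):
    X, y = random_xy
    for ao in (0, 1, 3):
        model = fit_kopls_xy(X, y, sigma=2.0, Ao=ao)
        yhat, _ = predict_kopls(model, X)
        np.testing.assert_allclose(yhat, model.yhat, atol=1e-8)


def test_duplicate_of_training_sample_predicts_same_value(random_xy):
    X, y = random_xy
    model = fit_kopls_xy(X, y, sigma=1.5, Ao=2)
    yhat, _ = predict_kopls(model, X[[4]])
    assert abs(yhat[0] - model.yhat[4]) < 1e-8


def test_held_out_separable_data_classified_perfectly(separable_xy):
    X, y = separable_xy
    model = fit_kopls_xy(X, y, sigma=1.0, Ao=1)
    rng = np.random.default_rng(8)
    Xt = np.vstack([rng.normal(-3, 0.15, (10, 4)), rng.normal(3, 0.15, (10, 4))])
    yt = np.r_[np.zeros(10, int), np.ones(10, int)]
    yhat, _ = predict_kopls(model, Xt)
    assert np.all(classify(model, yhat) == yt)


def test_classification_sign_and_tie_rules(random_xy):
    X, y = random_xy
    model = fit_kopls_xy(X, y, sigma=2.0, Ao=1)
    model.y_offset = 0.0
    assert classify(model, np.array([0.7]))[0] == model.classes_[1]
    assert classify(model, np.array([-0.7]))[0] == model.classes_[0]
    model.majority_class = model.classes_[0]
    assert classify(model, np.array([0.0]))[0] == model.classes_[0]


# ---------------------------------------------------------------- stats

def test_full_span_basis_explains_all_kernel_variation(random_xy):
    X, _ = random_xy
    Kc, _ = center_kernel(gaussian_kernel(X, X, 1.0))
    assert explained_kernel_fraction(Kc, np.eye(X.shape[0])) == pytest.approx(1.0)


def test_q2y_computed_from_cv_predictions(random_xy):
    X, y = random_xy
    model = fit_kopls_xy(X, y, sigma=2.0, Ao=1)
    coded = np.where(y == model.classes_[1], 1.0, -1.0)
    stats = fit_stats(model, cv_y=coded, cv_pred=coded)  # perfect CV predictions
    assert stats.Q2Y == pytest.approx(1.0)


# ------------------------------------------------------------ persistence

def test_model_roundtrips_through_json(tmp_path, random_xy):
    X, y = random_xy
    model = fit_kopls_xy(X, y, sigma=2.0, Ao=2)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = KOPLSModel.load(path)
    Xt = np.random.default_rng(3).standard_normal((5, X.shape[1]))
    np.testing.assert_allclose(
        predict_kopls(loaded, Xt)[0], predict_kopls(model, Xt)[0], atol=1e-12
    )
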