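"""Attribution methods against closed forms and exhaustive oracles."""

import itertools
import math

import numpy as np
import pytest

from lsaspec import (CNNArchitecture, build_cnn, fit_pls1, gradcam_map,
                     permutation_shap, pls_coefficients, predict_pls1,
                     vip_scores)


# -- Grad-CAM -----------------------------------------------------------------

def _tiny_model(seed=0, n_filters=2, fc_units=3, N=15, P=2):
    arch = CNNArchitecture(n_filters=[n_filters], filter_widths=[3],
                           fc_units=fc_units)
    return build_cnn(arch, N, P, seed=seed)


def test_gradcam_shape_and_nonnegativity(rng):
    model = _tiny_model()
    cam = gradcam_map(model, rng.normal(size=15), component=1)
    assert cam.shape == (15,)
    assert np.all(cam >= 0)


def test_gradcam_component_index_validated(rng):
    with pytest.raises(IndexError):
        gradcam_map(_tiny_model(), rng.normal(size=15), component=5)


def test_gradcam_zero_when_output_weights_zero(rng):
    model = _tiny_model()
    weights = model.get_weights()
    weights[-2][:] = 0.0                       # output-layer weight matrix
    weights[-1][:] = 1.0                       # keep output alive via bias
    model.set_weights(weights)
    cam = gradcam_map(model, rng.normal(size=15), component=0)
    assert np.all(cam == 0)


def test_gradcam_single_filter_map_proportional_to_feature_map(rng):
    """With one filter, identity conv and positive head weights the map is
    a positive multiple of the (positive part of the) feature map."""
    model = _tiny_model(n_filters=1, fc_units=1)
    weights = model.get_weights()
    for w in weights:
        w[:] = np.abs(w) + 0.01               # all-positive network
    model.set_weights(weights)
    x = np.abs(rng.normal(size=15)) + 0.5
    fmap, grads = model.feature_maps_and_grads(x, 0)
    # per-position gradients vary through pooling; alpha is their mean
    alpha = grads.mean(axis=1)
    assert alpha[0] > 0
    cam_direct = np.maximum(alpha @ fmap, 0.0)
    cam = gradcam_map(model, x, 0)
    interp = np.interp(np.linspace(0, cam_direct.size - 1, 15),
                       np.arange(cam_direct.size), cam_direct)
    assert np.allclose(cam, interp)


def test_gradcam_gradients_match_finite_differences(rng):
    """d(output)/d(feature map) from backprop vs central differences."""
    model = _tiny_model(seed=3)
    x = rng.normal(size=15)
    fmap, grads = model.feature_maps_and_grads(x, 0)
    conv_idx = model.last_conv_index

    def head_output(fm):
        a = fm[None]
        for layer in model.layers[conv_idx + 1:]:
            a = layer.forward(a, False, None)
        return float(a[0, 0])

    eps = 1e-5
    for (k, pos) in [(0, 2), (1, 5), (0, 9), (1, 12)]:
        fp = fmap.copy()
        fp[k, pos] += eps
        up = head_output(fp)
        fp[k, pos] -= 2 * eps
        down = head_output(fp)
        fd = (up - down) / (2 * eps)
        # restore caches consumed by the probe evaluations
        model.feature_maps_and_grads(x, 0)
        assert grads[k, pos] == pytest.approx(fd, abs=1e-4)


# -- permutation SHAP ---------------------------------------------------------

def test_shap_linear_model_single_background_exact():
    f = lambda X: (X @ np.array([2.0, 0.0]))[:, None]
    phi = permutation_shap(f, background=np.zeros((1, 2)),
                           explain=np.array([[1.0, 1.0]]), component=0,
                           n_permutations=2, seed=0)
    assert np.allclose(phi, [[2.0, 0.0]])


def test_shap_constant_model_zero():
    f = lambda X: np.full((X.shape[0], 1), 3.3)
    phi = permutation_shap(f, background=np.ones((4, 3)),
                           explain=np.zeros((2, 3)), component=0,
                           n_permutations=10, seed=0)
    assert np.allclose(phi, 0.0)


def test_shap_additivity_exact(rng):
    """sum_j phi_j = f(x) - E_bg[f] holds to machine precision."""
    W = rng.normal(size=(6, 2))

    def f(X):
        return np.tanh(X @ W) + 0.3 * (X**2) @ W

    bg = rng.normal(size=(5, 6))
    x = rng.normal(size=(1, 6))
    phi = permutation_shap(f, bg, x, component=1, n_permutations=8, seed=1)
    assert phi.sum() == pytest.approx(
        float(f(x)[0, 1] - f(bg)[:, 1].mean()), abs=1e-8)


def _exact_shapley(f, bg, x, component):
    """Exhaustive Shapley over all coalitions (small d only)."""
    d = x.size

    def value(S):
        Xm = bg.copy()
        for j in S:
            Xm[:, j] = x[j]
        return float(np.atleast_2d(f(Xm))[:, component].mean())

    phi = np.zeros(d)
    for j in range(d):
        rest = [k for k in range(d) if k != j]
        for r in range(d):
            for S in itertools.combinations(rest, r):
                wgt = (math.factorial(r) * math.factorial(d - r - 1)
                       / math.factorial(d))
                phi[j] += wgt * (value(S + (j,)) - value(S))
    return phi


def test_shap_matches_exhaustive_oracle(rng):
    W1 = rng.normal(size=(5, 4))
    w2 = rng.normal(size=4)

    def f(X):
        return np.tanh(X @ W1) @ w2[:, None]

    bg = rng.normal(size=(4, 5))
    x = rng.normal(size=5)
    exact = _exact_shapley(f, bg, x, 0)
    est = permutation_shap(f, bg, x[None], component=0,
                           n_permutations=10_000, seed=2)[0]
    rng_range = exact.max() - exact.min()
    assert np.abs(est - exact).max() < 0.02 * rng_range


def test_shap_symmetry_for_duplicated_features(rng):
    """Identical features must receive equal attribution in expectation."""
    w = np.array([1.5, 1.5, -0.7])

    def f(X):
        return (X @ w)[:, None]

    bg = rng.normal(size=(6, 3))
    bg[:, 1] = bg[:, 0]
    x = np.array([[2.0, 2.0, 1.0]])
    phi = permutation_shap(f, bg, x, component=0, n_permutations=10_000,
                           seed=3)[0]
    assert phi[0] == pytest.approx(phi[1], abs=0.05)


def test_shap_empty_background_rejected():
    with pytest.raises(ValueError, match="background"):
        permutation_shap(lambda X: X, np.empty((0, 3)), np.ones((1, 3)), 0)


# -- VIP and coefficients -----------------------------------------------------

def test_vip_uniform_weights_are_one(rng):
    # A=1 with equal-magnitude weights: every score must be exactly 1
    X = rng.normal(size=(30, 8))
    y = X.sum(axis=1)                        # symmetric dependence
    m = fit_pls1(X - X.mean(0), y, A=1)
    m.W[:, 0] = 1.0 / np.sqrt(8)             # idealised equal weights
    v = vip_scores(m)
    assert np.allclose(v, 1.0)


def test_vip_normalisation_identity(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        X = r.normal(size=(25, 12))
        y = r.normal(size=25)
        v = vip_scores(fit_pls1(X, y, A=4))
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)
        assert np.all(v >= 0)


def test_vip_matches_literal_formula_loop(rng):
    X = rng.normal(size=(30, 10))
    y = rng.normal(size=30)
    m = fit_pls1(X, y, A=3)
    v = vip_scores(m)
    N = 10
    denom = sum(m.q[a] ** 2 * (m.T[:, a] @ m.T[:, a]) for a in range(3))
    for j in range(N):
        num = sum(m.q[a] ** 2 * (m.T[:, a] @ m.T[:, a])
                  * (m.W[j, a] / np.linalg.norm(m.W[:, a])) ** 2
                  for a in range(3))
        assert v[j] == pytest.approx(np.sqrt(N * num / denom), abs=1e-10)


def test_coefficients_linear_in_y_and_predictive(rng):
    X = rng.normal(size=(25, 9))
    y = rng.normal(size=25)
    m1 = fit_pls1(X, y, A=3)
    m2 = fit_pls1(X, 2.0 * y, A=3)
    assert np.allclose(2.0 * m1.beta, m2.beta)
    res = pls_coefficients(m1)
    direct = (X - m1.x_mean) @ res.values + m1.y_mean
    assert np.abs(direct - predict_pls1(m1, X)).max() < 1e-10


def test_coefficients_localise_informative_channel(rng):
    from lsaspec import SGFConfig
    X = rng.normal(size=(60, 31))
    y = 5.0 * X[:, 15]
    m = fit_pls1(X, y, A=2, sgf=SGFConfig(window=5, deriv=0))
    beta = np.abs(pls_coefficients(m).values)
    assert np.argmax(beta) == 15
    inside = beta[13:18].mean()
    outside = np.concatenate([beta[:11], beta[20:]]).mean()
    assert inside > 3 * outside
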