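"""Unit and property tests for the LSA augmentation pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsaspec import (LSAConfig, augment_dataset, estimate_pure_components,
                     fit_sampler, perturb_spectrum, reconstruction_cv,
                     sample_concentrations, select_local_subset,
                     synthesize_spectrum, tune_lsa)


# -- concentration sampling --------------------------------------------------

def test_uniform_sampler_degenerate_range_is_constant(rng):
    Y = np.full((5, 1), 3.25)
    s = fit_sampler(Y, mode="uniform")
    draws = sample_concentrations(s, 100, seed=0)
    assert np.all(draws == 3.25)


def test_kde_sampler_recovers_mean(rng):
    Y = rng.normal(5.0, 1.0, size=(2000, 1))
    s = fit_sampler(Y, mode="KDE")
    draws = sample_concentrations(s, 10_000, seed=1)
    assert abs(draws.mean() - 5.0) < 0.05


def test_normal_sampler_closed_form_parameters():
    s = fit_sampler(np.array([[0.0], [2.0], [4.0]]), mode="normal")
    assert s.params[0]["mean"] == pytest.approx(2.0)
    assert s.params[0]["sd"] == pytest.approx(np.std([0, 2, 4], ddof=1))


def test_zero_variance_column_warns_and_degrades():
    Y = np.column_stack([np.full(10, 1.5), np.arange(10.0)])
    with pytest.warns(UserWarning, match="zero variance"):
        s = fit_sampler(Y, mode="KDE")
    draws = sample_concentrations(s, 50, seed=0)
    assert np.all(draws[:, 0] == 1.5)


def test_sampling_empty_and_deterministic(rng):
    Y = rng.uniform(1, 4, size=(30, 2))
    s = fit_sampler(Y, mode="KDE")
    assert sample_concentrations(s, 0, seed=0).shape == (0, 2)
    a = sample_concentrations(s, 200, seed=9)
    b = sample_concentrations(s, 200, seed=9)
    assert np.array_equal(a, b)


def test_no_clamping_when_data_far_from_zero(rng):
    Y = rng.normal(50.0, 1.0, size=(500, 1))
    s = fit_sampler(Y, mode="KDE")
    draws = sample_concentrations(s, 10_000, seed=2)
    assert np.all(draws > 0)
    assert (draws == 0).sum() == 0


# -- local subset selection --------------------------------------------------

def test_nearest_point_selected():
    Y = np.array([[0.0], [1.0], [2.0]])
    assert select_local_subset(Y, np.array([0.9]), 1, l=2)[0] == 1


def test_norm_order_changes_selection():
    Y = np.array([[3.0, 0.0], [2.0, 2.0]])
    y = np.array([0.0, 0.0])
    assert select_local_subset(Y, y, 1, l=1)[0] == 0      # distances 3 vs 4
    assert select_local_subset(Y, y, 1, l=2)[0] == 1      # 3 vs 2.828


def test_ties_broken_by_row_index():
    Y = np.array([[1.0], [1.0], [1.0]])
    idx = select_local_subset(Y, np.array([1.0]), 2, l=2)
    assert list(idx) == [0, 1]


def test_n_lsa_exceeding_m_rejected():
    with pytest.raises(ValueError, match="n_lsa"):
        select_local_subset(np.ones((3, 1)), np.array([1.0]), 4)


@pytest.mark.parametrize("l", [1, 2])
def test_matches_exhaustive_sort_oracle(l, rng):
    for _ in range(250):
        M = int(rng.integers(2, 30))
        P = int(rng.integers(1, 4))
        n = int(rng.integers(1, M + 1))
        Y = rng.normal(size=(M, P))
        y = rng.normal(size=P)
        got = select_local_subset(Y, y, n, l=l)
        d = np.sum(np.abs(Y - y) ** l, axis=1) ** (1.0 / l)
        expected = sorted(range(M), key=lambda i: (d[i], i))[:n]
        assert list(got) == expected


# -- pure-component estimation -----------------------------------------------

def test_identity_design_returns_rows():
    X = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    prof = estimate_pure_components(X, np.eye(2), "OLS")
    assert np.allclose(prof.S[:, 0], X[0]) and np.allclose(prof.S[:, 1], X[1])


def test_nnls_clips_negative_coefficient():
    X, Y = np.array([[-0.5]]), np.array([[1.0]])
    assert estimate_pure_components(X, Y, "OLS").S[0, 0] == pytest.approx(-0.5)
    assert estimate_pure_components(X, Y, "NNLS").S[0, 0] == 0.0


@pytest.mark.parametrize("solver", ["OLS", "NNLS"])
def test_noise_free_recovery_vs_normal_equations(solver, rng):
    Y = rng.uniform(0.5, 3.0, size=(20, 5))
    S_true = rng.uniform(0.0, 2.0, size=(40, 5))
    X = Y @ S_true.T
    prof = estimate_pure_components(X, Y, solver)
    assert np.abs(prof.S - S_true).max() < 1e-8
    # independent oracle: normal equations
    S_ne = np.linalg.solve(Y.T @ Y, Y.T @ X).T
    assert np.abs(prof.S - S_ne).max() < 1e-8


def test_all_zero_concentrations_rejected():
    with pytest.raises(np.linalg.LinAlgError, match="all-zero"):
        estimate_pure_components(np.ones((3, 4)), np.zeros((3, 2)), "OLS")


def test_nnls_nonnegative_and_matches_ols_when_feasible(rng):
    for _ in range(200):
        # full-column-rank designs: the unconstrained minimiser is unique,
        # so a feasible OLS solution must coincide with NNLS
        P = int(rng.integers(1, 4))
        n = int(rng.integers(P + 1, 8))
        Y = rng.uniform(0.1, 2.0, size=(n, P))
        X = rng.normal(size=(n, 3))
        s_nnls = estimate_pure_components(X, Y, "NNLS").S
        s_ols = estimate_pure_components(X, Y, "OLS").S
        assert np.all(s_nnls >= 0)
        feasible = np.all(s_ols >= 0, axis=1)
        if feasible.any():
            assert np.abs(s_nnls[feasible] - s_ols[feasible]).max() < 1e-8


# -- synthesis and perturbation ----------------------------------------------

def test_synthesis_basis_null_and_linearity(rng):
    S = rng.normal(size=(10, 3))
    assert np.allclose(synthesize_spectrum(S, np.array([0, 1, 0])), S[:, 1])
    assert np.all(synthesize_spectrum(S, np.zeros(3)) == 0)
    y1, y2 = rng.normal(size=3), rng.normal(size=3)
    lhs = synthesize_spectrum(S, 2.0 * y1 + 0.5 * y2)
    rhs = 2.0 * synthesize_spectrum(S, y1) + 0.5 * synthesize_spectrum(S, y2)
    assert np.abs(lhs - rhs).max() < 1e-12
    with pytest.raises(ValueError, match="components"):
        synthesize_spectrum(S, np.ones(4))


def test_perturb_identity_when_sigmas_zero(rng):
    x = rng.normal(size=20)
    wl = np.arange(20.0)
    assert np.array_equal(perturb_spectrum(x, wl, 0.0, 0.0, rng), x)


def test_exact_grid_shift(rng):
    x = rng.normal(size=15)
    wl = np.arange(15.0)
    out = perturb_spectrum(x, wl, 0.0, 1.0, rng, shift=1.0)
    assert np.allclose(out[1:], x[:-1])
    assert out[0] == x[0]                      # edge held


def test_noise_sd_matches_nominal(rng):
    x = np.zeros(100)
    wl = np.arange(100.0)
    reps = np.stack([perturb_spectrum(x, wl, 0.2, 0.0, rng)
                     for _ in range(200)])
    assert np.std(reps) == pytest.approx(0.2, rel=0.05)


# -- end-to-end augmentation -------------------------------------------------

def test_augment_bookkeeping_and_determinism(ds_small_noisy):
    ds, _ = ds_small_noisy
    cfg = LSAConfig(n_lsa=5, n_gen=3, seed=4)
    aug = augment_dataset(ds, cfg)
    assert aug.X_star.shape == (3, ds.n_wavelengths)
    assert aug.Y_star.shape == (3, ds.n_components)
    assert np.isfinite(aug.X_star).all()
    aug2 = augment_dataset(ds, cfg)
    assert np.array_equal(aug.X_star, aug2.X_star)
    assert np.array_equal(aug.Y_star, aug2.Y_star)


@pytest.mark.parametrize("solver", ["OLS", "NNLS"])
def test_noise_free_generation_matches_ground_truth(ds_small, solver):
    ds, pure = ds_small
    cfg = LSAConfig(n_lsa=8, n_gen=50, solver=solver, seed=1)
    aug = augment_dataset(ds, cfg)
    expected = aug.Y_star @ pure.S.T
    assert np.abs(aug.X_star - expected).max() < 1e-6


# -- reconstruction CV and tuning --------------------------------------------

def test_reconstruction_exact_on_noise_free_data(ds_small):
    ds, _ = ds_small
    for solver in ("OLS", "NNLS"):
        rmsecv, resid = reconstruction_cv(
            ds, LSAConfig(n_lsa=6, solver=solver))
        assert rmsecv < 1e-6
        assert resid.shape == ds.X.shape


def test_reconstruction_tracks_noise_floor():
    from lsaspec import ds1_like, make_dataset
    s = 0.01
    ds, _ = make_dataset(ds1_like(noise_sd=s, seed=2))
    assert ds.n_samples * ds.n_wavelengths >= 1e4
    rmsecv, _ = reconstruction_cv(ds, LSAConfig(n_lsa=12))
    assert s / 2 < rmsecv < 2 * s


def test_reconstruction_single_group_rejected(ds_small):
    ds, _ = ds_small
    solo = ds.subset(ds.groups == ds.group_labels()[0])
    with pytest.raises(ValueError, match="2 groups"):
        reconstruction_cv(solo, LSAConfig())


def test_reconstruction_monotone_in_noise():
    from conftest import small_spec
    from lsaspec import make_dataset
    med = []
    for s in (0.0, 0.005, 0.05):
        vals = []
        for seed in (1, 2, 3):
            ds, _ = make_dataset(small_spec(noise_sd=s, seed=seed))
            r, _ = reconstruction_cv(ds, LSAConfig(n_lsa=8))
            vals.append(r)
        med.append(np.median(vals))
    assert med[0] <= med[1] <= med[2]


def test_tune_lsa_table_and_selection(ds_small):
    ds, _ = ds_small
    best, table = tune_lsa(ds, {"n_lsa": [3, 30]})
    assert len(table) == 2
    assert {row["n_lsa"] for row in table} == {3, 30}
    assert best.n_lsa in (3, 30)


def test_tune_lsa_prefers_generating_configuration(ds_small_noisy):
    # on bilinear data with mild noise a large subset averages the noise
    # away, so the global-limit configuration should win over a tiny subset
    ds, _ = ds_small_noisy
    best, table = tune_lsa(ds, {"n_lsa": [2, ds.n_samples]})
    assert best.n_lsa == ds.n_samples


def test_tune_lsa_empty_grid_rejected(ds_small):
    ds, _ = ds_small
    with pytest.raises(ValueError, match="grid"):
        tune_lsa(ds, {})


# -- config validation --------------------------------------------------------

@given(st.sampled_from(["n_lsa", "l", "solver", "sigma_noise", "n_gen",
                        "sampler_mode"]))
@settings(max_examples=12, deadline=None)
def test_invalid_configs_rejected(fieldname):
    bad = {"n_lsa": 0, "l": 3, "solver": "QR", "sigma_noise": -1.0,
           "n_gen": 0, "sampler_mode": "copula"}[fieldname]
    with pytest.raises(ValueError):
        LSAConfig(**{fieldname: bad})
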