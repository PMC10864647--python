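"""Shared fixtures: synthetic chromatography data sets of various sizes."""

import logging

import numpy as np
import pytest

from lsaspec import SyntheticSpec, ds1_like, make_dataset

# silence expected rank-deficiency warnings from tiny local subsets
logging.getLogger("lsaspec.augment").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ds1_clean():
    """Noise-free 225-sample, 5-group, 3-component, 61-wavelength set."""
    ds, pure = make_dataset(ds1_like(noise_sd=0.0, seed=11))
    return ds, pure


@pytest.fixture(scope="session")
def ds1_noisy():
    """Same layout with 0.001-absorbance-unit cell noise."""
    ds, pure = make_dataset(ds1_like(noise_sd=0.001, seed=11))
    return ds, pure


def small_spec(noise_sd=0.0, seed=5, n_fractions=20, n_groups=3):
    """Compact 2-component generator for fast protocol tests."""
    band_params = [
        [(250.0, 8.0, 1.0), (275.0, 6.0, 0.6)],
        [(260.0, 7.0, 0.8), (288.0, 7.0, 0.9)],
    ]
    elution = []
    for e in range(n_groups):
        shift = 1.5 * e
        elution.append([
            (6.0 + shift, 3.0, 1.2 + 0.1 * e),
            (12.0 + shift, 3.5, 1.5 + 0.1 * e),
        ])
    return SyntheticSpec(band_params=band_params, elution_params=elution,
                         n_fractions=n_fractions, noise_sd=noise_sd,
                         seed=seed)


@pytest.fixture(scope="session")
def ds_small():
    """60-sample, 3-group, 2-component set (noise-free)."""
    ds, pure = make_dataset(small_spec())
    return ds, pure


@pytest.fixture(scope="session")
def ds_small_noisy():
    ds, pure = make_dataset(small_spec(noise_sd=0.001))
    return ds, pure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
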