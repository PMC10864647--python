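"""Synthetic chromatography-like spectral data with known ground truth.

Emulates fraction analytics of preparative protein chromatography monitored
by UV/Vis spectroscopy: per experiment, each component elutes as a Gaussian
concentration peak over the fraction index; each component has a smooth
pure-component absorbance spectrum built from Gaussian absorption bands; the
recorded spectra follow Beer-Lambert bilinear mixing

    X = Y . S_true^T + baseline + noise,

with homoscedastic Gaussian cell noise and an optional linear baseline.
Because the generating pure spectra ``S_true`` are known, every downstream
stage (pure-component estimation, augmentation, regression) can be tested
against exact ground truth.

The ``ds1_like`` preset mirrors the scale of a typical three-protein
chromatography calibration set: 3 components, 5 experiments of 45 fractions
(225 samples), 61 wavelengths on a 240-300 nm grid at 1 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import PureComponentProfiles
from .dataset import SpectralDataset

__all__ = [
    "SyntheticSpec",
    "make_pure_spectra",
    "make_concentration_profiles",
    "make_dataset",
    "ds1_like",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic chromatography generator.

    band_params: per component, a list of (center_nm, width_nm, height)
        Gaussian absorption bands; height is absorbance per unit
        concentration at the band center.
    elution_params: per experiment, per component, a tuple
        (retention_fraction, peak_width_fractions, peak_height_conc).
    """

    wavelength_start: float = 240.0
    wavelength_stop: float = 300.0
    wavelength_step: float = 1.0
    band_params: list[list[tuple[float, float, float]]] = field(default_factory=list)
    elution_params: list[list[tuple[float, float, float]]] = field(default_factory=list)
    n_fractions: int = 45
    noise_sd: float = 0.001
    baseline_slope: float = 0.0
    conc_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength_step <= 0:
            raise ValueError("wavelength_step must be > 0")
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if not self.band_params:
            raise ValueError("band_params must define at least one component")
        for p, bands in enumerate(self.band_params):
            if not bands:
                raise ValueError(f"component {p} has an empty band list")
            for c, w, h in bands:
                if w <= 0:
                    raise ValueError(f"component {p}: band width must be > 0")
                if h < 0:
                    raise ValueError(f"component {p}: band height must be >= 0")
        if not self.elution_params:
            raise ValueError("elution_params must define at least one experiment")
        n_comp = len(self.band_params)
        for e, comps in enumerate(self.elution_params):
            if len(comps) != n_comp:
                raise ValueError(
                    f"experiment {e}: expected {n_comp} elution tuples, got {len(comps)}"
                )
            for rt, w, h in comps:
                if w <= 0:
                    raise ValueError(f"experiment {e}: peak width must be > 0")
                if h < 0:
                    raise ValueError(f"experiment {e}: peak height must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wavelength_stop - self.wavelength_start)
                      / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)

    @property
    def n_components(self) -> int:
        return len(self.band_params)

    @property
    def n_experiments(self) -> int:
        return len(self.elution_params)


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def make_pure_spectra(spec: SyntheticSpec) -> PureComponentProfiles:
    """Ground-truth pure-component spectra S_true (N x P), sums of Gaussian bands."""
    wl = spec.wavelengths
    cols = []
    for bands in spec.band_params:
        col = np.zeros_like(wl)
        for center, width, height in bands:
            col += height * _gaussian(wl, center, width)
        cols.append(col)
    S = np.column_stack(cols)
    return PureComponentProfiles(S=S, wavelengths=wl, scope="global")


def make_concentration_profiles(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Elution concentration matrix Y (M x P) and experiment group labels (M,).

    Within each experiment, component p follows a Gaussian elution peak over
    the fraction index.  M = n_experiments * n_fractions.  Values below
    ``conc_floor`` are reported as 0, emulating the quantification limit of
    the reference fraction analytics (spectra are mixed from the *reported*
    concentrations, so the bilinear model stays exact).
    """
    frac = np.arange(spec.n_fractions, dtype=float)
    blocks, groups = [], []
    for e, comps in enumerate(spec.elution_params):
        Y_e = np.column_stack(
            [h * _gaussian(frac, rt, w) for rt, w, h in comps]
        )
        Y_e[Y_e < spec.conc_floor] = 0.0
        blocks.append(Y_e)
        groups.extend([f"exp{e}"] * spec.n_fractions)
    return np.vstack(blocks), np.array(groups)


def make_dataset(spec: SyntheticSpec) -> tuple[SpectralDataset, PureComponentProfiles]:
    """Full synthetic data set: X = Y.S_true^T + baseline + N(0, noise_sd).

    Reproducible under ``spec.seed``.  Returns the data set and the
    generating pure-component profiles.
    """
    rng = np.random.default_rng(spec.seed)
    pure = make_pure_spectra(spec)
    Y, groups = make_concentration_profiles(spec)
    X = Y @ pure.S.T
    if spec.baseline_slope != 0.0:
        X = X + spec.baseline_slope * (spec.wavelengths - spec.wavelength_start)
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
    ds = SpectralDataset(
        X=X,
        Y=Y,
        wavelengths=spec.wavelengths,
        component_names=[f"comp{p}" for p in range(spec.n_components)],
        groups=groups,
    )
    return ds, pure


def ds1_like(noise_sd: float = 0.001, baseline_slope: float = 0.0,
             seed: int = 0, n_fractions: int = 45) -> SyntheticSpec:
    """Preset mirroring a three-protein UV/Vis chromatography calibration set.

    3 components with overlapping aromatic-like absorption bands on a
    240-300 nm / 1 nm grid (61 features), 5 experiments of ``n_fractions``
    fractions with experiment-to-experiment retention shifts (225 samples at
    the default), homoscedastic cell noise of ``noise_sd`` absorbance units.
    """
    # Overlapping but distinguishable bands, loosely protein-like: a strong
    # far-UV edge plus an aromatic band with component-specific position.
    band_params = [
        [(245.0, 8.0, 1.2), (278.0, 7.0, 0.8)],   # comp0
        [(248.0, 9.0, 1.0), (270.0, 6.0, 1.1)],   # comp1
        [(243.0, 7.0, 0.9), (288.0, 8.0, 0.7)],   # comp2
    ]
    # Five runs with shifted, partially overlapping elution peaks.  The
    # fraction window spans the elution region (as fraction analytics of an
    # elution peak does), so every collected fraction carries appreciable
    # analyte and no sample is pure baseline.
    elution_params = []
    for e in range(5):
        shift = 2.0 * e
        scale = 1.0 + 0.1 * e
        elution_params.append([
            (8.0 + shift, 6.0, 1.5 * scale),
            (21.0 + shift, 6.0, 2.0 * scale),
            (34.0 + shift, 6.0, 1.2 * scale),
        ])
    return SyntheticSpec(
        band_params=band_params,
        elution_params=elution_params,
        n_fractions=n_fractions,
        noise_sd=noise_sd,
        baseline_slope=baseline_slope,
        seed=seed,
    )
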