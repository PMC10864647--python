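"""Local subset augmentation (LSA) of spectral calibration data.

LSA generates realistic in-silico absorbance spectra from a small
experimental calibration set by exploiting Beer-Lambert bilinearity:

1. *Concentration sampling* — the marginal distribution of each component's
   concentration is approximated (Gaussian KDE by default) and a random
   concentration vector ``y*`` is drawn.
2. *Local subset selection* — the ``n_lsa`` calibration samples whose
   concentration vectors are nearest to ``y*`` (l1 or l2 norm) form a local
   subset (X~, Y~).
3. *Spectrum synthesis* — per-unit-concentration pure-component profiles
   ``S~`` (N x P) are estimated from the local subset by classical least
   squares, X~ ≈ Y~ S~^T, solved independently per wavelength with an OLS or
   NNLS solver, and the new spectrum is the bilinear mix ``x* = S~ y*``.
   Gaussian white noise (per feature) and a normally distributed wavelength
   shift (per spectrum) add instrument-like variation.

Because the profiles are estimated *locally*, the method adapts to
concentration-dependent deviations from a single global bilinear model
(detector nonlinearity, noise regimes, co-eluting background).

The quality of the augmentation is measured by a leave-one-group-out
reconstruction cross-validation: each experimental spectrum is re-synthesised
at its measured concentrations from the other experiments' data only, and the
residuals are summarised as an RMSECV.  ``tune_lsa`` grid-searches the LSA
hyperparameters against this criterion.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls as _scipy_nnls
from scipy.stats import gaussian_kde

from .dataset import SpectralDataset

__all__ = [
    "LSAConfig",
    "PureComponentProfiles",
    "ConcentrationSampler",
    "AugmentedDataset",
    "fit_sampler",
    "sample_concentrations",
    "select_local_subset",
    "estimate_pure_components",
    "synthesize_spectrum",
    "perturb_spectrum",
    "augment_dataset",
    "reconstruction_cv",
    "tune_lsa",
]

logger = logging.getLogger(__name__)


@dataclass
class LSAConfig:
    """Hyperparameters of the LSA method.

    n_lsa: local subset size; l: distance-norm order (1 = cityblock,
    2 = euclidean); solver: 'OLS' or 'NNLS'; sigma_noise in absorbance
    units; sigma_shift in wavelength units; n_gen: number of generated
    samples; sampler_mode: 'KDE', 'uniform' or 'normal'.
    """

    n_lsa: int = 5
    l: int = 2
    solver: str = "NNLS"
    sigma_noise: float = 0.0
    sigma_shift: float = 0.0
    n_gen: int = 1000
    sampler_mode: str = "KDE"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lsa < 1:
            raise ValueError("n_lsa must be >= 1")
        if self.l not in (1, 2):
            raise ValueError("norm order l must be 1 or 2")
        if self.solver.upper() not in ("OLS", "NNLS"):
            raise ValueError("solver must be 'OLS' or 'NNLS'")
        if self.sigma_noise < 0 or self.sigma_shift < 0:
            raise ValueError("sigma_noise and sigma_shift must be >= 0")
        if self.n_gen < 1:
            raise ValueError("n_gen must be >= 1")
        if self.sampler_mode.upper() not in ("KDE", "UNIFORM", "NORMAL"):
            raise ValueError("sampler_mode must be 'KDE', 'uniform' or 'normal'")
        self.solver = self.solver.upper()
        self.sampler_mode = self.sampler_mode.upper()


@dataclass
class PureComponentProfiles:
    """Per-unit-concentration absorbance estimates S (N x P)."""

    S: np.ndarray
    wavelengths: np.ndarray
    scope: str = "local"  # 'local' or 'global'

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.S.ndim != 2:
            raise ValueError("S must be N x P")
        if self.S.shape[0] != self.wavelengths.size:
            raise ValueError("S row count must match wavelength axis length")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("S contains non-finite entries")


@dataclass
class AugmentedDataset:
    """Generated (X*, Y*) pairs with the configuration that produced them."""

    X_star: np.ndarray
    Y_star: np.ndarray
    config: LSAConfig
    source_fingerprint: str = ""

    @property
    def n_samples(self) -> int:
        return self.X_star.shape[0]


# ---------------------------------------------------------------------------
# concentration sampling
# ---------------------------------------------------------------------------

class ConcentrationSampler:
    """Per-component univariate concentration sampler (KDE/uniform/normal).

    Components are sampled independently; cross-component correlation in the
    calibration data is not preserved (deliberate: it widens the sampled
    composition space beyond the correlated elution trajectories).
    """

    def __init__(self, mode: str, params: list[dict]):
        self.mode = mode.upper()
        self.params = params  # one dict per component

    @property
    def n_components(self) -> int:
        return len(self.params)

    def _draw_component(self, p: int, n: int, rng: np.random.Generator) -> np.ndarray:
        par = self.params[p]
        if par.get("point") is not None:
            return np.full(n, par["point"], dtype=float)
        if self.mode == "KDE":
            return par["kde"].resample(n, seed=rng)[0]
        if self.mode == "UNIFORM":
            return rng.uniform(par["low"], par["high"], size=n)
        return rng.normal(par["mean"], par["sd"], size=n)

    def sample(self, n: int, rng: np.random.Generator,
               max_redraws: int = 100) -> np.ndarray:
        """Draw n concentration vectors (n x P), all entries >= 0.

        Negative draws are rejected and redrawn per component up to
        ``max_redraws`` rounds, then clamped to 0.
        """
        out = np.empty((n, self.n_components), dtype=float)
        for p in range(self.n_components):
            col = self._draw_component(p, n, rng)
            for _ in range(max_redraws):
                neg = col < 0
                if not neg.any():
                    break
                col[neg] = self._draw_component(p, int(neg.sum()), rng)
            np.clip(col, 0.0, None, out=col)
            out[:, p] = col
        return out


def fit_sampler(Y: np.ndarray, mode: str = "KDE",
                seed: int | None = None) -> ConcentrationSampler:
    """Fit a per-component concentration sampler on a concentration matrix.

    KDE mode uses a univariate Gaussian kernel-density estimate per column
    (Scott's-rule bandwidth); uniform mode uses the per-column [min, max]
    range; normal mode the per-column (mean, sample SD).  A zero-variance
    column degrades to a point mass with a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mode_u = mode.upper()
    if mode_u not in ("KDE", "UNIFORM", "NORMAL"):
        raise ValueError("mode must be 'KDE', 'uniform' or 'normal'")
    if mode_u in ("KDE", "NORMAL") and Y.shape[0] < 2:
        raise ValueError(f"{mode} sampler needs at least 2 samples")
    params: list[dict] = []
    for p in range(Y.shape[1]):
        col = Y[:, p]
        if mode_u in ("KDE", "NORMAL") and np.ptp(col) == 0:
            warnings.warn(
                f"component {p} has zero variance; sampler degrades to a "
                f"point mass at {col[0]}", stacklevel=2)
            params.append({"point": float(col[0])})
            continue
        if mode_u == "KDE":
            params.append({"point": None, "kde": gaussian_kde(col)})
        elif mode_u == "UNIFORM":
            params.append({"point": None, "low": float(col.min()),
                           "high": float(col.max())})
        else:
            params.append({"point": None, "mean": float(col.mean()),
                           "sd": float(col.std(ddof=1))})
    return ConcentrationSampler(mode_u, params)


def sample_concentrations(sampler: ConcentrationSampler, n: int,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw n concentration vectors from a fitted sampler (reproducible)."""
    if n == 0:
        return np.empty((0, sampler.n_components))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return sampler.sample(n, rng)


# ---------------------------------------------------------------------------
# subset selection and pure-component estimation
# ---------------------------------------------------------------------------

def select_local_subset(Y: np.ndarray, y_star: np.ndarray, n_lsa: int,
                        l: int = 2) -> np.ndarray:
    """Indices of the n_lsa rows of Y nearest to y_star in the l-norm.

    Returned in ascending-distance order; exact ties broken by ascending
    row index (stable sort).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    y_star = np.asarray(y_star, dtype=float).ravel()
    if n_lsa > Y.shape[0]:
        raise ValueError(f"n_lsa={n_lsa} exceeds sample count M={Y.shape[0]}")
    diff = Y - y_star
    if l == 1:
        d = np.abs(diff).sum(axis=1)
    elif l == 2:
        d = np.sqrt((diff**2).sum(axis=1))
    else:
        raise ValueError("norm order l must be 1 or 2")
    order = np.argsort(d, kind="stable")
    return order[:n_lsa]


def estimate_pure_components(X_sub: np.ndarray, Y_sub: np.ndarray,
                             solver: str = "NNLS",
                             wavelengths: np.ndarray | None = None,
                             scope: str = "local") -> PureComponentProfiles:
    """Classical least-squares estimate of pure-component profiles.

    Finds S~ (N x P) minimising ||X_sub - Y_sub S~^T||_F^2, one independent
    P-dimensional least-squares problem per wavelength.  NNLS constrains
    every coefficient to be >= 0; rank-deficient OLS returns the
    minimum-norm solution (with a logged warning).
    """
    X_sub = np.atleast_2d(np.asarray(X_sub, dtype=float))
    Y_sub = np.atleast_2d(np.asarray(Y_sub, dtype=float))
    if X_sub.shape[0] != Y_sub.shape[0]:
        raise ValueError("X_sub and Y_sub row counts differ")
    if not np.any(Y_sub):
        raise np.linalg.LinAlgError(
            f"all-zero concentration subset ({Y_sub.shape[0]} samples); "
            "pure-component profiles are unidentifiable")
    n, N = X_sub.shape
    P = Y_sub.shape[1]
    solver = solver.upper()
    if solver == "OLS":
        B, _, rank, _ = np.linalg.lstsq(Y_sub, X_sub, rcond=None)
        if rank < P:
            logger.warning(
                "rank-deficient local subset (rank %d < P=%d); "
                "minimum-norm OLS solution used", rank, P)
        S = B.T
    elif solver == "NNLS":
        S = np.empty((N, P))
        for j in range(N):
            S[j], _ = _scipy_nnls(Y_sub, X_sub[:, j])
    else:
        raise ValueError("solver must be 'OLS' or 'NNLS'")
    if wavelengths is None:
        wavelengths = np.arange(N, dtype=float)
    return PureComponentProfiles(S=S, wavelengths=wavelengths, scope=scope)


def synthesize_spectrum(S: PureComponentProfiles | np.ndarray,
                        y_star: np.ndarray) -> np.ndarray:
    """Bilinear mix x* = S~ y* of pure-component profiles."""
    S_mat = S.S if isinstance(S, PureComponentProfiles) else np.asarray(S, float)
    y_star = np.asarray(y_star, dtype=float).ravel()
    if S_mat.shape[1] != y_star.size:
        raise ValueError(
            f"profile has {S_mat.shape[1]} components but y* has {y_star.size}")
    return S_mat @ y_star


def perturb_spectrum(x: np.ndarray, wavelengths: np.ndarray,
                     sigma_noise: float, sigma_shift: float,
                     rng: np.random.Generator,
                     shift: float | None = None) -> np.ndarray:
    """Wavelength shift then white noise.

    One shift delta ~ N(0, sigma_shift) is drawn per spectrum and the
    spectrum re-evaluated at ``wavelengths - delta`` by linear interpolation
    (edge values held); then i.i.d. N(0, sigma_noise) noise is added per
    feature.  ``shift`` overrides the random draw (testing hook).
    """
    x = np.asarray(x, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if sigma_noise < 0 or sigma_shift < 0:
        raise ValueError("sigma values must be >= 0")
    out = x
    if shift is None:
        shift = rng.normal(0.0, sigma_shift) if sigma_shift > 0 else 0.0
    if shift != 0.0:
        out = np.interp(wavelengths - shift, wavelengths, x)
    if sigma_noise > 0:
        out = out + rng.normal(0.0, sigma_noise, size=x.shape)
    return np.array(out, dtype=float, copy=True)


# ---------------------------------------------------------------------------
# end-to-end augmentation
# ---------------------------------------------------------------------------

class _ProfileCache:
    """Memoises pure-component estimates per selected subset.

    Nearby concentration draws select identical local subsets, so the same
    least-squares problem recurs; caching is exact (keyed on the index
    tuple) and changes no result.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray, solver: str,
                 wavelengths: np.ndarray):
        self.X, self.Y = X, Y
        self.solver = solver
        self.wavelengths = wavelengths
        self._cache: dict[tuple, PureComponentProfiles] = {}

    def get(self, idx: np.ndarray) -> PureComponentProfiles:
        key = tuple(sorted(int(i) for i in idx))
        hit = self._cache.get(key)
        if hit is None:
            hit = estimate_pure_components(
                self.X[idx], self.Y[idx], self.solver,
                wavelengths=self.wavelengths)
            self._cache[key] = hit
        return hit


def augment_dataset(ds: SpectralDataset, cfg: LSAConfig) -> AugmentedDataset:
    """Generate cfg.n_gen in-silico (spectrum, concentration) pairs by LSA.

    For each draw: sample y* from the fitted concentration sampler, select
    the local subset, estimate pure-component profiles, synthesise
    ``x* = S~ y*`` and apply the configured perturbation.  Deterministic
    under ``cfg.seed``.  n_lsa is capped at M (using every sample equals the
    global classical least-squares estimate).
    """
    n_lsa = min(cfg.n_lsa, ds.n_samples)
    rng = np.random.default_rng(cfg.seed)
    sampler = fit_sampler(ds.Y, cfg.sampler_mode)
    Y_star = sample_concentrations(sampler, cfg.n_gen, rng)
    cache = _ProfileCache(ds.X, ds.Y, cfg.solver, ds.wavelengths)
    X_star = np.empty((cfg.n_gen, ds.n_wavelengths))
    for g in range(cfg.n_gen):
        try:
            idx = select_local_subset(ds.Y, Y_star[g], n_lsa, cfg.l)
            profiles = cache.get(idx)
            x = synthesize_spectrum(profiles, Y_star[g])
            X_star[g] = perturb_spectrum(
                x, ds.wavelengths, cfg.sigma_noise, cfg.sigma_shift, rng)
        except Exception as exc:
            raise RuntimeError(f"augmentation failed at generated sample {g}: "
                               f"{exc}") from exc
    fingerprint = f"M={ds.n_samples},N={ds.n_wavelengths},P={ds.n_components}"
    return AugmentedDataset(X_star=X_star, Y_star=Y_star, config=cfg,
                            source_fingerprint=fingerprint)


def reconstruction_cv(ds: SpectralDataset, cfg: LSAConfig,
                      apply_perturbation: bool = True,
                      clamp_n_lsa: bool = True
                      ) -> tuple[float, np.ndarray]:
    """Leave-one-group-out reconstruction error of the LSA method.

    For every held-out sample, the local subset and pure-component profiles
    are estimated from the retained groups only and the spectrum is
    re-synthesised at the sample's measured concentrations; the residual is
    synthesised minus measured.  Returns (RMSECV, residual matrix M x N
    aligned with ds rows).  With ``apply_perturbation`` the configured
    noise/shift is applied to the synthesised spectra (identity when both
    sigmas are 0).  ``clamp_n_lsa`` caps n_lsa at the retained sample count
    of each rotation (otherwise a too-small rotation raises).
    """
    labels = ds.group_labels()
    if len(labels) < 2:
        raise ValueError("reconstruction_cv needs at least 2 groups")
    rng = np.random.default_rng(cfg.seed)
    residuals = np.empty_like(ds.X)
    for label in labels:
        held = ds.groups == label
        retained = ~held
        m_ret = int(retained.sum())
        n_lsa = cfg.n_lsa
        if n_lsa > m_ret:
            if not clamp_n_lsa:
                raise ValueError(
                    f"rotation holding out group {label!r}: retained data has "
                    f"{m_ret} samples < n_lsa={cfg.n_lsa}")
            n_lsa = m_ret
        X_ret, Y_ret = ds.X[retained], ds.Y[retained]
        cache = _ProfileCache(X_ret, Y_ret, cfg.solver, ds.wavelengths)
        for i in np.flatnonzero(held):
            idx = select_local_subset(Y_ret, ds.Y[i], n_lsa, cfg.l)
            x_hat = synthesize_spectrum(cache.get(idx), ds.Y[i])
            if apply_perturbation:
                x_hat = perturb_spectrum(x_hat, ds.wavelengths,
                                         cfg.sigma_noise, cfg.sigma_shift, rng)
            residuals[i] = x_hat - ds.X[i]
    rmsecv = float(np.sqrt(np.mean(residuals**2)))
    return rmsecv, residuals


def tune_lsa(ds: SpectralDataset, grid: dict,
             base: LSAConfig | None = None,
             apply_perturbation: bool = True) -> tuple[LSAConfig, list[dict]]:
    """Exhaustive grid search of LSA hyperparameters by reconstruction RMSECV.

    ``grid`` maps any subset of {'n_lsa', 'l', 'solver', 'sigma_noise',
    'sigma_shift'} to value lists; unlisted parameters come from ``base``.
    Returns the argmin configuration (ties: smaller n_lsa, then l=2 first,
    then listing order) and the full results table.
    """
    allowed = {"n_lsa", "l", "solver", "sigma_noise", "sigma_shift"}
    if not grid or not any(grid.get(k) for k in allowed):
        raise ValueError("grid must list values for at least one hyperparameter")
    unknown = set(grid) - allowed
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")
    base = base or LSAConfig()
    keys = [k for k in ("n_lsa", "l", "solver", "sigma_noise", "sigma_shift")
            if k in grid]
    table: list[dict] = []
    for listing_idx, values in enumerate(
            itertools.product(*(grid[k] for k in keys))):
        cfg = replace(base, **dict(zip(keys, values)))
        rmsecv, _ = reconstruction_cv(ds, cfg,
                                      apply_perturbation=apply_perturbation)
        row = {k: getattr(cfg, k) for k in
               ("n_lsa", "l", "solver", "sigma_noise", "sigma_shift")}
        row["rmsecv"] = rmsecv
        row["_listing"] = listing_idx
        table.append(row)
    best = min(table, key=lambda r: (r["rmsecv"], r["n_lsa"],
                                     0 if r["l"] == 2 else 1, r["_listing"]))
    best_cfg = replace(base, **{k: best[k] for k in
                                ("n_lsa", "l", "solver", "sigma_noise",
                                 "sigma_shift")})
    for row in table:
        del row["_listing"]
    return best_cfg, table
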