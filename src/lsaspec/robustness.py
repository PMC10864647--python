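"""In-silico noise/shift robustness study for CNN and PLS models.

Two one-at-a-time sweeps perturb spectra with Gaussian white noise
(absorbance-unit SDs) or normally distributed wavelength shifts
(wavelength-unit SDs).  Two modes are compared per model type:

* **fixed** — the model is trained once on unperturbed generated data and
  evaluated on evaluation spectra perturbed at each level;
* **retrained** — the model is retrained at each level on generated data
  perturbed at that level (and evaluated on equally perturbed spectra).

Both model families are calibrated on LSA-generated data so the comparison
isolates the effect of the perturbation.  The cell summary is the sum over
components of the NRMSE on the evaluation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .augment import AugmentedDataset, LSAConfig, augment_dataset, \
    perturb_spectrum
from .cnn import CNNArchitecture, TrainingConfig, build_cnn, train_cnn
from .dataset import SpectralDataset
from .metrics import compute_metrics
from .pls import SGFConfig, fit_pls1, predict_pls1

__all__ = ["RobustnessGrid", "perturb_generated", "run_robustness_study"]


@dataclass
class RobustnessGrid:
    """Perturbation levels; defaults follow common UV/Vis noise regimes."""

    noise_levels: list[float] = field(
        default_factory=lambda: [0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0])
    shift_levels: list[float] = field(
        default_factory=lambda: [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
    modes: tuple[str, ...] = ("fixed", "retrained")
    n_seeds: int = 1

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.noise_levels + self.shift_levels):
            raise ValueError("perturbation levels must be >= 0")
        if not self.noise_levels and not self.shift_levels:
            raise ValueError("grid must contain at least one level")
        for m in self.modes:
            if m not in ("fixed", "retrained"):
                raise ValueError(f"unknown mode {m!r}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


def perturb_generated(aug: AugmentedDataset, wavelengths: np.ndarray,
                      sigma_noise: float, sigma_shift: float,
                      seed: int = 0) -> AugmentedDataset:
    """Apply noise/shift perturbation to every generated spectrum.

    Concentrations are unchanged; identity when both sigmas are 0;
    deterministic under seed.
    """
    if sigma_noise == 0 and sigma_shift == 0:
        return aug
    rng = np.random.default_rng(seed)
    X = np.stack([
        perturb_spectrum(x, wavelengths, sigma_noise, sigma_shift, rng)
        for x in aug.X_star
    ])
    return AugmentedDataset(X_star=X, Y_star=aug.Y_star.copy(),
                            config=aug.config,
                            source_fingerprint=aug.source_fingerprint)


def _perturb_matrix(X: np.ndarray, wavelengths: np.ndarray,
                    sigma_noise: float, sigma_shift: float,
                    seed: int) -> np.ndarray:
    if sigma_noise == 0 and sigma_shift == 0:
        return X
    rng = np.random.default_rng(seed)
    return np.stack([
        perturb_spectrum(x, wavelengths, sigma_noise, sigma_shift, rng)
        for x in X
    ])


def _train_cnn_on(aug: AugmentedDataset, ds: SpectralDataset,
                  arch: CNNArchitecture, train_cfg: TrainingConfig,
                  X_val: np.ndarray | None = None):
    model = build_cnn(arch, ds.n_wavelengths, ds.n_components,
                      seed=train_cfg.seed)
    train_cnn(model, aug.X_star, aug.Y_star,
              ds.X if X_val is None else X_val, ds.Y, train_cfg)
    return model.predict


def _train_pls_on(aug: AugmentedDataset, ds: SpectralDataset,
                  pls_cfgs: list[tuple[int, SGFConfig]]):
    step = float(ds.wavelengths[1] - ds.wavelengths[0])
    models = [fit_pls1(aug.X_star, aug.Y_star[:, p], A, sgf=sgf,
                       wavelength_step=step)
              for p, (A, sgf) in enumerate(pls_cfgs)]

    def predict(X):
        return np.column_stack([predict_pls1(m, X) for m in models])

    return predict


def run_robustness_study(ds: SpectralDataset, cnn_arch: CNNArchitecture,
                         lsa_cfg: LSAConfig,
                         pls_cfgs: list[tuple[int, SGFConfig]],
                         grid: RobustnessGrid,
                         train_cfg: TrainingConfig | None = None,
                         eval_ds: SpectralDataset | None = None,
                         seed: int = 0) -> list[dict]:
    """Summed-NRMSE table over model type x perturbation level x mode.

    Noise and shift axes are swept one at a time (two sweeps).  Generated
    calibration data come from ``lsa_cfg`` applied to ``ds``; evaluation is
    on ``eval_ds`` (default: ``ds`` itself) with spectra perturbed at the
    swept level.  Each cell is replicated over ``grid.n_seeds`` seeds.
    """
    train_cfg = train_cfg or TrainingConfig()
    eval_ds = eval_ds or ds
    sweeps = []
    if grid.noise_levels:
        sweeps.append(("noise", grid.noise_levels))
    if grid.shift_levels:
        sweeps.append(("shift", grid.shift_levels))

    table: list[dict] = []
    for rep in range(grid.n_seeds):
        cell_seed = seed + 7919 * rep
        aug_clean = augment_dataset(
            ds, replace(lsa_cfg, seed=lsa_cfg.seed + cell_seed))
        # fixed models: trained once on unperturbed generated data
        fixed = {}
        for model_type in ("cnn", "pls"):
            try:
                if model_type == "cnn":
                    fixed[model_type] = _train_cnn_on(
                        aug_clean, ds, cnn_arch,
                        replace(train_cfg, seed=train_cfg.seed + cell_seed))
                else:
                    fixed[model_type] = _train_pls_on(aug_clean, ds, pls_cfgs)
            except Exception as exc:
                raise RuntimeError(
                    f"fixed {model_type} training failed (seed {rep}): {exc}"
                ) from exc

        for axis, levels in sweeps:
            for li, level in enumerate(levels):
                s_noise = level if axis == "noise" else 0.0
                s_shift = level if axis == "shift" else 0.0
                X_eval = _perturb_matrix(eval_ds.X, eval_ds.wavelengths,
                                         s_noise, s_shift,
                                         seed=cell_seed + 131 * li)
                for model_type in ("cnn", "pls"):
                    for mode in grid.modes:
                        try:
                            if mode == "fixed":
                                predict = fixed[model_type]
                            else:
                                aug_p = perturb_generated(
                                    aug_clean, ds.wavelengths, s_noise,
                                    s_shift, seed=cell_seed + 977 + 131 * li)
                                if model_type == "cnn":
                                    # validation spectra perturbed at the
                                    # level too, so early stopping selects
                                    # weights for the deployed regime
                                    X_val = _perturb_matrix(
                                        ds.X, ds.wavelengths, s_noise,
                                        s_shift, seed=cell_seed + 557
                                        + 131 * li)
                                    predict = _train_cnn_on(
                                        aug_p, ds, cnn_arch,
                                        replace(train_cfg,
                                                seed=train_cfg.seed
                                                + cell_seed + li),
                                        X_val=X_val)
                                else:
                                    predict = _train_pls_on(aug_p, ds,
                                                            pls_cfgs)
                            m = compute_metrics(eval_ds.Y,
                                                predict(X_eval))
                            table.append({
                                "model": model_type, "mode": mode,
                                "axis": axis, "level": level, "seed": rep,
                                "sum_nrmse": float(np.nansum(m.nrmse)),
                                "nrmse": m.nrmse.tolist(),
                            })
                        except Exception as exc:
                            raise RuntimeError(
                                f"robustness cell failed (model={model_type}"
                                f", mode={mode}, {axis}={level}, seed={rep})"
                                f": {exc}") from exc
    return table
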