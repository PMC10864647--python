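"""Shared regression metrics.

Per-component RMSE, NRMSE (RMSE normalised by the mean observed
concentration) and R^2 = 1 - SS_res/SS_tot.  Cross-validated residuals are
pooled over all rotations before computing R^2 (see `pooled` flags on the
model-selection routines); NRMSE follows NRMSE = RMSE / ybar with ybar the
arithmetic mean of the observed values in the evaluated subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Metrics", "compute_metrics", "sse_cv_scaled"]


@dataclass
class Metrics:
    """Per-component regression metrics; undefined entries are NaN."""

    rmse: np.ndarray
    nrmse: np.ndarray
    r2: np.ndarray

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse.tolist(),
            "nrmse": self.nrmse.tolist(),
            "r2": self.r2.tolist(),
        }


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Per-component RMSE, NRMSE and R^2.

    NRMSE is NaN where the mean observed concentration is 0; R^2 is NaN where
    y_true has zero variance.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.shape[0] < 1:
        raise ValueError("need at least one sample")

    resid = y_pred - y_true
    rmse = np.sqrt(np.mean(resid**2, axis=0))

    ybar = np.mean(y_true, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nrmse = np.where(ybar > 0, rmse / ybar, np.nan)

    sstot = np.sum((y_true - ybar) ** 2, axis=0)
    ssres = np.sum(resid**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sstot > 0, 1.0 - ssres / sstot, np.nan)

    return Metrics(rmse=rmse, nrmse=nrmse, r2=r2)


def sse_cv_scaled(residuals: np.ndarray, n_pls: int) -> float:
    """Cross-validated sum of squared errors scaled by degrees of freedom.

    ``sum(residual^2) / (M - n_pls - 1)`` where M is the number of pooled CV
    predictions and n_pls the number of latent PLS components.  Used for PLS
    model selection, penalising model complexity.
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    m = residuals.size
    dof = m - n_pls - 1
    if dof <= 0:
        raise ValueError(
            f"degrees of freedom M - n_pls - 1 = {m} - {n_pls} - 1 <= 0"
        )
    return float(np.sum(residuals**2) / dof)
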