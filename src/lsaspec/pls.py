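"""Single-response PLS regression (NIPALS) with Savitzky-Golay preprocessing.

The baseline chemometric model: spectra are optionally smoothed/derived with
a Savitzky-Golay filter (second-degree polynomial), mean-centered, and
regressed against one component's concentration by PLS1 computed with the
non-linear iterative partial least squares (NIPALS) algorithm.  Model
selection grid-searches the number of latent components, the derivative
order and the filter window against a degrees-of-freedom-scaled
cross-validated SSE (leave-one-group-out, residuals pooled).

The NIPALS internals (loading weights w_a, y-loadings q_a, score vectors
t_a) are retained on the fitted model because the VIP importance scores are
computed from them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectralDataset
from .metrics import sse_cv_scaled

__all__ = ["SGFConfig", "PLSModel", "sgf_preprocess", "fit_pls1",
           "predict_pls1", "tune_pls"]


@dataclass
class SGFConfig:
    """Savitzky-Golay filter settings: odd window, polyorder 2, deriv 0-2."""

    window: int = 11
    polyorder: int = 2
    deriv: int = 0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("SGF window must be an odd integer >= 3")
        if self.window <= self.polyorder:
            raise ValueError("SGF window must exceed the polynomial order")
        if not 0 <= self.deriv <= self.polyorder:
            raise ValueError("deriv must be between 0 and polyorder")


def sgf_preprocess(X: np.ndarray, cfg: SGFConfig,
                   delta: float = 1.0) -> np.ndarray:
    """Per-row Savitzky-Golay smoothing/differentiation.

    ``delta`` is the wavelength step so derivatives are per wavelength unit.
    Edges are handled by the filter's polynomial fit (no shortening).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if cfg.window > X.shape[1]:
        raise ValueError(
            f"SGF window {cfg.window} exceeds spectrum length {X.shape[1]}")
    return savgol_filter(X, cfg.window, cfg.polyorder, deriv=cfg.deriv,
                         delta=delta, axis=1, mode="interp")


@dataclass
class PLSModel:
    """Fitted PLS1 model with NIPALS internals.

    W, P are N x A loading-weight and x-loading matrices; q the length-A
    y-loadings; T the M x A training scores; beta the length-N regression
    coefficient vector on the preprocessed-spectrum scale, so that
    predict = (SGF(X) - x_mean) . beta + y_mean.
    """

    A: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    beta: np.ndarray
    sgf: SGFConfig | None = None
    wavelength_step: float = 1.0
    n_wavelengths: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_wavelengths == 0:
            self.n_wavelengths = self.beta.size


def fit_pls1(X: np.ndarray, y: np.ndarray, A: int,
             sgf: SGFConfig | None = None,
             wavelength_step: float = 1.0) -> PLSModel:
    """Fit a PLS1 model by NIPALS with deflation.

    X is the raw spectra matrix (M x N); preprocessing (optional SGF, then
    mean centering) is applied internally and stored on the model.  After
    each component the weight vector is normalised and X/y are deflated, so
    the training scores are mutually orthogonal.  beta = W (P^T W)^-1 q.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    M, N = X.shape
    if y.size != M:
        raise ValueError("y length must match X row count")
    if not 1 <= A <= min(M - 1, N):
        raise ValueError(f"A must be in [1, min(M-1, N)] = [1, {min(M - 1, N)}]")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; PLS1 fit is undefined")

    Xp = sgf_preprocess(X, sgf, delta=wavelength_step) if sgf else X.copy()
    x_mean = Xp.mean(axis=0)
    y_mean = float(y.mean())
    Xc = Xp - x_mean
    yc = y - y_mean

    W = np.empty((N, A))
    Pmat = np.empty((N, A))
    qvec = np.empty(A)
    T = np.empty((M, A))
    for a in range(A):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise np.linalg.LinAlgError(
                f"zero weight vector at component {a + 1}; "
                "residual X carries no covariance with y")
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        p = (Xc.T @ t) / tt
        q = float(t @ yc) / tt
        Xc -= np.outer(t, p)
        yc = yc - q * t
        W[:, a], Pmat[:, a], qvec[a], T[:, a] = w, p, q, t

    beta = W @ np.linalg.solve(Pmat.T @ W, qvec)
    return PLSModel(A=A, W=W, P=Pmat, q=qvec, T=T, x_mean=x_mean,
                    y_mean=y_mean, beta=beta, sgf=sgf,
                    wavelength_step=wavelength_step, n_wavelengths=N)


def predict_pls1(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations: stored SGF + centering + beta."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_wavelengths:
        raise ValueError(
            f"model expects {model.n_wavelengths} wavelengths, "
            f"got {X_new.shape[1]}")
    Xp = (sgf_preprocess(X_new, model.sgf, delta=model.wavelength_step)
          if model.sgf else X_new)
    return (Xp - model.x_mean) @ model.beta + model.y_mean


def tune_pls(ds: SpectralDataset, component: int,
             a_values: range | list = range(1, 11),
             deriv_values: range | list = range(0, 3),
             window_values: list | None = None,
             pooled: bool = True
             ) -> tuple[int, SGFConfig, list[dict]]:
    """Grid search (A, SGF deriv, SGF window) by scaled cross-validated SSE.

    Leave-one-group-out CV; held-out residuals are pooled across rotations
    and scored by ``sse_cv_scaled``.  Ties break toward smaller A, then
    smaller window, then lower derivative order.  Returns
    (best A, best SGFConfig, results table).
    """
    labels = ds.group_labels()
    if len(labels) < 2:
        raise ValueError("tune_pls needs at least 2 groups")
    if window_values is None:
        window_values = [w for w in range(3, 32, 2)]
    window_values = [w for w in window_values if w <= ds.n_wavelengths]
    step = float(ds.wavelengths[1] - ds.wavelengths[0])
    y = ds.Y[:, component]
    rotations = [(ds.groups == lab) for lab in labels]
    a_max_global = min(min((~h).sum() for h in rotations) - 1,
                       ds.n_wavelengths)

    table: list[dict] = []
    for deriv, window in itertools.product(deriv_values, window_values):
        sgf = SGFConfig(window=window, deriv=deriv)
        # SGF is independent of A: fit per rotation incrementally over A
        for A in a_values:
            if A > a_max_global:
                continue
            residuals = []
            try:
                for held in rotations:
                    model = fit_pls1(ds.X[~held], y[~held], A, sgf=sgf,
                                     wavelength_step=step)
                    pred = predict_pls1(model, ds.X[held])
                    residuals.append(pred - y[held])
                resid = np.concatenate(residuals)
                score = sse_cv_scaled(resid, A)
            except (ValueError, np.linalg.LinAlgError) as exc:
                table.append({"A": A, "deriv": deriv, "window": window,
                              "ssecv_scaled": np.inf, "error": str(exc)})
                continue
            table.append({"A": A, "deriv": deriv, "window": window,
                          "ssecv_scaled": score})
    if not table:
        raise ValueError("empty PLS tuning grid")
    best = min(table, key=lambda r: (r["ssecv_scaled"], r["A"], r["window"],
                                     r["deriv"]))
    return best["A"], SGFConfig(window=best["window"], deriv=best["deriv"]), table
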