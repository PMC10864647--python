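"""Per-wavelength feature importance for CNN and PLS models.

Four complementary attribution methods:

* **Grad-CAM** (CNN-specific): gradients of one output component with
  respect to the last convolutional layer's feature maps are averaged over
  positions into per-filter weights; the ReLU of the weighted feature-map
  sum, linearly interpolated back to the wavelength axis, localises the
  spectral regions driving the prediction.  Non-negative by construction.
* **Permutation SHAP** (model-agnostic): Shapley values estimated by
  averaging marginal prediction changes over random feature orderings,
  walking each ordering forward and backward (antithetic pairing).  Masked
  wavelengths take values from the background spectra; each coalition is
  valued as the mean prediction over the full background set, so the local
  additivity identity sum_j phi_j = f(x) - E_bg[f] holds exactly for every
  completed permutation pair.
* **VIP scores** (PLS-specific): variable importance in projection,
  v_j = sqrt(N * sum_a q_a^2 t_a'^t_a (w_aj/||w_a||)^2 / sum_a q_a^2 t_a'^t_a),
  normalised so the mean squared score is 1.
* **Regression coefficients** (PLS): beta on the preprocessed-spectrum scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn import CNNModel
from .pls import PLSModel

__all__ = ["ImportanceResult", "gradcam_map", "permutation_shap",
           "vip_scores", "pls_coefficients"]


@dataclass
class ImportanceResult:
    """Per-wavelength attribution values tagged by method and component."""

    method: str                       # gradcam | shap | vip | coefficients
    component: int
    values: np.ndarray                # length N, aligned to the wavelength axis
    per_sample: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def gradcam_map(model: CNNModel, x: np.ndarray, component: int) -> np.ndarray:
    """Grad-CAM localisation map for one spectrum and output component.

    alpha_k = mean over positions of d(output_component)/d(feature map k);
    map = ReLU(sum_k alpha_k * feature_map_k), linearly interpolated from
    the reduced feature length to the input length N.  All values >= 0.
    """
    fmap, grads = model.feature_maps_and_grads(x, component)
    alpha = grads.mean(axis=1)                       # one weight per filter
    cam = np.maximum(alpha @ fmap, 0.0)              # length = reduced L
    L = cam.size
    N = model.n_wavelengths
    if L == N:
        return cam
    return np.interp(np.linspace(0.0, L - 1, N), np.arange(L), cam)


def permutation_shap(predict_fn, background: np.ndarray,
                     explain: np.ndarray, component: int,
                     n_permutations: int = 1000,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Permutation-estimated Shapley values, (n_explain, N).

    ``predict_fn`` maps an (m, N) spectra matrix to (m, P) outputs.  For
    each explained spectrum, random feature orderings are walked forward
    and backward (antithetic pairs); at every step the newly unmasked
    wavelength's marginal change in the mean background-masked prediction
    is credited to that wavelength.  ``n_permutations`` counts permutation
    walks (rounded up to an even number).
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    explain = np.atleast_2d(np.asarray(explain, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if background.shape[1] != explain.shape[1]:
        raise ValueError("background and explain feature counts differ")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    B, N = background.shape
    n_pairs = max(1, (n_permutations + 1) // 2)
    # chunk walks so one predict call covers many coalitions
    chunk = max(1, 20000 // ((N + 1) * B))

    phi = np.zeros((explain.shape[0], N))
    for e, x in enumerate(explain):
        acc = np.zeros(N)
        walks_left = 2 * n_pairs
        orders_iter = _antithetic_orders(N, n_pairs, rng)
        while walks_left > 0:
            k = min(chunk, walks_left)
            orders = [next(orders_iter) for _ in range(k)]
            # coalition tensor: (k, N+1, B, N); step s unmasks order[:s]
            coal = np.broadcast_to(background, (k, N + 1, B, N)).copy()
            for w, order in enumerate(orders):
                for s, j in enumerate(order, start=1):
                    coal[w, s:, :, j] = x[j]
            preds = predict_fn(coal.reshape(-1, N))
            preds = np.atleast_2d(np.asarray(preds, dtype=float))
            vals = preds[:, component].reshape(k, N + 1, B).mean(axis=2)
            incr = np.diff(vals, axis=1)             # (k, N)
            for w, order in enumerate(orders):
                acc[order] += incr[w]
            walks_left -= k
        phi[e] = acc / (2 * n_pairs)
    return phi


def _antithetic_orders(N: int, n_pairs: int, rng: np.random.Generator):
    """Yield 2*n_pairs orderings: each random permutation then its reverse."""
    for _ in range(n_pairs):
        order = rng.permutation(N)
        yield order
        yield order[::-1]


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable-importance-in-projection scores of a fitted PLS1 model.

    Weighted by each component's explained y-variance q_a^2 t_a't_a; the
    normalisation gives (1/N) sum_j v_j^2 = 1.
    """
    W = model.W
    if W is None or model.q is None:
        raise ValueError("model is not fitted")
    N = W.shape[0]
    ssy = model.q**2 * np.einsum("ma,ma->a", model.T, model.T)   # per component
    w_unit_sq = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(N * (w_unit_sq @ ssy) / ssy.sum())


def pls_coefficients(model: PLSModel) -> ImportanceResult:
    """Regression coefficients beta on the preprocessed-spectrum scale."""
    if model.beta is None:
        raise ValueError("model is not fitted")
    chain = ["SGF(window=%d, polyorder=%d, deriv=%d)"
             % (model.sgf.window, model.sgf.polyorder, model.sgf.deriv)
             ] if model.sgf else []
    chain.append("mean centering")
    return ImportanceResult(
        method="coefficients", component=0, values=model.beta.copy(),
        metadata={"preprocessing": chain, "y_mean": model.y_mean})
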