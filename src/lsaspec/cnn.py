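"""1-D convolutional regression networks for absorbance spectra.

A deliberately small CNN family for mapping a spectrum (length N) to P
non-negative concentrations: 1-3 'valid' convolutional layers (linear
activation by default), max pooling of width 2 after layers 1 and 2, a
single fully connected layer (tanh), optional dropout and L2 weight
regularisation, and a ReLU output that restricts predictions to positive
values.  Training minimises the mean MSE over all responses with Adam
(lr 1e-3, batch 100) and early stopping on a held-out validation loss
(patience in consecutive non-improving epochs, best-epoch weights
restored).

The networks here are a few thousand parameters at most, so forward and
backward passes are implemented directly in numpy (vectorised over the
batch).  This keeps the package dependency-light and — importantly for the
interpretability tooling — exposes the last convolutional layer's feature
maps and their exact gradients, which Grad-CAM needs.

The cross-validation protocol regenerates the in-silico calibration data
inside every leave-one-group-out rotation from the retained groups only:
the network is calibrated exclusively on generated data while the
experimental (training) data serve as the early-stopping validation set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .augment import LSAConfig, augment_dataset
from .dataset import SpectralDataset
from .metrics import compute_metrics

__all__ = ["CNNArchitecture", "TrainingConfig", "CNNModel", "EarlyStopping",
           "build_cnn", "train_cnn", "cross_validate_cnn",
           "train_unaugmented"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_ACTIVATIONS = ("linear", "tanh", "relu", "elu", "sigmoid")


@dataclass
class CNNArchitecture:
    """Architecture description: one entry per convolutional layer.

    Pooling (width 2) is applied after convolutional layers 1 and 2 only;
    convolutions are 'valid' (no padding), so the feature length shrinks by
    width-1 per layer and halves at each pooling step.
    """

    n_filters: list[int] = field(default_factory=lambda: [5])
    filter_widths: list[int] = field(default_factory=lambda: [9])
    fc_units: int = 12
    conv_activation: str = "linear"
    fc_activation: str = "tanh"
    weight_init: str = "uniform"       # 'uniform' (+-0.05) or 'glorot_uniform'
    dropout_rate: float = 0.0
    l2_factor: float = 0.0
    pooling_width: int = 2

    def __post_init__(self) -> None:
        if not 1 <= len(self.n_filters) <= 3:
            raise ValueError("1 to 3 convolutional layers are supported")
        if len(self.filter_widths) != len(self.n_filters):
            raise ValueError("filter_widths and n_filters lengths differ")
        for f in self.n_filters:
            if f < 1:
                raise ValueError("each layer needs at least 1 filter")
        for w in self.filter_widths:
            if w < 3 or w % 2 == 0:
                raise ValueError("filter widths must be odd and >= 3")
        if self.fc_units < 1:
            raise ValueError("fc_units must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_factor < 0:
            raise ValueError("l2_factor must be >= 0")
        for act in (self.conv_activation, self.fc_activation):
            if act not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")

    @property
    def n_conv_layers(self) -> int:
        return len(self.n_filters)


@dataclass
class TrainingConfig:
    """Training protocol: Adam, mean MSE over responses, early stopping."""

    learning_rate: float = 1e-3
    batch_size: int = 100
    max_epochs: int = 100
    patience: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("training parameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def _activation(name: str):
    if name == "linear":
        return (lambda z: z), (lambda z, a: np.ones_like(z))
    if name == "tanh":
        return np.tanh, (lambda z, a: 1.0 - a**2)
    if name == "relu":
        return (lambda z: np.maximum(z, 0.0)), (lambda z, a: (z > 0).astype(z.dtype))
    if name == "sigmoid":
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))
        return sig, (lambda z, a: a * (1.0 - a))
    if name == "elu":
        elu = lambda z: np.where(z > 0, z, np.expm1(z))
        return elu, (lambda z, a: np.where(z > 0, 1.0, a + 1.0))
    raise ValueError(name)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv1D:
    """Valid 1-D convolution, (B, C, L) -> (B, F, L-w+1), with activation."""

    def __init__(self, W: np.ndarray, b: np.ndarray, activation: str):
        self.W, self.b = W, b
        self.act_name = activation
        self.f, self.df = _activation(activation)
        self.gW = np.zeros_like(W)
        self.gb = np.zeros_like(b)

    def params(self):
        return [(self.W, self.gW, True), (self.b, self.gb, False)]

    def forward(self, x, train, rng):
        self.windows = sliding_window_view(x, self.W.shape[2], axis=2)
        self.z = np.einsum("bclw,fcw->bfl", self.windows, self.W,
                           optimize=True) + self.b[None, :, None]
        self.a = self.f(self.z)
        return self.a

    def backward(self, da):
        dz = da * self.df(self.z, self.a)
        self.gW[:] = np.einsum("bclw,bfl->fcw", self.windows, dz,
                               optimize=True)
        self.gb[:] = dz.sum(axis=(0, 2))
        w = self.W.shape[2]
        dz_pad = np.pad(dz, ((0, 0), (0, 0), (w - 1, w - 1)))
        wins = sliding_window_view(dz_pad, w, axis=2)
        return np.einsum("bftw,fcw->bct", wins, self.W[:, :, ::-1],
                         optimize=True)


class _MaxPool2:
    """Max pooling, width 2, stride 2; odd tail truncated."""

    def params(self):
        return []

    def forward(self, x, train, rng):
        B, F, L = x.shape
        self.L = L
        L2 = L // 2
        r = x[:, :, :2 * L2].reshape(B, F, L2, 2)
        self.idx = r.argmax(axis=-1)
        return r.max(axis=-1)

    def backward(self, dout):
        B, F, L2 = dout.shape
        dx = np.zeros((B, F, self.L), dtype=dout.dtype)
        pos = 2 * np.arange(L2)[None, None, :] + self.idx
        np.put_along_axis(dx, pos, dout, axis=2)
        return dx


class _Flatten:
    def params(self):
        return []

    def forward(self, x, train, rng):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.shape)


class _Dense:
    def __init__(self, W: np.ndarray, b: np.ndarray, activation: str):
        self.W, self.b = W, b
        self.f, self.df = _activation(activation)
        self.gW = np.zeros_like(W)
        self.gb = np.zeros_like(b)

    def params(self):
        return [(self.W, self.gW, True), (self.b, self.gb, False)]

    def forward(self, x, train, rng):
        self.x = x
        self.z = x @ self.W + self.b
        self.a = self.f(self.z)
        return self.a

    def backward(self, da):
        dz = da * self.df(self.z, self.a)
        self.gW[:] = self.x.T @ dz
        self.gb[:] = dz.sum(axis=0)
        return dz @ self.W.T


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def params(self):
        return []

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (rng.random(x.shape) < keep) / keep
        return x * self.mask

    def backward(self, dout):
        return dout if self.mask is None else dout * self.mask


class _ReLUOut:
    """Output ReLU restricting predictions to positive values."""

    def params(self):
        return []

    def forward(self, x, train, rng):
        self.mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self.mask


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class CNNModel:
    """A built network: layer stack plus bookkeeping for Adam and Grad-CAM."""

    def __init__(self, arch: CNNArchitecture, n_wavelengths: int,
                 n_components: int, seed: int = 0):
        self.arch = arch
        self.n_wavelengths = n_wavelengths
        self.n_components = n_components
        rng = np.random.default_rng(seed)

        def init(shape, fan_in, fan_out):
            if arch.weight_init == "glorot_uniform":
                lim = math.sqrt(6.0 / (fan_in + fan_out))
            else:                       # 'uniform': fixed small range
                lim = 0.05
            return rng.uniform(-lim, lim, size=shape)

        self.layers: list = []
        self.last_conv_index = -1
        L, C = n_wavelengths, 1
        for i, (F, w) in enumerate(zip(arch.n_filters, arch.filter_widths)):
            if w > L:
                raise ValueError(
                    f"conv layer {i + 1}: filter width {w} exceeds current "
                    f"feature length {L}")
            Wc = init((F, C, w), C * w, F * w)
            self.layers.append(_Conv1D(Wc, np.zeros(F), arch.conv_activation))
            self.last_conv_index = len(self.layers) - 1
            L = L - w + 1
            if i < 2:                   # pooling after conv layers 1 and 2
                self.layers.append(_MaxPool2())
                L = L // 2
                if L < 1:
                    raise ValueError(
                        f"feature length vanished after pooling layer {i + 1}")
            C = F
        self.feature_length = L
        flat = C * L
        self.layers.append(_Flatten())
        W1 = init((flat, arch.fc_units), flat, arch.fc_units)
        self.layers.append(_Dense(W1, np.zeros(arch.fc_units),
                                  arch.fc_activation))
        if arch.dropout_rate > 0:
            self.layers.append(_Dropout(arch.dropout_rate))
        W2 = init((arch.fc_units, n_components), arch.fc_units, n_components)
        # small positive output bias keeps the ReLU output alive at start
        self.layers.append(_Dense(W2, np.full(n_components, 0.1), "linear"))
        self.layers.append(_ReLUOut())

    # -- parameter access ---------------------------------------------------
    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _, _ in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _, _), w in zip(self.parameters(), weights):
            p[:] = w

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        a = np.asarray(X, dtype=float)[:, None, :]
        for layer in self.layers:
            a = layer.forward(a, train, rng)
        return a

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Non-negative concentration predictions, (M, P)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_wavelengths:
            raise ValueError(
                f"model expects {self.n_wavelengths} wavelengths, "
                f"got {X.shape[1]}")
        return self.forward(X, train=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def feature_maps_and_grads(self, x: np.ndarray,
                               component: int) -> tuple[np.ndarray, np.ndarray]:
        """Last conv layer's feature maps and d(output_c)/d(feature map).

        Returns (A, G), both (n_filters_last, L_last), for a single input
        spectrum.  Gradients are of the post-ReLU output component.
        """
        if not 0 <= component < self.n_components:
            raise IndexError(f"component {component} out of range")
        x = np.asarray(x, dtype=float).reshape(1, -1)
        self.forward(x, train=False)
        dout = np.zeros((1, self.n_components))
        dout[0, component] = 1.0
        for li in range(len(self.layers) - 1, self.last_conv_index, -1):
            dout = self.layers[li].backward(dout)
        fmap = self.layers[self.last_conv_index].a[0]
        return fmap, dout[0]


def build_cnn(arch: CNNArchitecture, n_wavelengths: int, n_components: int,
              seed: int = 0) -> CNNModel:
    """Instantiate a trainable network for the given input/output sizes."""
    return CNNModel(arch, n_wavelengths, n_components, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _, _ in params]
        self.v = [np.zeros_like(p) for p, _, _ in params]
        self.t = 0

    def step(self, l2: float) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g, is_weight) in enumerate(self.params):
            grad = g + (2.0 * l2 * p if (l2 > 0 and is_weight) else 0.0)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad**2
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t)
                                                + self.eps)


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


class EarlyStopping:
    """Stop after `patience` consecutive epochs without improvement.

    An epoch improves when its validation loss is strictly below the best
    seen so far; the best epoch (1-based) is tracked for weight restoring.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.bad_epochs = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; returns True to stop."""
        self.epoch += 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def train_cnn(model: CNNModel, X_cal: np.ndarray, Y_cal: np.ndarray,
              X_val: np.ndarray, Y_val: np.ndarray, cfg: TrainingConfig,
              early_stopping: bool = True) -> dict:
    """Calibrate the network on generated data, validate on experimental data.

    Minimises the mean MSE over all responses with Adam; stops when the
    validation loss has not improved for ``cfg.patience`` consecutive epochs
    (or at max_epochs) and restores the weights of the best validation
    epoch.  Returns a history dict with per-epoch losses and the best epoch
    (1-based).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    Y_cal = np.atleast_2d(np.asarray(Y_cal, dtype=float))
    X_val = np.asarray(X_val, dtype=float)
    Y_val = np.atleast_2d(np.asarray(Y_val, dtype=float))
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.parameters(), cfg.learning_rate)
    l2 = model.arch.l2_factor

    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": 0}
    stopper = EarlyStopping(cfg.patience)
    best_weights = model.get_weights()
    M = X_cal.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(M)
        epoch_loss = 0.0
        for start in range(0, M, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X_cal[idx], Y_cal[idx]
            pred = model.forward(xb, train=True, rng=rng)
            loss = _mse(pred, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            dout = 2.0 * (pred - yb) / pred.size
            model.backward(dout)
            opt.step(l2)
        history["train_loss"].append(epoch_loss / M)
        val_loss = _mse(model.predict(X_val), Y_val)
        history["val_loss"].append(val_loss)
        stop = stopper.update(val_loss)
        if stopper.best_epoch == epoch:
            best_weights = model.get_weights()
            history["best_epoch"] = epoch
        if early_stopping and stop:
            break
    model.set_weights(best_weights)
    history["stopped_epoch"] = len(history["val_loss"])
    return history


def cross_validate_cnn(ds: SpectralDataset, arch: CNNArchitecture,
                       lsa_cfg: LSAConfig, train_cfg: TrainingConfig,
                       train_fn=None) -> dict:
    """Leave-one-group-out CV with rotation-specific data generation.

    Per rotation the in-silico calibration data are regenerated from the
    retained groups only, the network is trained on them (validating on the
    retained experimental data), and the held-out group is predicted.
    Held-out predictions are pooled before computing per-component R^2 and
    the sum-of-R^2 objective.

    ``train_fn(X_cal, Y_cal, X_val, Y_val, rotation) -> predict`` overrides
    the default build+train step (testing hook).
    """
    labels = ds.group_labels()
    if len(labels) < 2:
        raise ValueError("cross-validation needs at least 2 groups")
    preds = np.full_like(ds.Y, np.nan)
    for rot, label in enumerate(labels):
        held = ds.groups == label
        retained_ds = ds.subset(~held)
        try:
            aug = augment_dataset(
                retained_ds, replace(lsa_cfg, seed=lsa_cfg.seed + 1000 + rot))
            if train_fn is None:
                model = build_cnn(arch, ds.n_wavelengths, ds.n_components,
                                  seed=train_cfg.seed + rot)
                train_cnn(model, aug.X_star, aug.Y_star,
                          retained_ds.X, retained_ds.Y,
                          replace(train_cfg, seed=train_cfg.seed + rot))
                predict = model.predict
            else:
                predict = train_fn(aug.X_star, aug.Y_star,
                                   retained_ds.X, retained_ds.Y, rot)
            preds[held] = np.atleast_2d(predict(ds.X[held]))
        except Exception as exc:
            raise RuntimeError(
                f"cross-validation rotation holding out group {label!r} "
                f"failed: {exc}") from exc
    m = compute_metrics(ds.Y, preds)
    return {
        "r2_cv": m.r2,
        "rmsecv": m.rmse,
        "nrmse_cv": m.nrmse,
        "sum_r2_cv": float(np.sum(m.r2)),
        "predictions": preds,
    }


def train_unaugmented(ds: SpectralDataset, arch: CNNArchitecture,
                      seed: int = 0, max_epochs: int = 300,
                      val_fraction: float = 0.2) -> tuple[CNNModel, dict]:
    """Baseline protocol without data augmentation.

    The experimental training data are split randomly 80/20 into
    calibration/validation subsets, the network is trained for a fixed
    number of epochs with early stopping disabled, and the weights of the
    epoch with minimum validation loss are restored.
    """
    if ds.n_samples < 10:
        raise ValueError("need at least 10 samples for the 80/20 split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ds.n_samples)
    n_val = max(1, int(round(val_fraction * ds.n_samples)))
    val_idx, cal_idx = order[:n_val], order[n_val:]
    model = build_cnn(arch, ds.n_wavelengths, ds.n_components, seed=seed)
    cfg = TrainingConfig(max_epochs=max_epochs, patience=max_epochs - 1,
                         seed=seed)
    history = train_cnn(model, ds.X[cal_idx], ds.Y[cal_idx],
                        ds.X[val_idx], ds.Y[val_idx], cfg,
                        early_stopping=False)
    history["calibration_indices"] = cal_idx.tolist()
    history["validation_indices"] = val_idx.tolist()
    return model, history
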