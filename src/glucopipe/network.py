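"""Feed-forward regression network trained by back-propagation.

The reference architecture is 30 inputs -> 250 -> 300 -> 1: two tanh
hidden layers and a linear output, trained by full-batch gradient
descent on mean squared error with a stepped learning-rate schedule
(initial 0.01, multiplied by a decay factor every 10 epochs) and early
stopping on a validation split. Weights and gradients are computed
explicitly — the trainer is the point of this module, not a wrapper.

Inputs and the glucose target are standardized with statistics fitted on
the training split only (:class:`Scaler`); predictions are mapped back
to mg/dL by :func:`predict_glucose`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, ParameterError, StateError

__all__ = [
    "NetworkParams",
    "TrainingSchedule",
    "TrainingHistory",
    "Scaler",
    "init_network",
    "forward",
    "mse_loss",
    "backprop_gradients",
    "train",
    "predict_glucose",
    "DEFAULT_LAYER_SIZES",
]

DEFAULT_LAYER_SIZES: tuple[int, ...] = (30, 250, 300, 1)


@dataclass
class NetworkParams:
    """Layered weights/biases. ``weights[l]`` maps layer l to l+1
    (shape ``(n_out, n_in)``); hidden activation is tanh unless switched
    to 'identity' (a hook that makes the network exactly linear)."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_activation: str = "tanh"
    seed: int = 0

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.layer_sizes,
                             [w.copy() for w in self.weights],
                             [b.copy() for b in self.biases],
                             self.hidden_activation, self.seed)


@dataclass(frozen=True)
class TrainingSchedule:
    """Full-batch gradient-descent schedule.

    lr at epoch e (0-indexed) is ``lr0 * decay_factor ** (e // decay_every)``;
    training runs at most ``max_epochs`` epochs and stops once the
    validation loss has not improved for ``early_stop_patience`` epochs.
    """

    max_epochs: int = 550
    lr0: float = 0.01
    decay_every: int = 10
    decay_factor: float = 0.95
    early_stop_patience: int = 50

    def __post_init__(self) -> None:
        if self.lr0 <= 0 or not (0 < self.decay_factor <= 1):
            raise ParameterError("need lr0 > 0 and decay_factor in (0, 1]")
        if self.max_epochs < 1 or self.decay_every < 1 or self.early_stop_patience < 1:
            raise ParameterError("epoch counts must be >= 1")

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.decay_factor ** (epoch // self.decay_every)


@dataclass
class TrainingHistory:
    """Per-epoch training/validation losses and learning rates."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def __len__(self) -> int:
        return len(self.train_loss)


def init_network(layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES,
                 seed: int = 0, hidden_activation: str = "tanh") -> NetworkParams:
    """Glorot-uniform weights (limit sqrt(6/(fan_in+fan_out))), zero biases."""
    if len(layer_sizes) < 2 or any(s < 1 for s in layer_sizes):
        raise ParameterError(f"bad layer sizes {layer_sizes}")
    if hidden_activation not in ("tanh", "identity"):
        raise ParameterError(f"unknown activation {hidden_activation!r}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        limit = np.sqrt(6.0 / (n_in + n_out))
        weights.append(rng.uniform(-limit, limit, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return NetworkParams(tuple(layer_sizes), weights, biases, hidden_activation, seed)


def _activate(net: NetworkParams, z: np.ndarray) -> np.ndarray:
    return np.tanh(z) if net.hidden_activation == "tanh" else z


def _activate_deriv(net: NetworkParams, a: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation value a = act(z)
    return 1.0 - a ** 2 if net.hidden_activation == "tanh" else np.ones_like(a)


def _forward_pass(net: NetworkParams, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; the last entry is the (n,) linear output."""
    a = X
    acts = [a]
    n_layers = len(net.weights)
    for l, (W, b) in enumerate(zip(net.weights, net.biases)):
        z = a @ W.T + b
        a = z if l == n_layers - 1 else _activate(net, z)  # identity output
        acts.append(a)
    return acts


def forward(net: NetworkParams, x: np.ndarray) -> np.ndarray | float:
    """Network output in standardized units; scalar for a single vector."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != net.layer_sizes[0]:
        raise DataError(f"expected {net.layer_sizes[0]} inputs, got {X.shape[1]}")
    out = _forward_pass(net, X)[-1][:, 0]
    return float(out[0]) if single else out


def mse_loss(net: NetworkParams, X: np.ndarray, y: np.ndarray) -> float:
    pred = _forward_pass(net, np.atleast_2d(X))[-1][:, 0]
    return float(np.mean((pred - np.asarray(y, dtype=float)) ** 2))


def backprop_gradients(net: NetworkParams, X: np.ndarray,
                       y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Exact MSE gradients for every weight matrix and bias vector.

    Loss is ``mean_i (f(x_i) - y_i)^2``; gradients are the standard
    chain-rule recursion through the tanh layers.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0] or X.shape[1] != net.layer_sizes[0]:
        raise DataError(f"shape mismatch: X {X.shape}, y {y.shape}")
    n = X.shape[0]
    acts = _forward_pass(net, X)
    pred = acts[-1][:, 0]
    # delta at the linear output: dL/dz_out, shape (n, 1)
    delta = (2.0 / n) * (pred - y)[:, None]
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(net.weights)
    for l in range(len(net.weights) - 1, -1, -1):
        grads[l] = (delta.T @ acts[l], delta.sum(axis=0))
        if l > 0:
            delta = (delta @ net.weights[l]) * _activate_deriv(net, acts[l])
    return grads


def train(net: NetworkParams, X_train: np.ndarray, y_train: np.ndarray,
          X_val: np.ndarray, y_val: np.ndarray,
          sched: TrainingSchedule | None = None
          ) -> tuple[NetworkParams, TrainingHistory]:
    """Full-batch gradient descent with lr decay and early stopping.

    Each epoch: one gradient step at the scheduled lr, then the losses
    of the updated parameters are recorded. The parameters from the
    best-validation epoch are returned.
    """
    sched = sched or TrainingSchedule()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise DataError("empty training or validation split")

    net = net.copy()
    hist = TrainingHistory()
    best_val = np.inf
    best_params = net.copy()
    for epoch in range(sched.max_epochs):
        lr = sched.lr_at(epoch)
        grads = backprop_gradients(net, X_train, y_train)
        for (dW, db), W, b in zip(grads, net.weights, net.biases):
            W -= lr * dW
            b -= lr * db
        tl = mse_loss(net, X_train, y_train)
        vl = mse_loss(net, X_val, y_val)
        hist.train_loss.append(tl)
        hist.val_loss.append(vl)
        hist.learning_rate.append(lr)
        if vl < best_val:
            best_val = vl
            hist.best_epoch = epoch
            best_params = net.copy()
        elif epoch - hist.best_epoch >= sched.early_stop_patience:
            break
    return best_params, hist


@dataclass
class Scaler:
    """Per-feature and target standardization fitted on training rows."""

    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    target_mean: float | None = None
    target_sd: float | None = None

    @property
    def fitted(self) -> bool:
        return self.feature_means is not None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Scaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        self.feature_means = X.mean(axis=0)
        sds = X.std(axis=0)
        if np.any(sds == 0):
            warnings.warn("zero-variance feature column(s); sd set to 1", stacklevel=2)
            sds = np.where(sds == 0, 1.0, sds)
        self.feature_sds = sds
        self.target_mean = float(y.mean())
        tsd = float(y.std())
        if tsd == 0:
            warnings.warn("zero-variance target; sd set to 1", stacklevel=2)
            tsd = 1.0
        self.target_sd = tsd
        return self

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        self._check()
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.feature_means) / self.feature_sds

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(y, dtype=float) - self.target_mean) / self.target_sd

    def inverse_y(self, y_std: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(y_std, dtype=float) * self.target_sd + self.target_mean

    def _check(self) -> None:
        if not self.fitted:
            raise StateError("scaler has not been fitted")


def predict_glucose(net: NetworkParams, scaler: Scaler,
                    X_raw: np.ndarray) -> np.ndarray:
    """Standardize raw features, run the network, return mg/dL."""
    out = forward(net, scaler.transform_x(X_raw))
    return np.asarray(scaler.inverse_y(out))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(path: str | Path, net: NetworkParams, scaler: Scaler,
               sched: TrainingSchedule | None = None) -> None:
    d = {
        "layer_sizes": list(net.layer_sizes),
        "hidden_activation": net.hidden_activation,
        "seed": net.seed,
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "scaler": {
            "feature_means": scaler.feature_means.tolist(),
            "feature_sds": scaler.feature_sds.tolist(),
            "target_mean": scaler.target_mean,
            "target_sd": scaler.target_sd,
        },
    }
    if sched is not None:
        d["schedule"] = {"max_epochs": sched.max_epochs, "lr0": sched.lr0,
                         "decay_every": sched.decay_every,
                         "decay_factor": sched.decay_factor,
                         "early_stop_patience": sched.early_stop_patience}
    Path(path).write_text(json.dumps(d))


def load_model(path: str | Path) -> tuple[NetworkParams, Scaler]:
    d = json.loads(Path(path).read_text())
    net = NetworkParams(tuple(d["layer_sizes"]),
                        [np.array(w) for w in d["weights"]],
                        [np.array(b) for b in d["biases"]],
                        d["hidden_activation"], int(d["seed"]))
    s = d["scaler"]
    scaler = Scaler(feature_means=np.array(s["feature_means"]),
                    feature_sds=np.array(s["feature_sds"]),
                    target_mean=s["target_mean"], target_sd=s["target_sd"])
    return net, scaler
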