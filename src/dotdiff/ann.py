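"""Multilayer perceptron mapping lesion-side measurements to matched perturbations.

The network replaces the reference measurement in difference imaging: its
input is the normalized lesion-side measurement (126 offset log(A*rho^2)
values followed by 126 offset unwrapped phases) and its output is the
matched normalized perturbation (126 real parts followed by 126 imaginary
parts).  Architecture: 252 - 256 - 128 - 256 - 252, ReLU after every
affine layer except the last.  Training: mean-square-error loss, Adam
with learning rate 1e-4 and weight decay 1e-5, batch size 64, 200 epochs,
learning rate cut to 0.2x whenever the validation loss has not improved
for three consecutive epochs; the returned parameters are those with the
lowest validation loss.

Everything is implemented on numpy: the model is small enough that a CPU
trains it in minutes, and full determinism under a seed is part of the
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FDMeasurement
from .perturbation import Perturbation, normalize_for_network


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    layer_widths: tuple = (252, 256, 128, 256, 252)

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 2:
            raise ValueError("need at least input and output layers")


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    lr_factor: float = 0.2
    lr_patience: int = 3
    rng_seed: int = 0


@dataclass
class MLPModel:
    """Feedforward ReLU network with explicit parameter arrays."""

    spec: ModelSpec
    weights: list = field(repr=False)
    biases: list = field(repr=False)
    seed: int = 0

    @property
    def parameter_count(self) -> int:
        return int(
            sum(w.size for w in self.weights) + sum(b.size for b in self.biases)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batched forward pass; final layer is affine (unbounded outputs)."""
        a = np.atleast_2d(np.asarray(x, dtype=float))
        if a.shape[1] != self.spec.layer_widths[0]:
            raise ValueError(
                f"input width {a.shape[1]} != model width {self.spec.layer_widths[0]}"
            )
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ w + b
            if i != last:
                np.maximum(a, 0.0, out=a)
        return a

    def copy_params(self) -> tuple[list, list]:
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    def set_params(self, params: tuple[list, list]) -> None:
        self.weights = [w.copy() for w in params[0]]
        self.biases = [b.copy() for b in params[1]]


def build_model(spec: ModelSpec = ModelSpec(), rng_seed: int = 0) -> MLPModel:
    """Seeded uniform fan-in initialization: U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
    rng = np.random.default_rng(rng_seed)
    weights, biases = [], []
    for n_in, n_out in zip(spec.layer_widths[:-1], spec.layer_widths[1:]):
        bound = 1.0 / np.sqrt(n_in)
        weights.append(rng.uniform(-bound, bound, size=(n_in, n_out)))
        biases.append(rng.uniform(-bound, bound, size=n_out))
    return MLPModel(spec=spec, weights=weights, biases=biases, seed=rng_seed)


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


def _backward(model: MLPModel, x: np.ndarray, y: np.ndarray):
    """Forward + backprop of the MSE loss; returns (loss, grads_w, grads_b)."""
    acts = [x]
    pre = []
    a = x
    last = len(model.weights) - 1
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w + b
        pre.append(z)
        a = np.maximum(z, 0.0) if i != last else z
        acts.append(a)
    loss = _mse(acts[-1], y)
    delta = 2.0 * (acts[-1] - y) / y.size
    grads_w = [None] * len(model.weights)
    grads_b = [None] * len(model.biases)
    for i in range(last, -1, -1):
        grads_w[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * (pre[i - 1] > 0)
    return loss, grads_w, grads_b


def train(model: MLPModel, train_set, val_set, config: TrainConfig = TrainConfig()):
    """Train with Adam + plateau LR schedule; keep the best-validation weights.

    Parameters
    ----------
    train_set, val_set : objects with ``X`` (n, 252) and ``Y`` (n, 252) arrays
        (e.g. :class:`dotdiff.synthdata.Corpus`).

    Returns
    -------
    (model, history) : the model with its best-validation parameters loaded,
        and a dict with per-epoch ``train_loss``, ``val_loss``, ``lr``.
    """
    Xtr, Ytr = np.asarray(train_set.X, float), np.asarray(train_set.Y, float)
    Xva, Yva = np.asarray(val_set.X, float), np.asarray(val_set.Y, float)
    if Xtr.shape[0] == 0 or Xva.shape[0] == 0:
        raise TrainingError("empty training or validation corpus")
    rng = np.random.default_rng(config.rng_seed)
    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    t = 0
    best_val = np.inf
    best_params = model.copy_params()
    stall = 0
    history = {"train_loss": [], "val_loss": [], "lr": []}
    n = Xtr.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, gw, gb = _backward(model, Xtr[idx], Ytr[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}, step {nb}"
                )
            epoch_loss += loss
            nb += 1
            grads = gw + gb
            t += 1
            for j, (p, g) in enumerate(zip(params, grads)):
                g = g + config.weight_decay * p  # coupled L2, Adam-style
                m[j] = beta1 * m[j] + (1 - beta1) * g
                v[j] = beta2 * v[j] + (1 - beta2) * g * g
                mhat = m[j] / (1 - beta1**t)
                vhat = v[j] / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        val_loss = _mse(model.forward(Xva), Yva)
        history["train_loss"].append(epoch_loss / max(nb, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if val_loss < best_val:
            best_val = val_loss
            best_params = model.copy_params()
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_patience:
                lr *= config.lr_factor
                stall = 0
    model.set_params(best_params)
    history["best_val_loss"] = best_val
    return model, history


def predict_perturbation(model: MLPModel, Ul: FDMeasurement) -> Perturbation:
    """Predict the matched perturbation from the lesion-side measurement alone.

    No reference measurement enters: the prediction is a pure function of
    Ul (after offset normalization), which is the point of the approach --
    the output is always a *matched* perturbation, whatever reference
    would have been available.
    """
    x = normalize_for_network(Ul).to_vector()
    if x.size != model.spec.layer_widths[0]:
        raise ValueError("measurement width does not match the model input layer")
    y = model.forward(x)[0]
    return Perturbation.from_vector(y, Ul.wavelength, "ann_predicted")


def constant_predictor_mse(train_set, val_set) -> float:
    """Validation MSE of the best constant predictor (training-set mean target).

    The baseline every trained model must beat: predicting the mean
    perturbation of the training corpus for every input.
    """
    mean = np.asarray(train_set.Y, float).mean(axis=0)
    return _mse(np.broadcast_to(mean, np.asarray(val_set.Y).shape), val_set.Y)
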