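"""From-scratch multilayer sigmoid perceptron.

One network per input channel (six serum markers, two image features).
Every layer applies the logistic sigmoid; training is batch gradient
descent on the squared-error loss E = 1/2 * sum (desired - actual)^2 with
momentum and bold-driver learning-rate adaptation (grow the rate on an
accepted step, halve it and drop momentum on a rejected one), so the
accepted-step error sequence is non-increasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkConfig",
    "Network",
    "TrainResult",
    "sigmoid",
    "forward",
    "loss",
    "gradients",
    "init_weights",
    "train",
    "predict_score",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Training/initialization hyper-parameters.

    ``eta_w``/``eta_b`` are the initial learning rates for weights and
    biases (adapted during training, floor ``lr_floor``); ``momentum`` is
    the dynamic coefficient scaling the previous update; initial weights
    and biases are drawn uniformly from [init_low, init_high) which must
    stay inside [0, 0.5].
    """

    layer_sizes: tuple[int, ...]
    eta_w: float = 0.9
    eta_b: float = 0.9
    momentum: float = 0.7
    tolerance: float = 1e-4
    init_low: float = 0.0
    init_high: float = 0.5
    max_epochs: int = 20000
    seed: int = 0
    lr_floor: float = 1e-4
    lr_grow: float = 1.05
    lr_shrink: float = 0.5

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 2 or any(s < 1 for s in sizes):
            raise ValueError("layer_sizes needs >= 2 positive entries")
        if sizes[-1] != 1:
            raise ValueError("last layer size must be 1 (scalar score)")
        if not (0.0 <= self.init_low < self.init_high <= 0.5):
            raise ValueError("init support must satisfy 0 <= low < high <= 0.5")
        if self.eta_w <= 0 or self.eta_b <= 0:
            raise ValueError("learning rates must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "eta_w": self.eta_w,
            "eta_b": self.eta_b,
            "momentum": self.momentum,
            "tolerance": self.tolerance,
            "init_low": self.init_low,
            "init_high": self.init_high,
            "max_epochs": self.max_epochs,
            "seed": self.seed,
            "lr_floor": self.lr_floor,
            "lr_grow": self.lr_grow,
            "lr_shrink": self.lr_shrink,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkConfig":
        data = dict(data)
        data["layer_sizes"] = tuple(data["layer_sizes"])
        return cls(**data)


@dataclass
class Network:
    """Layered weights W[m] of shape (out, in) and biases b[m] of shape (out,)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self):
        if len(self.weights) != len(self.biases):
            raise ValueError("weights/biases layer counts differ")
        for m, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or b.shape != (w.shape[0],):
                raise ValueError(f"layer {m}: inconsistent shapes {w.shape} / {b.shape}")
            if m > 0 and w.shape[1] != self.weights[m - 1].shape[0]:
                raise ValueError(f"layer {m}: input size does not chain")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1],) + tuple(w.shape[0] for w in self.weights)

    def copy(self) -> "Network":
        return Network([w.copy() for w in self.weights], [b.copy() for b in self.biases])


@dataclass(frozen=True)
class TrainResult:
    final_error: float
    epochs_run: int
    error_trajectory: tuple[float, ...]


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)), saturating at the extremes."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def _forward_batch(net: Network, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer for a (n, d) batch; index 0 is the input."""
    acts = [X]
    a = X
    for w, b in zip(net.weights, net.biases):
        a = sigmoid(a @ w.T + b)
        acts.append(a)
    return acts


def forward(net: Network, x: Sequence[float]) -> tuple[float, list[np.ndarray]]:
    """Single-sample forward pass: (scalar output, per-layer activations)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != net.layer_sizes[0]:
        raise ValueError(
            f"input length {x.shape} does not match first layer size {net.layer_sizes[0]}"
        )
    acts = _forward_batch(net, x[None, :])
    return float(acts[-1][0, 0]), [a[0] for a in acts]


def loss(outputs: Sequence[float], desired: Sequence[float]) -> float:
    """Squared-error loss E = 1/2 * sum (desired - actual)^2."""
    out = np.asarray(outputs, dtype=float)
    des = np.asarray(desired, dtype=float)
    if out.shape != des.shape:
        raise ValueError("outputs and desired lengths differ")
    return 0.5 * float(np.sum((des - out) ** 2))


def _gradients_batch(net: Network, X: np.ndarray, y: np.ndarray):
    """Exact batch gradients of the squared-error loss (summed over samples)."""
    acts = _forward_batch(net, X)
    out = acts[-1][:, 0]
    # delta at the output: dE/dz = (a - d) * a * (1 - a)
    delta = ((out - y) * out * (1.0 - out))[:, None]
    gw = [None] * len(net.weights)
    gb = [None] * len(net.biases)
    for m in range(len(net.weights) - 1, -1, -1):
        gw[m] = delta.T @ acts[m]
        gb[m] = delta.sum(axis=0)
        if m > 0:
            a = acts[m]
            delta = (delta @ net.weights[m]) * a * (1.0 - a)
    return gw, gb


def gradients(net: Network, x: Sequence[float], desired: float):
    """Backpropagated gradients dE/dW, dE/db for one sample (lists per layer)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != net.layer_sizes[0]:
        raise ValueError("input length does not match first layer size")
    return _gradients_batch(net, x[None, :], np.asarray([desired], dtype=float))


def init_weights(config: NetworkConfig) -> Network:
    """Seeded uniform initialization of weights and biases in
    [init_low, init_high) subset of [0, 0.5)."""
    rng = np.random.default_rng(config.seed)
    sizes = config.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(config.init_low, config.init_high, size=(fan_out, fan_in)))
        biases.append(rng.uniform(config.init_low, config.init_high, size=fan_out))
    return Network(weights=weights, biases=biases)


def _batch_loss(net: Network, X: np.ndarray, y: np.ndarray) -> float:
    out = _forward_batch(net, X)[-1][:, 0]
    return 0.5 * float(np.sum((y - out) ** 2))


def train(
    net: Network,
    inputs: Sequence[Sequence[float]],
    desired: Sequence[float],
    config: NetworkConfig,
) -> tuple[Network, TrainResult]:
    """Batch gradient descent with momentum and bold-driver adaptation.

    Each epoch proposes ``param += momentum * previous_update - eta * grad``;
    the step is accepted iff it does not increase E (then both rates grow by
    ``lr_grow``), otherwise it is rejected, rates halve (floored at
    ``lr_floor``) and the momentum buffer resets.  Training stops at
    ``E <= tolerance`` or ``max_epochs``.  The recorded trajectory holds the
    accepted error after every epoch and is therefore non-increasing.
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(desired, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must be a nonempty 2-D array")
    if y.shape != (X.shape[0],):
        raise ValueError("desired outputs must align with inputs")
    if X.shape[1] != net.layer_sizes[0]:
        raise ValueError("input width does not match the network")

    net = net.copy()
    vel_w = [np.zeros_like(w) for w in net.weights]
    vel_b = [np.zeros_like(b) for b in net.biases]
    lr_w, lr_b = config.eta_w, config.eta_b
    err = _batch_loss(net, X, y)
    trajectory = [err]
    epochs = 0
    for _ in range(config.max_epochs):
        if err <= config.tolerance:
            break
        epochs += 1
        gw, gb = _gradients_batch(net, X, y)
        cand_vw = [config.momentum * v - lr_w * g for v, g in zip(vel_w, gw)]
        cand_vb = [config.momentum * v - lr_b * g for v, g in zip(vel_b, gb)]
        cand = Network(
            [w + dv for w, dv in zip(net.weights, cand_vw)],
            [b + dv for b, dv in zip(net.biases, cand_vb)],
        )
        new_err = _batch_loss(cand, X, y)
        if new_err <= err:
            net, err = cand, new_err
            vel_w, vel_b = cand_vw, cand_vb
            lr_w *= config.lr_grow
            lr_b *= config.lr_grow
        else:
            lr_w = max(lr_w * config.lr_shrink, config.lr_floor)
            lr_b = max(lr_b * config.lr_shrink, config.lr_floor)
            vel_w = [np.zeros_like(w) for w in net.weights]
            vel_b = [np.zeros_like(b) for b in net.biases]
        trajectory.append(err)
    return net, TrainResult(
        final_error=err, epochs_run=epochs, error_trajectory=tuple(trajectory)
    )


def predict_score(net: Network, x: Sequence[float]) -> float:
    """Forward-pass scalar score in (0, 1)."""
    return forward(net, x)[0]


def save_network(net: Network, path, config: NetworkConfig | None = None) -> None:
    """Serialize to JSON; floats survive round-trip bit-exactly (repr)."""
    payload = {
        "layer_sizes": list(net.layer_sizes),
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "config": config.to_dict() if config is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_network(path) -> tuple[Network, NetworkConfig | None]:
    with open(path) as fh:
        payload = json.load(fh)
    net = Network(
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
    )
    cfg = payload.get("config")
    return net, (NetworkConfig.from_dict(cfg) if cfg else None)
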