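"""The convolutional classifier over 2x13 feature matrices.

Architecture (fixed by ``CNNConfig`` defaults):

    input (2, 13, 1)
    conv 64 filters, kernel (1,4), tanh   -> (2, 10, 64)
    max-pool (2,2), stride = size         -> (1, 5, 64)
    conv 128 filters, kernel (1,2), tanh  -> (1, 4, 128)
    max-pool (1,2)                        -> (1, 2, 128)
    flatten                               -> 256
    dense 512, tanh                       -> 512
    dense 2, sigmoid                      -> 2

Convolutions use valid padding and pooling stride equals pool size — the only
convention under which these layer shapes fit a 2x13 input. The two output
units are independent sigmoids trained with per-unit binary cross-entropy on
one-hot labels; the score of a sample is the "associated" unit (index 1).

Everything is implemented directly on numpy arrays (float64) with analytic
backpropagation; the small input and parameter sizes make this entirely
CPU-friendly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit


class ShapeError(ValueError):
    pass


class ArchitectureError(ValueError):
    """A layer configuration yields a non-positive output dimension."""


class TrainingError(RuntimeError):
    pass


@dataclass
class CNNConfig:
    conv1_filters: int = 64
    conv1_kernel: tuple[int, int] = (1, 4)
    pool1_size: tuple[int, int] = (2, 2)
    conv2_filters: int = 128
    conv2_kernel: tuple[int, int] = (1, 2)
    pool2_size: tuple[int, int] = (1, 2)
    dense_units: int = 512
    input_shape: tuple[int, int] = (2, 13)
    optimizer: str = "adam"  # "adam" | "sgd"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int | None = None  # None = full batch
    seed: int = 0


@dataclass
class DNNConfig:
    """Fully connected baseline over the flattened 26-dim feature."""

    hidden_sizes: tuple[int, ...] = (64, 32)
    input_dim: int = 26
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid-padding 2-D convolution on (n, H, W, C) arrays, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator) -> None:
        super().__init__()
        kh, kw = kernel
        self.kh, self.kw = kh, kw
        fan_in = kh * kw * in_ch
        self.W = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(kh, kw, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, H, W, C = x.shape
        kh, kw = self.kh, self.kw
        Ho, Wo = H - kh + 1, W - kw + 1
        cols = np.empty((n, Ho, Wo, kh, kw, C))
        for i in range(kh):
            for j in range(kw):
                cols[:, :, :, i, j, :] = x[:, i : i + Ho, j : j + Wo, :]
        self._cols = cols.reshape(n, Ho, Wo, kh * kw * C)
        self._x_shape = x.shape
        out_ch = self.W.shape[-1]
        return self._cols @ self.W.reshape(-1, out_ch) + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, Ho, Wo, out_ch = dout.shape
        kh, kw = self.kh, self.kw
        K = self._cols.shape[-1]
        Wmat = self.W.reshape(K, out_ch)
        self.grads[0][...] = (
            self._cols.reshape(-1, K).T @ dout.reshape(-1, out_ch)
        ).reshape(self.W.shape)
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        dcols = (dout @ Wmat.T).reshape(n, Ho, Wo, kh, kw, -1)
        dx = np.zeros(self._x_shape)
        for i in range(kh):
            for j in range(kw):
                dx[:, i : i + Ho, j : j + Wo, :] += dcols[:, :, :, i, j, :]
        return dx


class MaxPool2D(Layer):
    """Max pooling with stride equal to pool size; trailing rows/cols beyond
    a full window are cropped (none arise with the default shapes)."""

    def __init__(self, size: tuple[int, int]) -> None:
        super().__init__()
        self.ph, self.pw = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, H, W, C = x.shape
        ph, pw = self.ph, self.pw
        Ho, Wo = H // ph, W // pw
        xc = x[:, : Ho * ph, : Wo * pw, :]
        win = (
            xc.reshape(n, Ho, ph, Wo, pw, C)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, Ho, Wo, C, ph * pw)
        )
        self._argmax = win.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, Ho, Wo, C = dout.shape
        ph, pw = self.ph, self.pw
        dwin = np.zeros((n, Ho, Wo, C, ph * pw))
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._x_shape)
        dx[:, : Ho * ph, : Wo * pw, :] = (
            dwin.reshape(n, Ho, Wo, C, ph, pw)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, Ho * ph, Wo * pw, C)
        )
        return dx


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._y**2)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


# ---------------------------------------------------------------------------
# network, loss, optimizers
# ---------------------------------------------------------------------------

class Network:
    """Sequence of layers ending in a linear head whose outputs are passed
    through independent sigmoids and trained with per-unit binary
    cross-entropy on one-hot labels."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return expit(self.forward_logits(x))

    def loss_and_backward(self, x: np.ndarray, t_onehot: np.ndarray) -> float:
        """Mean BCE over samples and output units; fills layer gradients."""
        logits = self.forward_logits(x)
        p = expit(logits)
        eps = 1e-12
        loss = float(
            -(t_onehot * np.log(p + eps) + (1 - t_onehot) * np.log(1 - p + eps)).mean()
        )
        dlogits = (p - t_onehot) / p.size  # sigmoid+BCE fused gradient
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [
            (p, g)
            for layer in self.layers
            for p, g in zip(layer.params, layer.grads)
        ]


class SGD:
    def __init__(self, lr: float) -> None:
        self.lr = lr

    def step(self, params_grads) -> None:
        for p, g in params_grads:
            p -= self.lr * g


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params_grads) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p, _ in params_grads]
            self.v = [np.zeros_like(p) for p, _ in params_grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(params_grads):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_optimizer(name: str, lr: float):
    if name == "sgd":
        return SGD(lr)
    if name == "adam":
        return Adam(lr)
    raise ValueError(f"unknown optimizer {name!r}")


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def cnn_shape_chain(config: CNNConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Output shape of every layer for the given config; raises
    :class:`ArchitectureError` if any dimension becomes non-positive."""
    H, W = config.input_shape
    chain: list[tuple[str, tuple[int, ...]]] = [("input", (H, W, 1))]

    def check(name: str, shape: tuple[int, ...]) -> None:
        if any(d < 1 for d in shape):
            raise ArchitectureError(f"layer {name} yields impossible shape {shape}")
        chain.append((name, shape))

    kh, kw = config.conv1_kernel
    H, W, C = H - kh + 1, W - kw + 1, config.conv1_filters
    check("conv1", (H, W, C))
    ph, pw = config.pool1_size
    check("pool1", (H // ph, W // pw, C))
    H, W = H // ph, W // pw
    kh, kw = config.conv2_kernel
    H, W, C = H - kh + 1, W - kw + 1, config.conv2_filters
    check("conv2", (H, W, C))
    ph, pw = config.pool2_size
    check("pool2", (H // ph, W // pw, C))
    H, W = H // ph, W // pw
    check("flatten", (H * W * C,))
    check("dense", (config.dense_units,))
    check("output", (2,))
    return chain


def build_cnn(config: CNNConfig | None = None) -> Network:
    """Build the (untrained) convolutional classifier; weights are drawn from
    the seeded generator so construction is deterministic."""
    config = config or CNNConfig()
    chain = cnn_shape_chain(config)  # validates the architecture
    flat = chain[-3][1][0]
    rng = np.random.default_rng(config.seed)
    return Network(
        [
            Conv2D(1, config.conv1_filters, config.conv1_kernel, rng),
            Tanh(),
            MaxPool2D(config.pool1_size),
            Conv2D(config.conv1_filters, config.conv2_filters, config.conv2_kernel, rng),
            Tanh(),
            MaxPool2D(config.pool2_size),
            Flatten(),
            Dense(flat, config.dense_units, rng),
            Tanh(),
            Dense(config.dense_units, 2, rng),
        ]
    )


def build_dnn(config: DNNConfig | None = None) -> Network:
    """Fully connected baseline network on flattened features."""
    config = config or DNNConfig()
    rng = np.random.default_rng(config.seed)
    layers: list[Layer] = [Flatten()]
    n_in = config.input_dim
    for n_h in config.hidden_sizes:
        layers += [Dense(n_in, n_h, rng), Tanh()]
        n_in = n_h
    layers.append(Dense(n_in, 2, rng))
    return Network(layers)


# ---------------------------------------------------------------------------
# training and scoring
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A fitted network plus the bookkeeping needed to score new samples."""

    architecture: str  # "cnn" | "dnn" | "pca_cnn"
    network: Network
    input_shape: tuple[int, ...]
    history: list[float] = field(default_factory=list)
    preprocessing: str = ""

    def score(self, features: np.ndarray) -> np.ndarray:
        return predict_scores(self, features)


def _prepare_inputs(features: np.ndarray, input_shape: tuple[int, ...]) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim == len(input_shape):
        x = x[None, ...]
    if x.shape[1:] != tuple(input_shape):
        raise ShapeError(
            f"expected features shaped (*, {input_shape}), got {x.shape}"
        )
    if len(input_shape) == 2:  # add channel axis for conv nets
        x = x[..., None]
    return x


def train_classifier(
    network: Network,
    features: np.ndarray,
    labels: np.ndarray,
    *,
    architecture: str = "cnn",
    input_shape: tuple[int, ...] = (2, 13),
    optimizer: str = "adam",
    learning_rate: float = 1e-3,
    epochs: int = 200,
    batch_size: int | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit a network on (features, binary labels).

    Labels are one-hot encoded as (not-associated, associated); training is
    full-batch by default and deterministic given the seed (which drives
    mini-batch shuffling when ``batch_size`` is set).
    """
    labels = np.asarray(labels).astype(int)
    x = _prepare_inputs(features, input_shape)
    if x.shape[0] != labels.shape[0]:
        raise ShapeError("features and labels disagree on sample count")
    if len(np.unique(labels)) < 2:
        raise TrainingError("training data must contain both classes")
    t = np.zeros((labels.shape[0], 2))
    t[np.arange(labels.shape[0]), labels] = 1.0

    opt = _make_optimizer(optimizer, learning_rate)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    history: list[float] = []
    for _ in range(epochs):
        if batch_size is None or batch_size >= n:
            loss = network.loss_and_backward(x, t)
            opt.step(network.parameters())
            history.append(loss)
        else:
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                loss = network.loss_and_backward(x[idx], t[idx])
                opt.step(network.parameters())
                epoch_loss += loss * len(idx)
            history.append(epoch_loss / n)
    return TrainedClassifier(
        architecture=architecture,
        network=network,
        input_shape=tuple(input_shape),
        history=history,
    )


def predict_scores(model: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    """Score in [0, 1] per sample: the sigmoid output of the 'associated' unit."""
    x = _prepare_inputs(features, model.input_shape)
    return model.network.predict_proba(x)[:, 1]


def training_accuracy(model: TrainedClassifier, features: np.ndarray,
                      labels: np.ndarray) -> float:
    scores = predict_scores(model, features)
    return float(((scores >= 0.5).astype(int) == np.asarray(labels)).mean())
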