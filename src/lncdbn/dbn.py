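"""Restricted Boltzmann machines and their greedy stack (deep belief network).

The DBN is used purely as an unsupervised encoder: it compresses the binary
target-gene vector (length = panel size, 45 under the default filter) down to
a 13-dimensional code that can sit on top of the 13-tissue expression row in
the final 2x13 feature matrix.

An RBM is a bipartite stochastic network with visible units ``v`` and hidden
units ``h``, energy ``E(v, h) = -a.v - b.h - h.W.v``. Because the graph is
bipartite, the conditional distributions factorise:

    p(h_j = 1 | v) = sigmoid(b_j + W[j, :] . v)
    p(v_i = 1 | h) = sigmoid(a_i + W[:, i] . h)

Training uses contrastive divergence (CD-k, default k=1): the positive
statistics come from the data, the negative statistics from ``k`` steps of
block Gibbs sampling started at the data. The stack is trained greedily,
layer by layer, each layer's hidden-unit *probabilities* (not samples)
serving as the training data of the next. Encoding is the deterministic
composition of the per-layer hidden-probability maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

DEFAULT_LAYER_SIZES: tuple[int, ...] = (32, 13)


class ShapeError(ValueError):
    """An array does not match the layer shape contract."""


class TrainingError(RuntimeError):
    """Non-finite parameters or gradients encountered during training."""


def sigmoid(x):
    """Numerically stable logistic function, sigma(x) = 1 / (1 + exp(-x)).

    Saturates to 0/1 for large |x| without overflow or NaN.
    """
    return expit(np.asarray(x, dtype=float))


@dataclass
class TrainingConfig:
    """Hyper-parameters for CD-k training of one RBM layer.

    The learning rate, epoch count and batch size are free choices of this
    implementation; defaults are sized for the small (hundreds of rows,
    tens of columns) matrices this pipeline feeds the encoder.
    """

    learning_rate: float = 0.1
    epochs: int = 100
    cd_steps: int = 1
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class RBMParams:
    """Weights and biases of one RBM layer.

    ``W`` is (n_hidden, n_visible); ``a`` is the visible bias, ``b`` the
    hidden bias.
    """

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        nh, nv = self.W.shape
        if self.a.shape != (nv,) or self.b.shape != (nh,):
            raise ShapeError(
                f"inconsistent RBM shapes: W{self.W.shape}, a{self.a.shape}, "
                f"b{self.b.shape}"
            )
        if not (
            np.all(np.isfinite(self.W))
            and np.all(np.isfinite(self.a))
            and np.all(np.isfinite(self.b))
        ):
            raise TrainingError("non-finite RBM parameters")

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]


@dataclass
class DBNModel:
    """Greedily trained stack of RBMs used as a deterministic encoder."""

    layers: list[RBMParams]
    layer_sizes: tuple[int, ...]
    #: per layer, per epoch mean reconstruction cross-entropy (index 0 is the
    #: value at initialisation, before any update)
    training_log: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if nxt.n_visible != prev.n_hidden:
                raise ShapeError(
                    f"layer stacking mismatch: {prev.n_hidden} hidden feeds "
                    f"{nxt.n_visible} visible"
                )

    @property
    def code_size(self) -> int:
        return self.layers[-1].n_hidden


def _as_batch(v: np.ndarray, n_visible: int) -> tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    if single:
        v = v[None, :]
    if v.ndim != 2 or v.shape[1] != n_visible:
        raise ShapeError(f"expected (*, {n_visible}) input, got {v.shape}")
    return v, single


def rbm_hidden_prob(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(h=1 | v), element-wise sigmoid(b + W v). Accepts a vector or matrix."""
    vb, single = _as_batch(v, params.n_visible)
    p = expit(vb @ params.W.T + params.b)
    return p[0] if single else p


def rbm_visible_prob(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(v=1 | h), element-wise sigmoid(a + W^T h)."""
    hb, single = _as_batch(h, params.n_hidden)
    p = expit(hb @ params.W + params.a)
    return p[0] if single else p


def reconstruction_cross_entropy(data: np.ndarray, params: RBMParams) -> float:
    """Mean Bernoulli cross-entropy between data and its deterministic
    one-step reconstruction (probabilities up, probabilities down)."""
    data, _ = _as_batch(data, params.n_visible)
    ph = rbm_hidden_prob(data, params)
    pv = rbm_visible_prob(ph, params)
    eps = 1e-12
    ce = -(data * np.log(pv + eps) + (1.0 - data) * np.log(1.0 - pv + eps))
    return float(ce.sum(axis=1).mean())


def initialize_rbm(n_visible: int, n_hidden: int, rng: np.random.Generator) -> RBMParams:
    # small random weights break hidden-unit symmetry; biases start at zero
    W = rng.normal(0.0, 0.01, size=(n_hidden, n_visible))
    return RBMParams(W=W, a=np.zeros(n_visible), b=np.zeros(n_hidden))


def rbm_train_cd(
    data: np.ndarray, n_hidden: int, config: TrainingConfig
) -> tuple[RBMParams, list[float]]:
    """Train one RBM with CD-k; returns params and the per-epoch loss curve.

    ``data`` is binary (or in [0,1], treated as Bernoulli probabilities).
    Fully deterministic given ``(data, config)``: the seeded generator drives
    initialisation, epoch shuffling and Gibbs sampling in a fixed order.
    The loss curve records mean reconstruction cross-entropy, entry 0 being
    the value at initialisation.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValueError("data must be a non-empty 2-D matrix")
    if np.any((data < 0) | (data > 1)):
        raise ValueError("data entries must lie in [0, 1]")
    n, n_visible = data.shape
    rng = np.random.default_rng(config.seed)
    params = initialize_rbm(n_visible, n_hidden, rng)
    log = [reconstruction_cross_entropy(data, params)]
    lr = config.learning_rate
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            v0 = data[order[start : start + config.batch_size]]
            m = v0.shape[0]
            ph0 = rbm_hidden_prob(v0, params)
            h = (rng.random(ph0.shape) < ph0).astype(float)
            for _ in range(config.cd_steps):
                pv = rbm_visible_prob(h, params)
                ph = rbm_hidden_prob(pv, params)
                h = (rng.random(ph.shape) < ph).astype(float)
            dW = (ph0.T @ v0 - ph.T @ pv) / m
            da = (v0 - pv).mean(axis=0)
            db = (ph0 - ph).mean(axis=0)
            if not (
                np.all(np.isfinite(dW))
                and np.all(np.isfinite(da))
                and np.all(np.isfinite(db))
            ):
                raise TrainingError(f"non-finite gradient at epoch {epoch}")
            params.W += lr * dW
            params.a += lr * da
            params.b += lr * db
        log.append(reconstruction_cross_entropy(data, params))
    return params, log


def dbn_train(
    data: np.ndarray,
    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES,
    config: TrainingConfig | None = None,
) -> DBNModel:
    """Greedy layer-wise pretraining of the RBM stack.

    Layer 1 is trained on ``data``; layer l on layer l-1's hidden
    probabilities (the deterministic, low-variance choice). Each layer's
    seed is derived from ``config.seed`` and the layer index.
    """
    if not layer_sizes:
        raise ValueError("layer_sizes must be non-empty")
    config = config or TrainingConfig()
    layers: list[RBMParams] = []
    logs: list[list[float]] = []
    current = np.asarray(data, dtype=float)
    for l, n_hidden in enumerate(layer_sizes):
        layer_cfg = TrainingConfig(
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            cd_steps=config.cd_steps,
            batch_size=config.batch_size,
            seed=(int(config.seed) + l) % (2**31),
        )
        params, log = rbm_train_cd(current, n_hidden, layer_cfg)
        layers.append(params)
        logs.append(log)
        current = rbm_hidden_prob(current, params)
    return DBNModel(layers=layers, layer_sizes=tuple(layer_sizes), training_log=logs)


def dbn_encode(v: np.ndarray, model: DBNModel) -> np.ndarray:
    """Deterministic forward pass of hidden probabilities through the stack.

    Output entries lie strictly in (0, 1); no sampling is involved, so two
    calls on the same input are bitwise identical.
    """
    out = v
    for params in model.layers:
        out = rbm_hidden_prob(out, params)
    return out


def combine_features(code: np.ndarray, expr: np.ndarray) -> np.ndarray:
    """Stack the gene code over the expression vector into the 2x13 feature.

    Row 0 is the DBN code of the target-gene feature, row 1 the 13-tissue
    expression profile. The two must have equal length (13 under the default
    layer sizes); a mismatch is a configuration error.
    """
    code = np.asarray(code, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if code.ndim != 1 or expr.ndim != 1 or code.shape != expr.shape:
        raise ShapeError(
            f"code and expression must be equal-length vectors, got "
            f"{code.shape} and {expr.shape}"
        )
    return np.vstack([code, expr])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_dbn(path, model: DBNModel) -> None:
    """Save a DBN as keyed arrays (.npz) with the layer sizes embedded."""
    arrays: dict[str, np.ndarray] = {
        "layer_sizes": np.asarray(model.layer_sizes, dtype=np.int64)
    }
    for i, p in enumerate(model.layers):
        arrays[f"W_{i}"] = p.W
        arrays[f"a_{i}"] = p.a
        arrays[f"b_{i}"] = p.b
        arrays[f"log_{i}"] = np.asarray(model.training_log[i], dtype=float)
    np.savez(path, **arrays)


def load_dbn(path) -> DBNModel:
    with np.load(path) as data:
        sizes = tuple(int(s) for s in data["layer_sizes"])
        layers = [
            RBMParams(W=data[f"W_{i}"], a=data[f"a_{i}"], b=data[f"b_{i}"])
            for i in range(len(sizes))
        ]
        logs = [list(map(float, data[f"log_{i}"])) for i in range(len(sizes))]
    return DBNModel(layers=layers, layer_sizes=sizes, training_log=logs)
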