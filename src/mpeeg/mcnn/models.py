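"""Model definitions: the multi-scale CNN and the LeNet-5 baseline.

The multi-scale network runs two parallel sub-networks over the same
32 x 32 input: a 2-D stack (with an identity-skip residual block formed by
the two shape-preserving pad-2 convolutions) and a 1-D stack convolving
along the channel axis with 7x1 / 5x1 kernels.  Branch outputs are
flattened, concatenated, and fed to a dropout / dense-84 / dropout /
dense-``n_classes`` head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core.types import ValidationError
from .layers import (
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool2D,
    Param,
    ReLU,
    Residual,
    Sequential,
)


@dataclass
class MCNNConfig:
    """Architecture + optimization settings.

    ``decay`` is the inverse-time learning-rate decay coefficient
    (``lr_t = lr0 / (1 + decay * t)`` per epoch ``t``); set
    ``decay_mode='weight_decay'`` to reinterpret it as an L2 weight decay
    with constant learning rate.
    """

    input_side: int = 32
    n_classes: int = 2
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    decay: float = 0.1
    decay_mode: str = "inverse_time"
    max_epochs: int = 50
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValidationError(f"n_classes must be 2 or 3, got {self.n_classes}")
        if self.decay_mode not in ("inverse_time", "weight_decay"):
            raise ValidationError(f"unknown decay_mode {self.decay_mode!r}")
        if not 0 < self.learning_rate:
            raise ValidationError("learning rate must be positive")


class ClassifierNet:
    """Base: a layer graph with a class-probability head.

    ``n_classes == 2`` uses a width-2 sigmoid output trained with binary
    cross-entropy; ``n_classes == 3`` uses softmax with categorical
    cross-entropy.
    """

    def __init__(self, n_classes: int, rng: np.random.Generator) -> None:
        self.n_classes = n_classes
        self.rng = rng

    # subclasses set self.net (or override forward/backward)
    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def loss_and_grad(self, logits: np.ndarray, labels: np.ndarray
                      ) -> tuple[float, np.ndarray]:
        n = logits.shape[0]
        onehot = np.eye(self.n_classes)[labels]
        if self.n_classes == 2:
            p = _sigmoid(logits)
            eps = 1e-12
            loss = -np.mean(onehot * np.log(p + eps) + (1 - onehot) * np.log(1 - p + eps))
            dlogits = (p - onehot) / (n * self.n_classes)
        else:
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            p = ez / ez.sum(axis=1, keepdims=True)
            loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
            dlogits = (p - onehot) / n
        return float(loss), dlogits

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        chunks = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            if self.n_classes == 2:
                p = _sigmoid(logits)
                p = p / np.maximum(p.sum(axis=1, keepdims=True), 1e-12)
            else:
                z = logits - logits.max(axis=1, keepdims=True)
                ez = np.exp(z)
                p = ez / ez.sum(axis=1, keepdims=True)
            chunks.append(p)
        return np.concatenate(chunks, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value = v.copy()


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _check_chain(layers: list[Layer], shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """Propagate a (C, H, W) shape through conv/pool layers, raising on the
    first inconsistent layer."""
    for li, layer in enumerate(layers):
        if isinstance(layer, Conv2D):
            try:
                shape = layer.out_shape(shape)
            except ValueError as exc:
                raise ValidationError(f"layer {li}: {exc}") from exc
        elif isinstance(layer, MaxPool2D):
            c, h, w = shape
            shape = (c, h // layer.ph, w // layer.pw)
            if shape[1] < 1 or shape[2] < 1:
                raise ValidationError(f"layer {li}: pooling collapses {h}x{w} to zero")
        elif isinstance(layer, Residual):
            inner = _check_chain(layer.body.layers, shape)
            if inner != shape:
                raise ValidationError(
                    f"layer {li}: residual body maps {shape} to {inner}"
                )
    return shape


class MultiScaleCNN(ClassifierNet):
    """Two parallel sub-networks over one 32 x 32 input, concatenated head."""

    def __init__(self, cfg: MCNNConfig) -> None:
        super().__init__(cfg.n_classes, np.random.default_rng(cfg.seed))
        rng = self.rng
        self.cfg = cfg
        side = cfg.input_side
        # Sub-network 1: 2-D scale with the residual block.
        self.branch1 = Sequential([
            Conv2D(1, 6, 5, "same", rng, "s1.conv1"), ReLU(),
            MaxPool2D(2),
            Conv2D(6, 16, 5, 0, rng, "s1.conv2"), ReLU(),
            Residual([
                Conv2D(16, 16, 5, 2, rng, "s1.res_conv1"), ReLU(),
                Conv2D(16, 16, 5, 2, rng, "s1.res_conv2"), ReLU(),
            ]),
            MaxPool2D(2),
            Conv2D(16, 120, 5, 0, rng, "s1.conv5"), ReLU(),
            MaxPool2D(2),
            Flatten(),
        ])
        # Sub-network 2: 1-D scale, kernels run along the channel (row) axis.
        self.branch2 = Sequential([
            Conv2D(1, 32, (7, 1), "same", rng, "s2.conv1"), ReLU(),
            MaxPool2D((2, 1)),
            Conv2D(32, 64, (5, 1), 0, rng, "s2.conv2"), ReLU(),
            MaxPool2D((2, 1)),
            Flatten(),
        ])
        shape1 = _check_chain(self.branch1.layers, (1, side, side))
        shape2 = _check_chain(self.branch2.layers, (1, side, side))
        n1 = int(np.prod(shape1))
        n2 = int(np.prod(shape2))
        self.head = Sequential([
            Dropout(cfg.dropout_rate, rng),
            Dense(n1 + n2, 84, rng, "head.fc1"),
            ReLU(),
            Dropout(cfg.dropout_rate, rng),
            Dense(84, cfg.n_classes, rng, "head.fc2"),
        ])
        self._n1 = n1

    def params(self) -> list[Param]:
        return self.branch1.params() + self.branch2.params() + self.head.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y1 = self.branch1.forward(x, train=train)
        y2 = self.branch2.forward(x, train=train)
        return self.head.forward(np.concatenate([y1, y2], axis=1), train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dy = self.head.backward(grad)
        d1 = self.branch1.backward(dy[:, : self._n1])
        d2 = self.branch2.backward(dy[:, self._n1 :])
        return d1 + d2

    @property
    def residual_block(self) -> Residual:
        for layer in self.branch1.layers:
            if isinstance(layer, Residual):
                return layer
        raise RuntimeError("no residual block present")


class LeNet5(ClassifierNet):
    """Classic LeNet-5 topology on a 32 x 32 single-channel input."""

    def __init__(self, n_classes: int, seed: int = 0, dropout_rate: float = 0.0) -> None:
        super().__init__(n_classes, np.random.default_rng(seed))
        rng = self.rng
        self.net = Sequential([
            Conv2D(1, 6, 5, 0, rng, "conv1"), ReLU(),
            MaxPool2D(2),
            Conv2D(6, 16, 5, 0, rng, "conv2"), ReLU(),
            MaxPool2D(2),
            Conv2D(16, 120, 5, 0, rng, "conv3"), ReLU(),
            Flatten(),
            Dense(120, 84, rng, "fc1"), ReLU(),
            Dense(84, n_classes, rng, "fc2"),
        ])
        _check_chain(self.net.layers, (1, 32, 32))


def build_mcnn(cfg: MCNNConfig) -> MultiScaleCNN:
    """Construct the multi-scale CNN, validating the full shape chain."""
    return MultiScaleCNN(cfg)


def build_lenet5(n_classes: int, seed: int = 0) -> LeNet5:
    """Construct the LeNet-5 ablation baseline."""
    if n_classes not in (2, 3):
        raise ValidationError(f"n_classes must be 2 or 3, got {n_classes}")
    return LeNet5(n_classes, seed=seed)


def reshape_to_input(row: np.ndarray, n_channels: int = 32) -> np.ndarray:
    """Assemble one PSD+PLV feature row into a symmetric matrix.

    ``row`` is [PSD(n) || PLV(n*(n-1)/2)] in canonical pair order; the
    result places channel i's PSD at (i, i) and PLV of pair (i, j) at
    (i, j) and (j, i).  Exactly inverted by :func:`input_to_row`.
    """
    row = np.asarray(row, dtype=np.float64).reshape(-1)
    expected = n_channels + n_channels * (n_channels - 1) // 2
    if row.size != expected:
        raise ValidationError(
            f"feature row must have length {expected} for {n_channels} channels, "
            f"got {row.size}"
        )
    mat = np.zeros((n_channels, n_channels))
    np.fill_diagonal(mat, row[:n_channels])
    iu = np.triu_indices(n_channels, k=1)
    mat[iu] = row[n_channels:]
    mat[(iu[1], iu[0])] = row[n_channels:]
    return mat


def input_to_row(mat: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reshape_to_input`."""
    mat = np.asarray(mat, dtype=np.float64)
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValidationError("input must be square")
    iu = np.triu_indices(n, k=1)
    return np.concatenate([np.diag(mat), mat[iu]])


def rows_to_tensor(rows: np.ndarray, n_channels: int = 32) -> np.ndarray:
    """Vectorized reshape of many feature rows to (N, 1, side, side)."""
    rows = np.asarray(rows, dtype=np.float64)
    n = rows.shape[0]
    out = np.zeros((n, n_channels, n_channels))
    idx = np.arange(n_channels)
    out[:, idx, idx] = rows[:, :n_channels]
    iu = np.triu_indices(n_channels, k=1)
    out[:, iu[0], iu[1]] = rows[:, n_channels:]
    out[:, iu[1], iu[0]] = rows[:, n_channels:]
    return out[:, None, :, :]
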