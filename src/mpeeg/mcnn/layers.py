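"""Minimal numpy layer library with manual backpropagation.

Only what the multi-scale CNN needs: 2-D convolution (arbitrary kernel /
zero padding), max pooling, ReLU, dense, inverted dropout, flatten and an
identity-skip residual wrapper.  Tensors are NCHW; every layer caches what
its backward pass needs, so forward/backward calls must alternate.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


class Param:
    """A trainable tensor and its gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _as_pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


class Conv2D(Layer):
    """Convolution with stride 1 and symmetric zero padding.

    ``padding`` may be an int, an (h, w) pair, or "same" (odd kernels
    only).  He-normal initialization from the supplied generator.
    Implemented as im2col + one BLAS matmul per pass.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel, padding, rng: np.random.Generator,
                 name: str = "conv") -> None:
        kh, kw = _as_pair(kernel)
        if padding == "same":
            if kh % 2 == 0 or kw % 2 == 0:
                raise ValueError("'same' padding requires odd kernels")
            ph, pw = kh // 2, kw // 2
        else:
            ph, pw = _as_pair(padding)
        self.kh, self.kw, self.ph, self.pw = kh, kw, ph, pw
        scale = np.sqrt(2.0 / (in_ch * kh * kw))
        self.w = Param(rng.normal(0.0, scale, size=(out_ch, in_ch, kh, kw)), f"{name}.w")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self._cols: Optional[np.ndarray] = None
        self._in_shape: Optional[tuple] = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        c, h, w = in_shape
        oh = h + 2 * self.ph - self.kh + 1
        ow = w + 2 * self.pw - self.kw + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"conv kernel {self.kh}x{self.kw} too large for input {h}x{w} "
                f"with padding ({self.ph},{self.pw})"
            )
        return self.w.value.shape[0], oh, ow

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        oc, oh, ow = self.out_shape((c, h, w))
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        # (n, c, oh, ow, kh, kw) view -> (n*oh*ow, c*kh*kw) copy
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw),
                                                        axis=(2, 3))
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, -1)
        self._cols = cols
        self._in_shape = (n, c, h, w, oh, ow)
        wmat = self.w.value.reshape(oc, -1)
        out = cols @ wmat.T + self.b.value
        return out.reshape(n, oh, ow, oc).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w, oh, ow = self._in_shape
        oc = self.w.value.shape[0]
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, oc)
        self.w.grad = (g2.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad = g2.sum(axis=0)
        dcols = g2 @ self.w.value.reshape(oc, -1)  # (n*oh*ow, c*kh*kw)
        dcols = dcols.reshape(n, oh, ow, c, self.kh, self.kw).transpose(0, 3, 1, 2, 4, 5)
        hp, wp = h + 2 * self.ph, w + 2 * self.pw
        dxp = np.zeros((n, c, hp, wp))
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + oh, j : j + ow] += dcols[:, :, :, :, i, j]
        if self.ph or self.pw:
            return dxp[:, :, self.ph : hp - self.ph, self.pw : wp - self.pw]
        return dxp


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are cropped."""

    def __init__(self, pool) -> None:
        self.ph, self.pw = _as_pair(pool)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // self.ph, w // self.pw
        xc = x[:, :, : ho * self.ph, : wo * self.pw]
        xr = xc.reshape(n, c, ho, self.ph, wo, self.pw)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, self.ph * self.pw)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        in_shape, idx = self._cache
        n, c, h, w = in_shape
        ho, wo = idx.shape[2], idx.shape[3]
        dxr = np.zeros((n, c, ho, wo, self.ph * self.pw))
        np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=-1)
        dxr = dxr.reshape(n, c, ho, wo, self.ph, self.pw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(in_shape)
        dx[:, :, : ho * self.ph, : wo * self.pw] = dxr.reshape(
            n, c, ho * self.ph, wo * self.pw
        )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense") -> None:
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)), f"{name}.w")
        self.b = Param(np.zeros(n_out), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Residual(Layer):
    """Identity-skip residual wrapper: ``out = body(x) + x``.

    The body must preserve shape.  With all body weights at zero the block
    is exactly the identity map.
    """

    def __init__(self, body: Sequence[Layer]) -> None:
        self.body = Sequential(body)

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.body.forward(x, train=train)
        if out.shape != x.shape:
            raise ValueError(
                f"residual body changed shape {x.shape} -> {out.shape}; "
                "identity skip impossible"
            )
        return out + x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.body.backward(grad) + grad
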