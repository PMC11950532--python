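"""Small neural-network engine for 3-D volumes, written on NumPy.

The brain-age models used here are deliberately small (desk-scale volumes,
a few tens of thousands of parameters), so the engine implements exactly
what they need and nothing more: strided 3-D convolutions, transposed
convolutions, dense layers, ReLU, mean-squared-error loss, and Adam.
Reverse-mode gradients are exact for both parameters and *inputs* — the
input gradient is what the sensitivity (saliency) maps are built from.

Everything is float64 and single-threaded NumPy, so a fixed seed yields
bit-identical results across runs; there is no separate "deterministic
mode" to enable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "ReLU",
    "Flatten",
    "Reshape",
    "Dense",
    "Conv3d",
    "ConvTranspose3d",
    "Sequential",
    "Adam",
    "mse_loss",
]


class Parameter:
    """A trainable array with an accumulated gradient.

    ``trainable=False`` freezes the parameter: optimizers skip it, but
    gradients still flow *through* the layer to its input (required for
    saliency on transfer-learned models with frozen encoders).
    """

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    """Reshape per-sample features to ``shape`` (batch axis preserved)."""

    def __init__(self, shape: tuple[int, ...]):
        self.shape = tuple(shape)

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def _offsets(k: int) -> list[tuple[int, int, int]]:
    return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]

def _out_dim(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


class Conv3d(Layer):
    """3-D cross-correlation over ``(N, C, D, H, W)`` input.

    Patch extraction and the backward scatter both run as 27 strided-slice
    operations (kernel 3**3), which keeps the whole layer allocation-light
    and exactly reversible.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2, pad: int = 1):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = k, stride, pad
        scale = np.sqrt(2.0 / (c_in * k ** 3))
        # rows ordered channel-major then kernel offset, matching _im2col
        self.W = Parameter(rng.normal(0.0, scale, size=(c_in * k ** 3, c_out)))
        self.b = Parameter(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(_out_dim(n, self.k, self.stride, self.pad) for n in spatial)

    def forward(self, x):
        N, C, D, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        k, s, p = self.k, self.stride, self.pad
        od, oh, ow = self.out_shape((D, H, W))
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = np.empty((N, C, k ** 3, od, oh, ow))
        for j, (a, b, c) in enumerate(_offsets(k)):
            cols[:, :, j] = xp[:, :, a:a + s * od:s, b:b + s * oh:s, c:c + s * ow:s]
        self._cols = cols.reshape(N, C * k ** 3, od * oh * ow)
        self._in_shape = x.shape
        out = np.einsum("nip,io->nop", self._cols, self.W.value, optimize=True)
        out += self.b.value[None, :, None]
        return out.reshape(N, self.c_out, od, oh, ow)

    def backward(self, grad):
        N, F, od, oh, ow = grad.shape
        k, s, p = self.k, self.stride, self.pad
        gm = grad.reshape(N, F, od * oh * ow)
        self.W.grad += np.einsum("nip,nfp->if", self._cols, gm, optimize=True)
        self.b.grad += gm.sum(axis=(0, 2))
        dcols = np.einsum("if,nfp->nip", self.W.value, gm, optimize=True)
        _, C, D, H, W = self._in_shape
        dc = dcols.reshape(N, C, k ** 3, od, oh, ow)
        dxp = np.zeros((N, C, D + 2 * p, H + 2 * p, W + 2 * p))
        for j, (a, b, c) in enumerate(_offsets(k)):
            dxp[:, :, a:a + s * od:s, b:b + s * oh:s, c:c + s * ow:s] += dc[:, :, j]
        return dxp[:, :, p:p + D, p:p + H, p:p + W]


class ConvTranspose3d(Layer):
    """Transposed 3-D convolution; the exact adjoint of :class:`Conv3d`.

    With the defaults (kernel 3, stride 2, pad 1, output padding 1) each
    spatial dimension doubles, mirroring a stride-2 Conv3d block.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2, pad: int = 1, out_pad: int = 1):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad, self.out_pad = k, stride, pad, out_pad
        scale = np.sqrt(2.0 / (c_in * k ** 3))
        # columns ordered output-channel-major then kernel offset
        self.W = Parameter(rng.normal(0.0, scale, size=(c_in, c_out * k ** 3)))
        self.b = Parameter(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        s, k, p, op = self.stride, self.k, self.pad, self.out_pad
        return tuple(s * (n - 1) - 2 * p + k + op for n in spatial)

    def forward(self, x):
        N, C, d, h, w = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        k, s, p = self.k, self.stride, self.pad
        od, oh, ow = self.out_shape((d, h, w))
        self._x = x
        contrib = np.einsum("ncp,cj->njp", x.reshape(N, C, -1), self.W.value,
                            optimize=True)
        contrib = contrib.reshape(N, self.c_out, k ** 3, d, h, w)
        yp = np.zeros((N, self.c_out, od + 2 * p, oh + 2 * p, ow + 2 * p))
        for j, (a, b, c) in enumerate(_offsets(k)):
            yp[:, :, a:a + s * d:s, b:b + s * h:s, c:c + s * w:s] += contrib[:, :, j]
        y = yp[:, :, p:p + od, p:p + oh, p:p + ow]
        return y + self.b.value[None, :, None, None, None]

    def backward(self, grad):
        N, F, od, oh, ow = grad.shape
        k, s, p = self.k, self.stride, self.pad
        _, C, d, h, w = self._x.shape
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = np.empty((N, F, k ** 3, d, h, w))
        for j, (a, b, c) in enumerate(_offsets(k)):
            cols[:, :, j] = gp[:, :, a:a + s * d:s, b:b + s * h:s, c:c + s * w:s]
        colsm = cols.reshape(N, F * k ** 3, d * h * w)
        self.W.grad += np.einsum("ncp,njp->cj", self._x.reshape(N, C, -1),
                                 colsm, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("cj,njp->ncp", self.W.value, colsm, optimize=True)
        return dx.reshape(self._x.shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.params()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters")
        for i, (p, v) in enumerate(zip(params, state)):
            v = np.asarray(v, dtype=np.float64)
            if p.value.shape != v.shape:
                raise ValueError(
                    f"parameter {i}: shape mismatch {p.value.shape} vs {v.shape}")
            p.value = v.copy()
            p.grad = np.zeros_like(p.value)


class Adam:
    """Adam optimizer over the *trainable* parameters only."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr, self.betas, self.eps = lr, betas, eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, 2.0 * diff / diff.size
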