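"""Minimal numpy neural-network layers with manual backpropagation.

Implements exactly what the convolutional variational autoencoder needs:
strided 2D convolution and transposed convolution (im2col/col2im), dense
layers, ReLU/Sigmoid, and Adam.  Layers cache their forward inputs and
expose ``params``/``grads`` lists consumed by the optimizer.  All gradients
are exercised by a finite-difference check in the test suite.
"""

from __future__ import annotations

import numpy as np


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
    return cols.reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`im2col` back to (N, C, H, W)."""
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


class Layer:
    params: list
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, in_c: int, out_c: int, k: int, stride: int, pad: int, rng) -> None:
        super().__init__()
        fan_in = in_c * k * k
        self.w = rng.standard_normal((out_c, in_c, k, k)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_c)
        self.k, self.stride, self.pad = k, stride, pad
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        n, c, h, w = x.shape
        self.cols = im2col(x, self.k, self.stride, self.pad)
        out_c = self.w.shape[0]
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        y = np.einsum("of,nfp->nop", self.w.reshape(out_c, -1), self.cols)
        return y.reshape(n, out_c, ho, wo) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, out_c, ho, wo = dout.shape
        dflat = dout.reshape(n, out_c, ho * wo)
        self.grads[0][...] = np.einsum("nop,nfp->of", dflat, self.cols).reshape(self.w.shape)
        self.grads[1][...] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.w.reshape(out_c, -1), dflat)
        return col2im(dcols, self.x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed convolution: forward is the input-gradient of a Conv2d."""

    def __init__(self, in_c: int, out_c: int, k: int, stride: int, pad: int,
                 output_padding: int, rng) -> None:
        super().__init__()
        if output_padding >= stride:
            raise ValueError("output_padding must be < stride")
        fan_in = in_c * k * k
        self.w = rng.standard_normal((in_c, out_c, k, k)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_c)
        self.k, self.stride, self.pad, self.op = k, stride, pad, output_padding
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        ho = (h - 1) * self.stride - 2 * self.pad + self.k + self.op
        wo = (w - 1) * self.stride - 2 * self.pad + self.k + self.op
        return ho, wo

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        n, in_c, h, w = x.shape
        out_c = self.w.shape[1]
        ho, wo = self._out_hw(h, w)
        xflat = x.reshape(n, in_c, h * w)
        dcols = np.einsum("if,nip->nfp", self.w.reshape(in_c, -1), xflat)
        y = col2im(dcols, (n, out_c, ho, wo), self.k, self.stride, self.pad)
        return y + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, in_c, h, w = self.x.shape
        cols = im2col(dout, self.k, self.stride, self.pad)  # (n, out_c*k*k, h*w)
        xflat = self.x.reshape(n, in_c, h * w)
        self.grads[0][...] = np.einsum("nip,nfp->if", xflat, cols).reshape(self.w.shape)
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dx = np.einsum("if,nfp->nip", self.w.reshape(in_c, -1), cols)
        return dx.reshape(self.x.shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng) -> None:
        super().__init__()
        self.w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self.x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self.y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.y * (1.0 - self.y)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self.shape)


class Reshape(Layer):
    def __init__(self, target: tuple) -> None:
        super().__init__()
        self.target = target

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self.shape)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list:
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
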