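"""Minimal convolutional nets with hand-written backpropagation.

Supports exactly what the desk-scale image translator needs: stride-1/2
convolutions (im2col), ReLU/LeakyReLU, tanh, residual skip, and Adam.
Arrays are ``(N, C, H, W)`` float64; everything is deterministic given
the construction seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "Generator", "PatchDiscriminator", "Adam"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, Ho*, Wo*, k, k)
    win = win[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(gcols: np.ndarray, xshape, k: int, stride: int, pad: int):
    n, c, h, w = xshape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    g = gcols.reshape(n, c, k, k, ho, wo)
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += g[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


class Conv2d:
    def __init__(self, cin: int, cout: int, k: int, stride: int, rng):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, scale, size=(cout, cin * k * k))
        self.b = np.zeros(cout)
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray):
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        y = np.einsum("oc,ncl->nol", self.W, cols) + self.b[None, :, None]
        return y.reshape(x.shape[0], -1, ho, wo), (cols, x.shape, (ho, wo))

    def backward(self, gy: np.ndarray, cache):
        cols, xshape, (ho, wo) = cache
        gyf = gy.reshape(gy.shape[0], gy.shape[1], -1)
        self.gW += np.einsum("nol,ncl->oc", gyf, cols)
        self.gb += gyf.sum(axis=(0, 2))
        gcols = np.einsum("oc,nol->ncl", self.W, gyf)
        return _col2im(gcols, xshape, self.k, self.stride, self.pad)

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def zero_grad(self):
        self.gW[:] = 0.0
        self.gb[:] = 0.0


def _leaky(x, a):
    return np.where(x > 0, x, a * x)


class Generator:
    """conv3x3 -> ReLU -> conv3x3 (+ input skip when channels match) -> tanh.

    Operates on [-1, 1] images; the skip makes the near-identity map,
    the natural starting point for style translation, easy to represent.
    """

    def __init__(self, cin: int, cout: int, nf: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cin, self.cout = cin, cout
        self.c1 = Conv2d(cin, nf, 3, 1, rng)
        self.c2 = Conv2d(nf, cout, 3, 1, rng)
        self.skip = cin == cout

    def forward(self, x: np.ndarray):
        h1, k1 = self.c1.forward(x)
        a1 = np.maximum(h1, 0.0)
        h2, k2 = self.c2.forward(a1)
        pre = h2 + x if self.skip else h2
        y = np.tanh(pre)
        return y, (k1, h1, k2, y)

    def backward(self, gy: np.ndarray, cache):
        k1, h1, k2, y = cache
        gpre = gy * (1.0 - y * y)
        ga1 = self.c2.backward(gpre, k2)
        gh1 = ga1 * (h1 > 0)
        gx = self.c1.backward(gh1, k1)
        if self.skip:
            gx = gx + gpre
        return gx

    def layers(self):
        return [self.c1, self.c2]


class PatchDiscriminator:
    """conv4x4/s2 -> LeakyReLU(0.2) -> conv4x4/s2 -> spatial score map."""

    def __init__(self, cin: int, nf: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.c1 = Conv2d(cin, nf, 4, 2, rng)
        self.c2 = Conv2d(nf, 1, 4, 2, rng)

    def forward(self, x: np.ndarray):
        h1, k1 = self.c1.forward(x)
        a1 = _leaky(h1, 0.2)
        s, k2 = self.c2.forward(a1)
        return s, (k1, h1, k2)

    def backward(self, gs: np.ndarray, cache):
        k1, h1, k2 = cache
        ga1 = self.c2.backward(gs, k2)
        gh1 = ga1 * np.where(h1 > 0, 1.0, 0.2)
        return self.c1.backward(gh1, k1)

    def layers(self):
        return [self.c1, self.c2]


class Adam:
    def __init__(self, layers, lr: float = 2e-4, beta1: float = 0.5, beta2: float = 0.999):
        self.layers = layers
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.t = 0
        self.m = {}
        self.v = {}
        for li, layer in enumerate(layers):
            for name, p, _ in layer.params():
                self.m[(li, name)] = np.zeros_like(p)
                self.v[(li, name)] = np.zeros_like(p)

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, p, g in layer.params():
                m = self.m[(li, name)]
                v = self.v[(li, name)]
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g * g
                mh = m / (1 - self.b1**self.t)
                vh = v / (1 - self.b2**self.t)
                p -= self.lr * mh / (np.sqrt(vh) + 1e-8)

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()
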