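"""Minimal NumPy convolutional network primitives.

Supports the two small networks the package needs: the toy convolutional
autoencoder backend and the Delta-March filter (a truncated convolutional
stack whose intermediate feature maps are differenced).  Layers operate on
``(N, C, H, W)`` float arrays; convolution is im2col-based, and backward
passes are implemented only where training needs them.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ReLU",
    "Sigmoid",
    "AvgPool2",
    "Upsample2",
    "Flatten",
    "Reshape",
    "Dense",
    "Sequential",
    "Adam",
    "random_conv_filter",
]


def _im2col(x, k, pad):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    sw = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, Ho, Wo, k, k)
    ho, wo = sw.shape[2], sw.shape[3]
    cols = sw.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1."""

    def __init__(self, cin, cout, k=3, rng=None, weight=None, bias=None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        if weight is None:
            rng = rng or np.random.default_rng(0)
            scale = np.sqrt(2.0 / (cin * k * k))
            weight = rng.normal(0.0, scale, (cout, cin, k, k))
        if bias is None:
            bias = np.zeros(cout)
        self.w = np.asarray(weight, dtype=np.float64)
        self.b = np.asarray(bias, dtype=np.float64)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._xshape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.pad)
        self._cols = cols
        wmat = self.w.reshape(self.cout, -1)
        y = cols @ wmat.T + self.b
        n = x.shape[0]
        return y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, g):
        n, _, ho, wo = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.grads[0][...] = (gmat.T @ self._cols).reshape(self.w.shape)
        self.grads[1][...] = gmat.sum(axis=0)
        dcols = gmat @ self.w.reshape(self.cout, -1)
        # col2im: scatter-add the k*k shifted views
        _, c, h, w = self._xshape
        p = self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        dcols = dcols.reshape(n, ho, wo, c, self.k, self.k).transpose(0, 3, 4, 5, 1, 2)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + ho, j : j + wo] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class AvgPool2(Layer):
    """2x2 average pooling, stride 2."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, g):
        n, c, h, w = self._shape
        return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, g):
        return g.reshape(g.shape[0], -1)


class Dense(Layer):
    def __init__(self, nin, nout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout))
        self.b = np.zeros(nout)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def __len__(self):
        return len(self.layers)

    def forward(self, x, depth: int | None = None):
        """Run the first ``depth`` layers (all when None)."""
        layers = self.layers if depth is None else self.layers[:depth]
        if depth is not None and depth > len(self.layers):
            raise ValueError(f"depth {depth} exceeds network depth {len(self.layers)}")
        for layer in layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params_and_grads(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)


class Adam:
    def __init__(self, net_or_nets, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        if isinstance(net_or_nets, Sequential):
            net_or_nets = [net_or_nets]
        self.pairs = [pg for net in net_or_nets for pg in net.params_and_grads()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def random_conv_filter(channels=(3, 16, 32), seed: int = 0) -> Sequential:
    """A fixed, seeded convolutional feature stack (forward-only filter).

    Layer sequence per stage: Conv3x3 -> ReLU -> AvgPool2.  With the default
    channels this yields C=32 feature maps at 1/4 resolution at full depth.
    Untrained weights are perfectly usable for Delta-Maps: differencing random
    projections of local image content still localizes where images differ.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF117]))
    layers: list[Layer] = []
    for cin, cout in zip(channels[:-1], channels[1:]):
        layers += [Conv2D(cin, cout, rng=rng), ReLU(), AvgPool2()]
    return Sequential(layers)


def image_to_tensor(image: np.ndarray) -> np.ndarray:
    """(H, W, 3) float image in [0,1] -> (1, 3, H, W) tensor."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    return np.ascontiguousarray(image.transpose(2, 0, 1)[None], dtype=np.float64)


def tensor_to_image(t: np.ndarray) -> np.ndarray:
    return np.clip(t[0].transpose(1, 2, 0), 0.0, 1.0)
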