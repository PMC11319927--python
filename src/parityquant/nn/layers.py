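"""Minimal numpy neural-network layers with explicit backprop.

Only what the multi-quantification model needs: grouped 2D convolution
(im2col), ReLU, linear layers, pooling, and residual blocks (basic and
bottleneck).  Every layer caches what its backward pass requires; ``backward``
consumes the upstream gradient, stores parameter gradients on the layer, and
returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def params_grads(self):
        """Yield (param, grad) array pairs; arrays are updated in place."""
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


def he_init(rng, shape, fan_in, dtype=np.float32):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Conv2d(Layer):
    """k x k convolution, ``same`` padding (pad = k//2), optional stride/groups."""

    def __init__(self, cin, cout, k=3, stride=1, groups=1, rng=None, dtype=np.float32):
        if cin % groups or cout % groups:
            raise ValueError("channels must divide groups")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride, self.groups = cin, cout, k, stride, groups
        cin_g = cin // groups
        self.W = he_init(rng, (cout, cin_g, k, k), cin_g * k * k, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x):
        k, s = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C, k, k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)), xp.shape

    def forward(self, x):
        n = x.shape[0]
        cols, self._xp_shape = self._im2col(x)
        self._x_shape = x.shape
        ho, wo = cols.shape[1], cols.shape[2]
        g, cin_g, cout_g = self.groups, self.cin // self.groups, self.cout // self.groups
        cols = cols.reshape(n * ho * wo, g, cin_g * self.k * self.k)
        self._cols = cols
        wmat = self.W.reshape(g, cout_g, cin_g * self.k * self.k)
        out = np.empty((n * ho * wo, g, cout_g), dtype=self.W.dtype)
        for gi in range(g):
            out[:, gi, :] = cols[:, gi, :] @ wmat[gi].T
        out = out.reshape(n, ho, wo, self.cout) + self.b
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dy):
        n, _, ho, wo = dy.shape
        k, s = self.k, self.stride
        g, cin_g, cout_g = self.groups, self.cin // self.groups, self.cout // self.groups
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, g, cout_g)
        self.db[...] = dyf.reshape(-1, self.cout).sum(axis=0)
        wmat = self.W.reshape(g, cout_g, cin_g * k * k)
        dcols = np.empty_like(self._cols)
        dwm = np.empty_like(wmat)
        for gi in range(g):
            dwm[gi] = dyf[:, gi, :].T @ self._cols[:, gi, :]
            dcols[:, gi, :] = dyf[:, gi, :] @ wmat[gi]
        self.dW[...] = dwm.reshape(self.W.shape)
        # col2im: scatter-add the k*k shifted views
        dcols = dcols.reshape(n, ho, wo, self.cin, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, self.cin, self._xp_shape[2], self._xp_shape[3]), dtype=self.W.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        p = k // 2
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        h, w = self._x_shape[2], self._x_shape[3]
        return dxp[:, :, :h, :w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2(Layer):
    """2x2 average pooling, stride 2 (even spatial dims assumed)."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._spatial = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / self._spatial


class Linear(Layer):
    def __init__(self, nin, nout, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.W = he_init(rng, (nout, nin), nin, dtype)
        self.b = np.zeros(nout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W


class _Sequential(Layer):
    def __init__(self, layers):
        self.layers = layers

    def params_grads(self):
        for l in self.layers:
            yield from l.params_grads()

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class BasicBlock(Layer):
    """conv3x3 -> relu -> conv3x3, residual skip (1x1 projection on shape change)."""

    def __init__(self, cin, cout, stride=1, rng=None, dtype=np.float32):
        self.main = _Sequential(
            [Conv2d(cin, cout, 3, stride, rng=rng, dtype=dtype), ReLU(), Conv2d(cout, cout, 3, 1, rng=rng, dtype=dtype)]
        )
        self.proj = Conv2d(cin, cout, 1, stride, rng=rng, dtype=dtype) if (stride != 1 or cin != cout) else None
        self.out_relu = ReLU()

    def params_grads(self):
        yield from self.main.params_grads()
        if self.proj is not None:
            yield from self.proj.params_grads()

    def forward(self, x):
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.out_relu.forward(self.main.forward(x) + skip)

    def backward(self, dy):
        dy = self.out_relu.backward(dy)
        dx = self.main.backward(dy)
        dskip = self.proj.backward(dy) if self.proj is not None else dy
        return dx + dskip


class Bottleneck(Layer):
    """1x1 reduce -> 3x3 (grouped, strided) -> 1x1 expand, residual skip."""

    def __init__(self, cin, cout, width, stride=1, groups=1, rng=None, dtype=np.float32):
        self.main = _Sequential(
            [
                Conv2d(cin, width, 1, 1, rng=rng, dtype=dtype),
                ReLU(),
                Conv2d(width, width, 3, stride, groups=groups, rng=rng, dtype=dtype),
                ReLU(),
                Conv2d(width, cout, 1, 1, rng=rng, dtype=dtype),
            ]
        )
        self.proj = Conv2d(cin, cout, 1, stride, rng=rng, dtype=dtype) if (stride != 1 or cin != cout) else None
        self.out_relu = ReLU()

    params_grads = BasicBlock.params_grads
    forward = BasicBlock.forward
    backward = BasicBlock.backward
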