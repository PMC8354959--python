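"""Minimal numpy neural-network core: rank-generic conv layers with manual backprop.

Layers operate on arrays shaped ``(batch, channels, *spatial)`` where the spatial
rank is 2 or 3.  Every layer exposes ``forward(x)`` and ``backward(dy)``;
``backward`` accumulates parameter gradients into ``layer.grads`` and returns the
gradient with respect to the layer input.  Convolution uses an im2col forward and
a strided col2im scatter for the input gradient, so no compiled extension is
needed and results are bit-deterministic on a single thread.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_out_extent(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col(xp: np.ndarray, k: int, stride: int, rank: int) -> np.ndarray:
    """(B, C, *padded) -> (B, P, C * k**rank) column matrix.

    P is the number of output positions; kernel offsets vary fastest.
    """
    spatial_axes = tuple(range(2, 2 + rank))
    win = sliding_window_view(xp, (k,) * rank, axis=spatial_axes)
    # win: (B, C, *out_full, *k^rank); subsample output positions by stride
    sub = (slice(None), slice(None)) + (slice(None, None, stride),) * rank
    win = win[sub]
    b, c = win.shape[:2]
    out_sp = win.shape[2 : 2 + rank]
    p = int(np.prod(out_sp))
    # -> (B, *out, C, *kernel) in one copy, columns laid out channel-major
    perm = (0,) + tuple(range(2, 2 + rank)) + (1,) + tuple(range(2 + rank, 2 + 2 * rank))
    win = win.transpose(perm)
    return win.reshape(b, p, c * k**rank), out_sp


def _col2im(dcols: np.ndarray, pad_shape, k: int, stride: int, out_sp) -> np.ndarray:
    """Adjoint of _im2col: scatter-add columns back onto the padded input grid.

    dcols: (B, P, C * k**rank).  Implemented as one strided slice-add per kernel
    offset (overlap for stride < k is handled by accumulation), which keeps the
    whole scatter in vectorised numpy.
    """
    rank = len(out_sp)
    b, p, ck = dcols.shape
    c = ck // k**rank
    dx = np.zeros((b, c) + tuple(pad_shape), dtype=dcols.dtype)
    dcols = dcols.reshape(b, p, c, k**rank).transpose(0, 2, 1, 3)
    dcols = dcols.reshape((b, c) + tuple(out_sp) + (k**rank,))
    for kidx, offs in enumerate(itertools.product(range(k), repeat=rank)):
        sl = (slice(None), slice(None)) + tuple(
            slice(o, o + stride * n, stride) for o, n in zip(offs, out_sp)
        )
        dx[sl] += dcols[..., kidx]
    return dx


def _unpad(x: np.ndarray, pad: int, rank: int) -> np.ndarray:
    if pad == 0:
        return x
    sl = (slice(None), slice(None)) + (slice(pad, -pad),) * rank
    return x[sl]


class Layer:
    """Base class; layers with parameters fill ``params``/``grads`` dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv(Layer):
    """Strided cross-correlation, rank 2 or 3, symmetric zero padding."""

    def __init__(self, rank, c_in, c_out, kernel=4, stride=2, pad=1,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.rank, self.c_in, self.c_out = rank, c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel**rank
        scale = np.sqrt(2.0 / fan_in)
        rng = rng or np.random.default_rng()
        self.params["W"] = (rng.standard_normal((fan_in, c_out)) * scale).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x):
        self._in_sp = x.shape[2:]
        xp = np.pad(x, ((0, 0), (0, 0)) + ((self.pad, self.pad),) * self.rank)
        self._pad_shape = xp.shape[2:]
        cols, out_sp = _im2col(xp, self.k, self.stride, self.rank)
        self._cols, self._out_sp = cols, out_sp
        y = cols @ self.params["W"] + self.params["b"]
        b = x.shape[0]
        return y.transpose(0, 2, 1).reshape((b, self.c_out) + tuple(out_sp))

    def backward(self, dy):
        b = dy.shape[0]
        p = int(np.prod(self._out_sp))
        dyf = np.ascontiguousarray(dy.reshape(b, self.c_out, p).transpose(0, 2, 1))
        k = self._cols.shape[2]
        self.grads["W"] = self._cols.reshape(b * p, k).T @ dyf.reshape(b * p, -1)
        self.grads["b"] = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.params["W"].T
        dxp = _col2im(dcols, self._pad_shape, self.k, self.stride, self._out_sp)
        return _unpad(dxp, self.pad, self.rank)


class ConvTranspose(Layer):
    """Transposed convolution: the adjoint map of ``Conv`` with the same geometry.

    Output extent is ``stride*(n-1) + k - 2*pad``; with k=4, stride=2, pad=1 each
    stage exactly doubles the spatial extent.
    """

    def __init__(self, rank, c_in, c_out, kernel=4, stride=2, pad=1,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.rank, self.c_in, self.c_out = rank, c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in
        scale = np.sqrt(2.0 / (c_in * kernel**rank))
        rng = rng or np.random.default_rng()
        self.params["W"] = (
            rng.standard_normal((c_in, c_out * kernel**rank)) * scale
        ).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def _geometry(self, in_sp):
        out_sp = tuple(self.stride * (n - 1) + self.k - 2 * self.pad for n in in_sp)
        pad_sp = tuple(n + 2 * self.pad for n in out_sp)
        return out_sp, pad_sp

    def forward(self, x):
        b = x.shape[0]
        in_sp = x.shape[2:]
        self._in_sp = in_sp
        out_sp, pad_sp = self._geometry(in_sp)
        p = int(np.prod(in_sp))
        xf = x.reshape(b, self.c_in, p).transpose(0, 2, 1)  # (B,P,Cin)
        self._xf = xf
        cols = xf @ self.params["W"]  # (B,P,Cout*k^r) with kernel offsets fastest
        # reinterpret columns over channel blocks: W rows are laid out (Cout, k^r)
        yp = _col2im(cols, pad_sp, self.k, self.stride, in_sp)
        y = _unpad(yp, self.pad, self.rank)
        return y + self.params["b"].reshape((1, self.c_out) + (1,) * self.rank)

    def backward(self, dy):
        b = dy.shape[0]
        dyp = np.pad(dy, ((0, 0), (0, 0)) + ((self.pad, self.pad),) * self.rank)
        dcols, out_sp = _im2col(dyp, self.k, self.stride, self.rank)
        # out_sp here equals the forward input spatial shape by construction
        p = dcols.shape[1]
        self.grads["W"] = self._xf.reshape(b * p, -1).T @ dcols.reshape(b * p, -1)
        axes = (0,) + tuple(range(2, 2 + self.rank))
        self.grads["b"] = dy.sum(axis=axes)
        dxf = dcols @ self.params["W"].T  # (B,P,Cin)
        return dxf.transpose(0, 2, 1).reshape((b, self.c_in) + tuple(self._in_sp))


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.params["W"] = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dy):
        return np.where(self._neg, self.slope * dy, dy)


class HardClip01(Layer):
    """Bounded-linear output unit: clip(x, 0, 1).

    Unlike a sigmoid it *reaches* 0 and 1 exactly, so voxels whose target is an
    exact background zero stop emitting l1 gradient once satisfied instead of
    pushing the logits ever deeper into saturation.  The gradient is 1 strictly
    inside (0, 1) and 0 outside; clipped-but-unsatisfied voxels are revived
    through the spatially shared convolution weights.
    """

    def forward(self, x):
        self._inside = (x > 0.0) & (x < 1.0)
        return np.clip(x, 0.0, 1.0)

    def backward(self, dy):
        return np.where(self._inside, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Reshape(Layer):
    def __init__(self, out_shape):
        super().__init__()
        self.out_shape = out_shape  # without batch axis

    def forward(self, x):
        self._in_shape = x.shape[1:]
        return x.reshape((x.shape[0],) + tuple(self.out_shape))

    def backward(self, dy):
        return dy.reshape((dy.shape[0],) + tuple(self._in_shape))


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                out.append((f"{i}.{name}", layer.params, layer.grads, name))
        return out


class Adam:
    """Adam optimizer over a list of (key, params-dict, grads-dict, name) entries."""

    def __init__(self, param_entries, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = list(param_entries)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p[n]) for k, p, _, n in self.entries}
        self.v = {k: np.zeros_like(p[n]) for k, p, _, n in self.entries}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for key, params, grads, name in self.entries:
            g = grads[name]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[name].dtype
            )
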