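"""Minimal NumPy neural-network engine (3D conv / pool / dense, Adam).

Just enough machinery for the two-branch 3D CNN: channels-last tensors
``(batch, x, y, slice, channel)``, im2col convolutions backed by BLAS GEMMs,
max-pooling with cached argmax, and manual reverse-mode gradients.  Designed
for small-cohort medical imaging workloads on a single CPU; float32 by
default, float64 available for numeric checks.

Everything is deterministic given the seeded ``numpy.random.Generator`` used
at initialization and the caller-controlled shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Param", "Conv3D", "ReLU", "MaxPool3D", "Flatten", "Dense", "Sigmoid",
           "Sequential", "Adam", "glorot_uniform"]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray | None = None
    name: str = ""

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _im2col(x: np.ndarray, k: tuple[int, int, int]):
    """(B, X, Y, Z, C) -> (B*P, kx*ky*kz*C) patch matrix for valid positions.

    Patch rows are laid out in (kx, ky, kz, channel) flat order — the weight
    matrix uses the same layout.  Built by one contiguous copy per kernel
    offset, which is much faster than gathering an 8D strided view.
    """
    b, X, Y, Z, c = x.shape
    kx, ky, kz = k
    xo, yo, zo = X - kx + 1, Y - ky + 1, Z - kz + 1
    cols = np.empty((b, xo, yo, zo, kx * ky * kz, c), dtype=x.dtype)
    o = 0
    for i in range(kx):
        for j in range(ky):
            for l in range(kz):
                cols[:, :, :, :, o, :] = x[:, i : i + xo, j : j + yo, l : l + zo, :]
                o += 1
    return cols.reshape(b * xo * yo * zo, kx * ky * kz * c), (xo, yo, zo)


class Conv3D:
    """3D convolution (cross-correlation) with 'valid' or 'same' padding."""

    def __init__(self, in_c: int, out_c: int, ksize=(3, 3, 3), padding="valid",
                 rng: np.random.Generator | None = None, dtype=np.float32, name="conv"):
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.in_c, self.out_c, self.ksize, self.padding = in_c, out_c, tuple(ksize), padding
        self.dtype = dtype
        self.name = name
        kvol = int(np.prod(self.ksize))
        fan_in, fan_out = in_c * kvol, out_c * kvol
        rng = rng or np.random.default_rng(0)
        # weight rows follow the im2col (kx, ky, kz, channel) flat order
        self.W = Param(glorot_uniform(rng, (kvol * in_c, out_c), fan_in, fan_out, dtype), name=f"{name}.W")
        self.b = Param(np.zeros(out_c, dtype=dtype), name=f"{name}.b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def kernels(self) -> np.ndarray:
        """Weights as (out_c, in_c, kx, ky, kz)."""
        kx, ky, kz = self.ksize
        return self.W.value.reshape(kx, ky, kz, self.in_c, self.out_c).transpose(4, 3, 0, 1, 2)

    def _pad(self):
        if self.padding == "same":
            return tuple((k - 1) // 2 for k in self.ksize), tuple(k - 1 - (k - 1) // 2 for k in self.ksize)
        return (0, 0, 0), (0, 0, 0)

    def make_cols(self, x_single: np.ndarray):
        """Precompute the im2col patch matrix for one sample (X, Y, Z, C).

        First-layer inputs never change during training, so callers may build
        these once and reuse them every epoch via :meth:`forward_cols`.
        """
        lo, hi = self._pad()
        x = x_single[None].astype(self.dtype, copy=False)
        if any(lo) or any(hi):
            x = np.pad(x, ((0, 0), (lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2]), (0, 0)))
        cols, out_sp = _im2col(x, self.ksize)
        return cols, out_sp

    def forward_cols(self, cols_list, out_sp, train: bool = True) -> np.ndarray:
        """Forward from precomputed per-sample patch matrices."""
        y = np.concatenate([c @ self.W.value for c in cols_list]) + self.b.value
        if train:
            self._cache = (cols_list, None, out_sp)
        return y.reshape(len(cols_list), *out_sp, self.out_c)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        lo, hi = self._pad()
        if any(lo) or any(hi):
            x = np.pad(x, ((0, 0), (lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2]), (0, 0)))
        if self.ksize == (1, 1, 1):
            b, xo, yo, zo, c = x.shape
            cols = x.reshape(-1, c)
            out_sp = (xo, yo, zo)
        else:
            cols, out_sp = _im2col(x, self.ksize)
        y = cols @ self.W.value + self.b.value
        if train:
            self._cache = (cols, x.shape, out_sp)
        return y.reshape(x.shape[0], *out_sp, self.out_c)

    def backward(self, dy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        cols, x_padded_shape, out_sp = self._cache
        b = dy.shape[0]
        dy2 = dy.reshape(b * int(np.prod(out_sp)), self.out_c)
        if isinstance(cols, list):  # cached per-sample patch matrices
            rows = cols[0].shape[0]
            grad = cols[0].T @ dy2[:rows]
            for i in range(1, b):
                grad += cols[i].T @ dy2[i * rows : (i + 1) * rows]
            self.W.grad = grad
        else:
            self.W.grad = cols.T @ dy2
        self.b.grad = dy2.sum(axis=0)
        self._cache = None
        if not need_input_grad:
            return None
        kx, ky, kz = self.ksize
        if self.ksize == (1, 1, 1):
            return (dy2 @ self.W.value.T).reshape(x_padded_shape)
        # col2im: one GEMM, then 27 slice-accumulates (no large gather)
        kvol = kx * ky * kz
        dcols = (dy2 @ self.W.value.T).reshape(b, *out_sp, kvol, self.in_c)
        dxp = np.zeros(x_padded_shape, dtype=dy.dtype)
        xo, yo, zo = out_sp
        o = 0
        for i in range(kx):
            for j in range(ky):
                for l in range(kz):
                    dxp[:, i : i + xo, j : j + yo, l : l + zo, :] += dcols[:, :, :, :, o, :]
                    o += 1
        lo, hi = self._pad()
        if any(lo) or any(hi):
            sl = tuple(slice(l_, s - h) for l_, h, s in zip(lo, hi, dxp.shape[1:4]))
            dxp = dxp[(slice(None), *sl, slice(None))]
        return dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=True):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy, need_input_grad=True):
        m, self._mask = self._mask, None
        return dy * m


class MaxPool3D:
    """Non-overlapping max pooling; trailing remainders are dropped (floor)."""

    def __init__(self, pool=(2, 2, 2)):
        self.pool = tuple(pool)
        self._cache = None

    def params(self):
        return []

    def forward(self, x, train=True):
        px, py, pz = self.pool
        b, X, Y, Z, c = x.shape
        xo, yo, zo = X // px, Y // py, Z // pz
        xc = x[:, : xo * px, : yo * py, : zo * pz, :]
        win = xc.reshape(b, xo, px, yo, py, zo, pz, c).transpose(0, 1, 3, 5, 7, 2, 4, 6)
        win = np.ascontiguousarray(win).reshape(b, xo, yo, zo, c, px * py * pz)
        idx = np.argmax(win, axis=-1)
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy, need_input_grad=True):
        idx, x_shape = self._cache
        self._cache = None
        px, py, pz = self.pool
        b, X, Y, Z, c = x_shape
        xo, yo, zo = X // px, Y // py, Z // pz
        dwin = np.zeros((b, xo, yo, zo, c, px * py * pz), dtype=dy.dtype)
        np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
        dxc = dwin.reshape(b, xo, yo, zo, c, px, py, pz).transpose(0, 1, 5, 2, 6, 3, 7, 4)
        dxc = dxc.reshape(b, xo * px, yo * py, zo * pz, c)
        if (xo * px, yo * py, zo * pz) == (X, Y, Z):
            return dxc
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dx[:, : xo * px, : yo * py, : zo * pz, :] = dxc
        return dx


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy, need_input_grad=True):
        return dy.reshape(self._shape)


class Dense:
    def __init__(self, in_f: int, out_f: int, rng=None, dtype=np.float32, name="dense"):
        rng = rng or np.random.default_rng(0)
        self.W = Param(glorot_uniform(rng, (in_f, out_f), in_f, out_f, dtype), name=f"{name}.W")
        self.b = Param(np.zeros(out_f, dtype=dtype), name=f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy, need_input_grad=True):
        x, self._x = self._x, None
        self.W.grad = x.T @ dy
        self.b.grad = dy.sum(axis=0)
        return dy @ self.W.value.T if need_input_grad else None


class Sigmoid:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x, train=True):
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, dy, need_input_grad=True):
        y, self._y = self._y, None
        return dy * y * (1.0 - y)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy, need_input_grad=False):
        for i, layer in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            dy = layer.backward(dy, need_input_grad=(not last) or need_input_grad)
        return dy


class Adam:
    """Adam with the standard bias correction; state is per-parameter."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                continue
            g = g.astype(p.value.dtype, copy=False)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None
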