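"""Minimal CPU neural-network engine used by :mod:`myoseg.model`.

Implements exactly the layers the segmentation network needs — strided
convolution, strided transposed convolution, instance/batch normalisation,
ReLU/LeakyReLU — with hand-written backward passes and an Adam optimiser.
Convolutions are lowered to matrix multiplies via im2col so the heavy
lifting happens in BLAS; the scatter (col2im) path reuses cached index
maps per geometry.

Everything is deterministic given the ``numpy.random.Generator`` used for
initialisation. Arrays keep the caller's dtype (float32 for training,
float64 for gradient checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Sequential",
    "ResidualBlock",
    "Adam",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# im2col / col2im with cached scatter indices
# ---------------------------------------------------------------------------

class _ConvGeometry:
    """Index bookkeeping for one (C, H, W, k, stride, pad) configuration."""

    _cache: dict[tuple, "_ConvGeometry"] = {}

    def __init__(self, C: int, H: int, W: int, k: int, stride: int, pad: int):
        self.C, self.H, self.W = C, H, W
        self.k, self.stride, self.pad = k, stride, pad
        self.Hp, self.Wp = H + 2 * pad, W + 2 * pad
        self.Ho = (self.Hp - k) // stride + 1
        self.Wo = (self.Wp - k) // stride + 1
        self._scatter_idx: np.ndarray | None = None

    @classmethod
    def get(cls, C, H, W, k, stride, pad) -> "_ConvGeometry":
        key = (C, H, W, k, stride, pad)
        geo = cls._cache.get(key)
        if geo is None:
            geo = cls._cache[key] = cls(C, H, W, k, stride, pad)
        return geo

    def im2col(self, x: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> (N, Ho*Wo, C*k*k)."""
        n = x.shape[0]
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # (N,C,Ho,Wo,k,k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, self.Ho * self.Wo, self.C * self.k * self.k)
        return np.ascontiguousarray(cols)

    def _indices(self) -> np.ndarray:
        if self._scatter_idx is None:
            ho = np.arange(self.Ho) * self.stride
            wo = np.arange(self.Wo) * self.stride
            c = np.arange(self.C)
            i = np.arange(self.k)
            j = np.arange(self.k)
            # flat index into padded (C, Hp, Wp) for each col entry, laid out
            # to match im2col's (Ho*Wo, C*k*k) ordering
            rr = ho[:, None, None, None, None] + i[None, None, None, :, None]
            cc = wo[None, :, None, None, None] + j[None, None, None, None, :]
            ch = c[None, None, :, None, None]
            flat = (ch * self.Hp + rr) * self.Wp + cc
            self._scatter_idx = np.broadcast_to(
                flat, (self.Ho, self.Wo, self.C, self.k, self.k)
            ).reshape(-1)
        return self._scatter_idx

    def col2im(self, gcols: np.ndarray, dtype=None) -> np.ndarray:
        """(N, Ho*Wo, C*k*k) -> (N, C, H, W), summing overlaps."""
        n = gcols.shape[0]
        idx = self._indices()
        size = self.C * self.Hp * self.Wp
        out = np.empty((n, size), dtype=np.float64)
        for b in range(n):
            out[b] = np.bincount(idx, weights=gcols[b].ravel(), minlength=size)
        out = out.reshape(n, self.C, self.Hp, self.Wp)
        if self.pad:
            out = out[:, :, self.pad : self.pad + self.H, self.pad : self.pad + self.W]
        return out.astype(dtype or gcols.dtype, copy=False)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: named parameters + matching gradient slots."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv2d(Layer):
    def __init__(self, cin, cout, k, stride=1, pad=None, rng=None, bias=True):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))  # Kaiming for ReLU nets
        self.params["W"] = (rng.standard_normal((cin * k * k, cout)) * std).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grad()

    # largest transient im2col buffer allowed in eval mode (elements)
    _EVAL_CHUNK_ELEMS = 2 ** 25

    def forward(self, x, training):
        n, c, h, w = x.shape
        geo = _ConvGeometry.get(c, h, w, self.k, self.stride, self.pad)
        W = self.params["W"].astype(x.dtype, copy=False)
        b = self.params.get("b")
        if training:
            cols = geo.im2col(x)
            self._cache = (cols, geo, x.dtype)
            y = cols.reshape(-1, cols.shape[-1]) @ W
            if b is not None:
                y += b.astype(x.dtype, copy=False)
            return y.reshape(n, geo.Ho * geo.Wo, self.cout).transpose(0, 2, 1).reshape(
                n, self.cout, geo.Ho, geo.Wo
            )
        # eval: no cache; chunk output rows so im2col stays bounded
        self._cache = None
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))[:, :, :: self.stride, :: self.stride]
        y = np.empty((n, self.cout, geo.Ho, geo.Wo), x.dtype)
        ckk = c * self.k * self.k
        chunk = max(1, self._EVAL_CHUNK_ELEMS // max(1, n * geo.Wo * ckk))
        for r0 in range(0, geo.Ho, chunk):
            r1 = min(geo.Ho, r0 + chunk)
            cols = np.ascontiguousarray(
                win[:, :, r0:r1].transpose(0, 2, 3, 1, 4, 5)
            ).reshape(-1, ckk)
            yy = cols @ W
            if b is not None:
                yy += b.astype(x.dtype, copy=False)
            y[:, :, r0:r1] = (
                yy.reshape(n, (r1 - r0) * geo.Wo, self.cout)
                .transpose(0, 2, 1)
                .reshape(n, self.cout, r1 - r0, geo.Wo)
            )
        return y

    def backward(self, g):
        cols, geo, dt = self._cache
        n = g.shape[0]
        gf = g.reshape(n, self.cout, -1).transpose(0, 2, 1).reshape(-1, self.cout)
        cf = cols.reshape(-1, cols.shape[-1])
        self.grads["W"] += (cf.T @ gf).astype(self.params["W"].dtype, copy=False)
        if "b" in self.params:
            self.grads["b"] += gf.sum(axis=0).astype(self.params["b"].dtype, copy=False)
        gcols = (gf @ self.params["W"].T.astype(dt, copy=False)).reshape(n, cols.shape[1], -1)
        return geo.col2im(gcols, dtype=dt)


class ConvTranspose2d(Layer):
    """3x3 stride-2 transposed conv that exactly doubles spatial size.

    Implemented as the adjoint of a stride-2 convolution: forward scatters
    through col2im, backward gathers through im2col.
    """

    def __init__(self, cin, cout, k=3, stride=2, rng=None):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.params["W"] = (rng.standard_normal((cout * k * k, cin)) * std).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grad()

    def _geo(self, h, w):
        # geometry of the *adjoint* convolution: (cout, s*h, s*w) -> (cin, h, w)
        return _ConvGeometry.get(self.cout, self.stride * h, self.stride * w, self.k, self.stride, self.pad)

    def forward(self, x, training):
        n, c, h, w = x.shape
        geo = self._geo(h, w)
        xr = x.reshape(n, c, -1).transpose(0, 2, 1).reshape(-1, c)  # (N*HW, cin)
        W = self.params["W"].astype(x.dtype, copy=False)
        gcols = (xr @ W.T).reshape(n, h * w, -1)
        y = geo.col2im(gcols, dtype=x.dtype)
        y += self.params["b"].astype(x.dtype, copy=False)[None, :, None, None]
        self._cache = (xr, geo, (n, c, h, w), x.dtype) if training else None
        return y

    def backward(self, g):
        xr, geo, (n, c, h, w), dt = self._cache
        cols = geo.im2col(g)  # (N, HW, cout*k*k)
        cf = cols.reshape(-1, cols.shape[-1])
        self.grads["W"] += (cf.T @ xr).astype(self.params["W"].dtype, copy=False)
        self.grads["b"] += g.sum(axis=(0, 2, 3)).astype(self.params["b"].dtype, copy=False)
        gx = (cf @ self.params["W"].astype(dt, copy=False)).reshape(n, h * w, c)
        return gx.transpose(0, 2, 1).reshape(n, c, h, w)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation over (H, W); non-affine."""

    def __init__(self, eps=1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x, training):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xn = (x - mu) * self._inv
        return self._xn

    def backward(self, g):
        xn = self._xn
        gm = g.mean(axis=(2, 3), keepdims=True)
        gxm = (g * xn).mean(axis=(2, 3), keepdims=True)
        return self._inv * (g - gm - xn * gxm)


class BatchNorm2d(Layer):
    """Affine batch norm over (N, H, W) with running statistics."""

    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.zero_grad()

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)[None, :, None, None]
        self._xn = (x - mu.astype(x.dtype)[None, :, None, None]) * self._inv
        self._training = training
        g = self.params["gamma"].astype(x.dtype)[None, :, None, None]
        b = self.params["beta"].astype(x.dtype)[None, :, None, None]
        return self._xn * g + b

    def backward(self, g):
        xn = self._xn
        self.grads["gamma"] += (g * xn).sum(axis=(0, 2, 3)).astype(
            self.params["gamma"].dtype, copy=False
        )
        self.grads["beta"] += g.sum(axis=(0, 2, 3)).astype(self.params["beta"].dtype, copy=False)
        gxn = g * self.params["gamma"].astype(g.dtype)[None, :, None, None]
        if not self._training:
            return gxn * self._inv
        m = gxn.mean(axis=(0, 2, 3), keepdims=True)
        mx = (gxn * xn).mean(axis=(0, 2, 3), keepdims=True)
        return self._inv * (gxn - m - xn * mx)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training):
        for lay in self.layers:
            x = lay.forward(x, training)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def iter_layers(self):
        for lay in self.layers:
            if isinstance(lay, (Sequential, ResidualBlock)):
                yield from lay.iter_layers()
            else:
                yield lay


class ResidualBlock(Layer):
    """conv3-BN-ReLU-conv3-BN plus the identity skip connection."""

    def __init__(self, c, rng):
        super().__init__()
        self.body = Sequential(
            Conv2d(c, c, 3, rng=rng),
            BatchNorm2d(c),
            ReLU(),
            Conv2d(c, c, 3, rng=rng),
            BatchNorm2d(c),
        )

    def forward(self, x, training):
        return x + self.body.forward(x, training)

    def backward(self, g):
        return g + self.body.backward(g)

    def iter_layers(self):
        yield from self.body.iter_layers()


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.5, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()
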