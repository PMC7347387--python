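"""Minimal feed-forward network core used by the CNN encoding model.

Implements exactly the layer set the encoding model needs — bias-free 2-D
convolutions with 'same' zero padding and stride 1, bias-free hidden dense
layers, a biased linear output, ReLU, inverted dropout and flatten — with
hand-written backward passes and an Adam optimizer.  Keeping the layers
bias-free is what makes the network's locally-linear (Jacobian) reading
exact: within one ReLU activation region the map from input to output is a
pure product of (masked) weight matrices plus the single output bias.

Training runs in float32 via im2col + GEMM; inference can run in float64
(``dtype`` argument) where the linearization identities are verified to
tight tolerances.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import blas as _blas


def _gemm_acc(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> None:
    """c += a @ b without temporaries, for C-contiguous float32/64 arrays.

    Uses the identity that a C-ordered (m, n) array is an F-ordered (n, m)
    array, so BLAS gemm with beta=1 can accumulate in place.
    """
    gemm = _blas.sgemm if a.dtype == np.float32 else _blas.dgemm
    gemm(1.0, b.T, a.T, beta=1.0, c=c.T, overwrite_c=True)

__all__ = [
    "Conv2d",
    "Dense",
    "ReLU",
    "Dropout",
    "Flatten",
    "Sequential",
    "Adam",
    "combined_loss",
    "combined_loss_grad",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He initialization for rectifier networks: N(0, sqrt(2 / fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    weights: np.ndarray | None = None
    bias: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError

    def params_and_grads(self):
        out = []
        if self.weights is not None:
            out.append((self.weights, self.gw, True))
        if self.bias is not None:
            out.append((self.bias, self.gb, False))
        return out


def _pad_same(x: np.ndarray, p: int) -> np.ndarray:
    b, h, w, c = x.shape
    xp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
    xp[:, p:p + h, p:p + w, :] = x
    return xp


class Conv2d(Layer):
    """Bias-free 2-D convolution, stride 1, zero 'same' padding, NHWC.

    Weights are stored flattened as (kh*kw*cin, cout) with (di, dj, c) row
    order.  Forward and both backward products are computed as one GEMM per
    kernel offset on shifted views of the padded tensor, which avoids
    materializing full im2col patch matrices.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, skip_input_grad: bool = False):
        if kernel_size % 2 != 1:
            raise ValueError("only odd kernel sizes supported")
        self.kh = self.kw = kernel_size
        self.cin, self.cout = in_channels, out_channels
        fan_in = self.kh * self.kw * in_channels
        self.weights = he_normal(rng, (fan_in, out_channels), fan_in)
        self.gw = np.zeros_like(self.weights)
        self.skip_input_grad = skip_input_grad
        self._xp = None
        self._xshape = None

    @property
    def kernels(self) -> np.ndarray:
        """Kernels as (kh, kw, cin, cout)."""
        return self.weights.reshape(self.kh, self.kw, self.cin, self.cout)

    def _offset_blocks(self, xp, h, w, c):
        """Shifted (B*H*W, C) blocks of the padded tensor, one per offset.

        Each block is a contiguous copy; the per-offset GEMMs accumulate
        into one output with BLAS beta=1.
        """
        for di in range(self.kh):
            for dj in range(self.kw):
                yield xp[:, di:di + h, dj:dj + w, :].reshape(-1, c)

    def forward(self, x, train=False, rng=None):
        b, h, w, c = x.shape
        self._xshape = x.shape
        wmat = self.weights if x.dtype == np.float32 else self.weights.astype(x.dtype)
        if self.kh == 1:
            x2d = x.reshape(b * h * w, c)
            if train:
                self._xp = x2d
            return (x2d @ wmat).reshape(b, h, w, self.cout)
        xp = _pad_same(x, self.kh // 2)
        out = np.zeros((b * h * w, self.cout), dtype=x.dtype)
        blocks = []
        for k, blk in enumerate(self._offset_blocks(xp, h, w, c)):
            if train:
                blocks.append(blk)
            _gemm_acc(blk, np.ascontiguousarray(wmat[k * c:(k + 1) * c]), out)
        if train:
            self._xp = blocks
        return out.reshape(b, h, w, self.cout)

    def backward(self, g):
        b, h, w, c = self._xshape
        gm = g.reshape(b * h * w, self.cout)
        if self.kh == 1:
            self.gw = self._xp.T @ gm
            self._xp = None
            if self.skip_input_grad:
                return None
            return (gm @ self.weights.T.astype(g.dtype, copy=False)).reshape(b, h, w, c)
        for k, blk in enumerate(self._xp):
            self.gw[k * c:(k + 1) * c] = blk.T @ gm
        self._xp = None
        if self.skip_input_grad:
            return None
        # transposed convolution: conv of g with spatially flipped,
        # channel-transposed kernels
        gp = _pad_same(g.reshape(b, h, w, self.cout), self.kh // 2)
        gx = np.zeros((b * h * w, c), dtype=g.dtype)
        wdtype = self.weights if g.dtype == np.float32 else self.weights.astype(g.dtype)
        for k, gblk in enumerate(self._offset_blocks(gp, h, w, self.cout)):
            di, dj = divmod(k, self.kw)
            kf = (self.kh - 1 - di) * self.kw + (self.kw - 1 - dj)
            _gemm_acc(gblk, np.ascontiguousarray(wdtype[kf * c:(kf + 1) * c].T), gx)
        return gx.reshape(b, h, w, c)


class Dense(Layer):
    """Fully connected layer; hidden layers use ``use_bias=False``."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 use_bias: bool = False):
        self.weights = he_normal(rng, (in_features, out_features), in_features)
        self.gw = np.zeros_like(self.weights)
        self.bias = np.zeros(out_features, dtype=np.float32) if use_bias else None
        self.gb = np.zeros_like(self.bias) if use_bias else None
        self._x = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._x = x
        wmat = self.weights if x.dtype == np.float32 else self.weights.astype(x.dtype)
        out = x @ wmat
        if self.bias is not None:
            out = out + (self.bias if x.dtype == np.float32 else self.bias.astype(x.dtype))
        return out

    def backward(self, g):
        self.gw = self._x.T @ g
        if self.bias is not None:
            self.gb = g.sum(axis=0)
        self._x = None
        return g @ self.weights.T


class ReLU(Layer):
    def __init__(self):
        self._out = None

    def forward(self, x, train=False, rng=None):
        out = np.maximum(x, 0)
        self._out = out
        return out

    @property
    def last_active(self):
        """Strict active mask of the most recent forward pass."""
        return self._out > 0

    def backward(self, g):
        g = g * (self._out > 0)
        self._out = None
        return g


class Dropout(Layer):
    """Inverted dropout; identity when not training."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0 or rng is None:
            return x
        u = rng.random(x.shape, dtype=np.float32 if x.dtype == np.float32 else np.float64)
        keep = (u >= self.p).astype(x.dtype) / (1.0 - self.p)
        self._mask = keep
        return x * keep

    def backward(self, g):
        if self._mask is None:
            return g
        g = g * self._mask
        self._mask = None
        return g


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p, _, _ in layer.params_and_grads()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = [p for layer in self.layers for p, _, _ in layer.params_and_grads()]
        if len(params) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            p[...] = w


class Adam:
    """Adam optimizer with optional decoupled-from-nothing L2 (added to grads)."""

    def __init__(self, params_and_grads_fn, lr=1e-4, beta1=0.9, beta2=0.999,
                 eps=1e-8, l2=0.0):
        self.fn = params_and_grads_fn
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.t = 0
        self.m = None
        self.v = None

    def step(self):
        triples = self.fn()
        if self.m is None:
            self.m = [np.zeros_like(p) for p, _, _ in triples]
            self.v = [np.zeros_like(p) for p, _, _ in triples]
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (p, g, is_weight), m, v in zip(triples, self.m, self.v):
            if self.l2 and is_weight:
                g = g + (2.0 * self.l2) * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _center(a):
    return a - a.mean()


def combined_loss(y: np.ndarray, yhat: np.ndarray,
                  mse_weight: float = 1.0, corr_weight: float = 1.0) -> float:
    """Training loss: weighted MSE minus weighted Pearson correlation.

    When either series has zero variance the correlation term is defined
    as 0 so the loss stays finite.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.size != yhat.size or y.size < 2:
        raise ValueError("series must have equal length >= 2")
    mse = np.mean((y - yhat) ** 2)
    yc, hc = _center(y), _center(yhat)
    denom = np.linalg.norm(yc) * np.linalg.norm(hc)
    corr = float(yc @ hc / denom) if denom > 0 else 0.0
    return float(mse_weight * mse - corr_weight * corr)


def combined_loss_grad(y: np.ndarray, yhat: np.ndarray,
                       mse_weight: float = 1.0, corr_weight: float = 1.0):
    """(loss, dloss/dyhat) for the combined loss, both in float64."""
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    n = y.size
    diff = yhat - y
    mse = np.mean(diff ** 2)
    g = mse_weight * 2.0 * diff / n
    yc, hc = _center(y), _center(yhat)
    a = np.linalg.norm(yc)
    b = np.linalg.norm(hc)
    if a > 0 and b > 0:
        corr = float(yc @ hc / (a * b))
        gcorr = yc / (a * b) - corr * hc / (b * b)
        g = g - corr_weight * gcorr
    else:
        corr = 0.0
    return float(mse_weight * mse - corr_weight * corr), g
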