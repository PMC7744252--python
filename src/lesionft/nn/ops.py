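"""Low-level neural-network primitives on numpy arrays.

Everything here operates on channels-last float32 tensors of shape
(batch, height, width, channels).  Convolutions are expressed as im2col
gathers (numba) followed by BLAS GEMMs; gradients are hand-derived.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

F32 = np.float32


# ---------------------------------------------------------------------------
# im2col / col2im for 3x3 dilated convolutions, stride 1, zero "same" padding
# ---------------------------------------------------------------------------

@njit(cache=True)
def _im2col_3x3(xp, d, H, W, col):  # pragma: no cover - jitted
    B = xp.shape[0]
    C = xp.shape[3]
    for b in range(B):
        for h in range(H):
            for w in range(W):
                row = (b * H + h) * W + w
                k = 0
                for i in range(3):
                    for j in range(3):
                        src = xp[b, h + i * d, w + j * d]
                        for c in range(C):
                            col[row, k] = src[c]
                            k += 1


@njit(cache=True)
def _bn_relu_train_fwd(y, gamma, beta, xhat, mask, mean, var):  # pragma: no cover
    """In-place BN (batch stats) + ReLU on y of shape (N, C).

    Fills xhat (normalized activations), mask (post-ReLU positivity),
    and the per-channel batch mean/var.
    """
    N, C = y.shape
    s1 = np.zeros(C, np.float64)
    s2 = np.zeros(C, np.float64)
    for n in range(N):
        for c in range(C):
            v = y[n, c]
            s1[c] += v
            s2[c] += v * v
    inv = np.empty(C, np.float32)
    for c in range(C):
        m = s1[c] / N
        mean[c] = m
        var[c] = s2[c] / N - m * m
        inv[c] = 1.0 / np.sqrt(var[c] + 1e-5)
    zero = F32(0.0)
    one = F32(1.0)
    for n in range(N):
        for c in range(C):
            xh = (y[n, c] - mean[c]) * inv[c]
            xhat[n, c] = xh
            out = gamma[c] * xh + beta[c]
            keep = one if out > zero else zero
            y[n, c] = out * keep
            mask[n, c] = keep


@njit(cache=True)
def _bn_relu_train_bwd(dy, xhat, mask, gamma, inv_std):  # pragma: no cover
    """Backward of BN+ReLU; writes dx into xhat (reusing its storage).

    Returns per-channel (dgamma, dbeta).  dy may be any-strided 4D
    (B, H, W, C); xhat/mask are (N, C) with N = B*H*W.
    """
    B, H, W, C = dy.shape
    N = B * H * W
    dgamma = np.zeros(C, np.float32)
    dbeta = np.zeros(C, np.float32)
    for b in range(B):
        for h in range(H):
            for w in range(W):
                n = (b * H + h) * W + w
                for c in range(C):
                    d = dy[b, h, w, c] * mask[n, c]
                    dgamma[c] += d * xhat[n, c]
                    dbeta[c] += d
    mg = dgamma / N
    mb = dbeta / N
    scale = gamma * inv_std
    for b in range(B):
        for h in range(H):
            for w in range(W):
                n = (b * H + h) * W + w
                for c in range(C):
                    d = dy[b, h, w, c] * mask[n, c]
                    xhat[n, c] = (d - mb[c] - xhat[n, c] * mg[c]) * scale[c]
    return dgamma, dbeta


@njit(cache=True)
def _affine_relu_fwd(y, a, b, mask):  # pragma: no cover - jitted
    """In-place y = max(a * y + b, 0) on (N, C), recording positivity."""
    N, C = y.shape
    zero = F32(0.0)
    one = F32(1.0)
    for n in range(N):
        for c in range(C):
            v = a[c] * y[n, c] + b[c]
            keep = one if v > zero else zero
            y[n, c] = v * keep
            mask[n, c] = keep


@njit(cache=True)
def _bias_relu(y, bias):  # pragma: no cover - jitted
    """In-place y = max(y + bias, 0) on (N, C)."""
    N, C = y.shape
    zero = F32(0.0)
    for n in range(N):
        for c in range(C):
            v = y[n, c] + bias[c]
            y[n, c] = v if v > zero else zero


@njit(cache=True)
def _dropout_fwd(x, rand, keep, mask):  # pragma: no cover - jitted
    """In-place inverted dropout on flat x given pregenerated uniforms."""
    inv = F32(1.0) / keep
    for i in range(x.size):
        if rand[i] < keep:
            mask[i] = inv
            x[i] *= inv
        else:
            mask[i] = 0.0
            x[i] = 0.0


@njit(cache=True)
def _col2im_3x3(dcol, d, H, W, dxp):  # pragma: no cover - jitted
    B = dxp.shape[0]
    C = dxp.shape[3]
    for b in range(B):
        for h in range(H):
            for w in range(W):
                row = (b * H + h) * W + w
                k = 0
                for i in range(3):
                    for j in range(3):
                        dst = dxp[b, h + i * d, w + j * d]
                        for c in range(C):
                            dst[c] += dcol[row, k]
                            k += 1


def he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """He (Kaiming) uniform initialization: U(-sqrt(6/fan_in), +sqrt(6/fan_in))."""
    limit = math.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class _BufferPool:
    """Reusable scratch arrays keyed by name; reallocated on shape change.

    Convolution workspaces (im2col matrices, gradient planes) are large and
    requested every iteration with identical shapes; reusing them avoids
    page-faulting freshly allocated memory in the hot loop.
    """

    def __init__(self):
        self._bufs: dict = {}

    def get(self, name: str, shape: tuple, dtype=F32) -> np.ndarray:
        key = (name, shape, np.dtype(dtype).str)
        buf = self._bufs.get(key)
        if buf is None:
            buf = np.empty(shape, dtype)
            self._bufs[key] = buf
        return buf


# workspaces that are consumed immediately within one layer call (the padded
# input, the gradient col matrix and the gradient planes) are shared across
# all layers: this keeps the training working set small enough to stay
# cache-friendly
_SHARED = _BufferPool()


class Conv3x3:
    """3x3 convolution with dilation, stride 1, zero same-padding, no bias.

    Weights are stored flattened as (9 * c_in, c_out) so the forward pass is a
    single GEMM on the im2col matrix.
    """

    def __init__(self, c_in: int, c_out: int, dilation: int,
                 rng: np.random.Generator):
        self.c_in = c_in
        self.c_out = c_out
        self.dilation = int(dilation)
        self.W = he_uniform(rng, fan_in=9 * c_in, shape=(9 * c_in, c_out))
        self.dW = np.zeros_like(self.W)
        self._pool = _BufferPool()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        B, H, W, C = x.shape
        d = self.dilation
        xp = self._pool.get("xp", (B, H + 2 * d, W + 2 * d, C))
        xp.fill(0.0)
        xp[:, d:-d, d:-d, :] = x
        col = self._pool.get("col", (B * H * W, 9 * C))
        _im2col_3x3(xp, d, H, W, col)
        y = self._pool.get("y", (B * H * W, self.c_out))
        np.matmul(col, self.W, out=y)
        self._shape = (B, H, W, C)
        return y.reshape(B, H, W, self.c_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        B, H, W, C = self._shape
        d = self.dilation
        do2 = dy.reshape(-1, self.c_out)
        col = self._pool.get("col", (B * H * W, 9 * C))
        self.dW = col.T @ do2
        if not need_dx:
            return None
        dcol = self._pool.get("dcol", (B * H * W, 9 * C))
        np.matmul(do2, self.W.T, out=dcol)
        dxp = self._pool.get("dxp", (B, H + 2 * d, W + 2 * d, C))
        dxp.fill(0.0)
        _col2im_3x3(dcol, d, H, W, dxp)
        return dxp[:, d:-d, d:-d, :]

    def params(self):
        return [self.W]

    def grads(self):
        return [self.dW]


class ConvBNReLU:
    """Fused 3x3 dilated convolution + batch norm + ReLU (one pathway layer).

    Training mode normalizes with batch statistics (updating the running
    mean/variance) and caches what the hand-derived backward pass needs.
    Eval mode folds the frozen BN affine into the convolution weights, so the
    whole layer is a single GEMM plus a bias-ReLU sweep -- the fast path used
    at inference and during fine-tuning, where the body is frozen.
    """

    momentum = 0.1
    eps = 1e-5

    def __init__(self, c_in: int, c_out: int, dilation: int,
                 rng: np.random.Generator):
        self.c_in = c_in
        self.c_out = c_out
        self.dilation = int(dilation)
        self.W = he_uniform(rng, fan_in=9 * c_in, shape=(9 * c_in, c_out))
        self.gamma = np.ones(c_out, F32)
        self.beta = np.zeros(c_out, F32)
        self.running_mean = np.zeros(c_out, F32)
        self.running_var = np.ones(c_out, F32)
        self.dW = np.zeros_like(self.W)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._pool = _BufferPool()
        self._shape: tuple | None = None
        self._inv_std: np.ndarray | None = None

    def _conv(self, x: np.ndarray, W: np.ndarray, col_pool) -> np.ndarray:
        B, H, Wd, C = x.shape
        d = self.dilation
        xp = _SHARED.get("xp", (B, H + 2 * d, Wd + 2 * d, C))
        xp.fill(0.0)
        xp[:, d:-d, d:-d, :] = x
        col = col_pool.get("col", (B * H * Wd, 9 * C))
        _im2col_3x3(xp, d, H, Wd, col)
        y = self._pool.get("y", (B * H * Wd, self.c_out))
        np.matmul(col, W, out=y)
        self._shape = (B, H, Wd, C)
        return y

    def forward_train(self, x: np.ndarray) -> np.ndarray:
        y = self._conv(x, self.W, self._pool)
        B, H, Wd, C = self._shape
        xhat = self._pool.get("xhat", y.shape)
        mask = self._pool.get("mask", y.shape)
        mean = np.empty(self.c_out, F32)
        var = np.empty(self.c_out, F32)
        _bn_relu_train_fwd(y, self.gamma, self.beta, xhat, mask, mean, var)
        m = F32(self.momentum)
        self.running_mean *= 1 - m
        self.running_mean += m * mean
        self.running_var *= 1 - m
        self.running_var += m * var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        return y.reshape(B, H, Wd, self.c_out)

    def forward_eval(self, x: np.ndarray) -> np.ndarray:
        a = (self.gamma / np.sqrt(self.running_var + self.eps)).astype(F32)
        bias = (self.beta - a * self.running_mean).astype(F32)
        y = self._conv(x, self.W * a, _SHARED)
        _bias_relu(y, bias)
        B, H, Wd, C = self._shape
        return y.reshape(B, H, Wd, self.c_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        B, H, Wd, C = self._shape
        xhat = self._pool.get("xhat", (B * H * Wd, self.c_out))
        mask = self._pool.get("mask", (B * H * Wd, self.c_out))
        self.dgamma, self.dbeta = _bn_relu_train_bwd(
            dy, xhat, mask, self.gamma, self._inv_std)
        dconv = xhat.reshape(B, H, Wd, self.c_out)
        d = self.dilation
        do2 = dconv.reshape(-1, self.c_out)
        col = self._pool.get("col", (B * H * Wd, 9 * C))
        # (do2.T @ col).T == col.T @ do2 with the cheaper transposed operand
        self.dW = (do2.T @ col).T
        if not need_dx:
            return None
        dcol = _SHARED.get("dcol", (B * H * Wd, 9 * C))
        np.matmul(do2, self.W.T, out=dcol)
        dxp = _SHARED.get("dxp", (B, H + 2 * d, Wd + 2 * d, C))
        dxp.fill(0.0)
        _col2im_3x3(dcol, d, H, Wd, dxp)
        # contiguous copy: the caller's BN backward streams much faster over
        # a contiguous gradient than over a padded-view slice; the buffer is
        # shared because it is consumed by that BN backward immediately
        dx = _SHARED.get("dx", (B, H, Wd, C))
        dx[...] = dxp[:, d:-d, d:-d, :]
        return dx

    def params(self):
        return [self.W, self.gamma, self.beta]

    def grads(self):
        return [self.dW, self.dgamma, self.dbeta]

    def stats(self):
        return [self.running_mean, self.running_var]


class Conv1x1:
    """1x1 convolution (per-pixel dense layer), optional bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bias: bool = False):
        self.c_in = c_in
        self.c_out = c_out
        self.W = he_uniform(rng, fan_in=c_in, shape=(c_in, c_out))
        self.b = np.zeros(c_out, F32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._x2: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        B, H, W, C = x.shape
        x2 = x.reshape(-1, C)
        y = x2 @ self.W
        if self.b is not None:
            y += self.b
        if cache:
            self._x2 = x2
            self._shape = (B, H, W)
        return y.reshape(B, H, W, self.c_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        B, H, W = self._shape
        do2 = dy.reshape(-1, self.c_out)
        self.dW = (do2.T @ self._x2).T
        if self.b is not None:
            self.db = do2.sum(axis=0)
        self._x2 = None
        if not need_dx:
            return None
        return (do2 @ self.W.T).reshape(B, H, W, self.c_in)

    def params(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def grads(self):
        return [self.dW] if self.b is None else [self.dW, self.db]


class BatchNorm:
    """Per-channel batch normalization over (B, H, W) with running statistics.

    ``training=True`` normalizes with batch statistics and updates the running
    mean/variance; ``training=False`` uses the stored running statistics (the
    mode used at inference and throughout patient-specific fine-tuning, where
    batch norm is frozen).
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = np.ones(channels, F32)
        self.beta = np.zeros(channels, F32)
        self.running_mean = np.zeros(channels, F32)
        self.running_var = np.ones(channels, F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool, cache: bool) -> np.ndarray:
        axes = (0, 1, 2)
        if training:
            x2 = x.reshape(-1, x.shape[-1])
            mean = x2.mean(axis=0)
            var = x2.var(axis=0)
            m = F32(self.momentum)
            self.running_mean *= 1 - m
            self.running_mean += m * mean.astype(F32)
            self.running_var *= 1 - m
            self.running_var += m * var.astype(F32)
            inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
            xhat = np.subtract(x, mean, dtype=F32)
            xhat *= inv_std
            if cache:
                self._cache = ("train", xhat, inv_std)
        else:
            inv_std = (1.0 / np.sqrt(self.running_var + self.eps)).astype(F32)
            xhat = np.subtract(x, self.running_mean, dtype=F32)
            xhat *= inv_std
            if cache:
                self._cache = ("eval", inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mode = self._cache[0]
        if mode == "eval":
            _, inv_std = self._cache
            self._cache = None
            # frozen BN is a per-channel affine map; no grads accumulated
            return dy * (self.gamma * inv_std)
        _, xhat, inv_std = self._cache
        self._cache = None
        axes = (0, 1, 2)
        self.dgamma = (dy * xhat).sum(axis=axes).astype(F32)
        self.dbeta = dy.sum(axis=axes).astype(F32)
        dxhat = dy * self.gamma
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) * inv_std
        return dx.astype(F32, copy=False)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def stats(self):
        return [self.running_mean, self.running_var]


class ReLU:
    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        self._mask = None
        return dy


class Dropout:
    """Inverted dropout applied in place; identity when inactive or rate == 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1): {rate}")
        self.rate = rate
        self._pool = _BufferPool()
        self._mask = None

    def forward(self, x: np.ndarray, rng: np.random.Generator | None,
                active: bool, cache: bool) -> np.ndarray:
        if not active or self.rate == 0.0:
            self._mask = None
            return x
        flat = x.reshape(-1)
        rand = rng.random(flat.size, dtype=np.float32)
        mask = self._pool.get("mask", (flat.size,))
        _dropout_fwd(flat, rand, F32(1.0 - self.rate), mask)
        self._mask = mask if cache else None
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dy *= self._mask.reshape(dy.shape)
        self._mask = None
        return dy


class BNReLU:
    """Batch norm + ReLU applied in place on a contiguous (B, H, W, C) tensor.

    Same numerics as ConvBNReLU without the convolution; used in the network
    head after the 128-kernel 1x1 convolution.  Eval mode reduces to a fused
    per-channel affine + ReLU using the frozen running statistics.
    """

    momentum = 0.1
    eps = 1e-5

    def __init__(self, channels: int):
        self.gamma = np.ones(channels, F32)
        self.beta = np.zeros(channels, F32)
        self.running_mean = np.zeros(channels, F32)
        self.running_var = np.ones(channels, F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._pool = _BufferPool()
        self._mode = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        shape = x.shape
        c = shape[-1]
        x2 = x.reshape(-1, c)
        if training:
            xhat = self._pool.get("xhat", x2.shape)
            mask = self._pool.get("mask", x2.shape)
            mean = np.empty(c, F32)
            var = np.empty(c, F32)
            _bn_relu_train_fwd(x2, self.gamma, self.beta, xhat, mask,
                               mean, var)
            m = F32(self.momentum)
            self.running_mean *= 1 - m
            self.running_mean += m * mean
            self.running_var *= 1 - m
            self.running_var += m * var
            self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
            self._mode = "train"
        else:
            a = (self.gamma / np.sqrt(self.running_var + self.eps)).astype(F32)
            b = (self.beta - a * self.running_mean).astype(F32)
            mask = self._pool.get("mask", x2.shape)
            _affine_relu_fwd(x2, a, b, mask)
            self._scale = a
            self._mode = "eval"
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = dy.shape[-1]
        if self._mode == "eval":
            mask = self._pool.get("mask", (dy.size // c, c))
            dy *= (mask * self._scale).reshape(dy.shape)
            return dy
        xhat = self._pool.get("xhat", (dy.size // c, c))
        mask = self._pool.get("mask", (dy.size // c, c))
        dy4 = dy.reshape((1, 1, -1, c)) if dy.ndim != 4 else dy
        self.dgamma, self.dbeta = _bn_relu_train_bwd(
            dy4, xhat, mask, self.gamma, self._inv_std)
        return xhat.reshape(dy.shape)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def stats(self):
        return [self.running_mean, self.running_var]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over an explicit list of parameter arrays (in-place)."""

    def __init__(self, params: list, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= (self.lr * (m / bias1)
                  / (np.sqrt(v / bias2) + self.eps)).astype(p.dtype)
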