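"""Minimal NumPy neural-network engine used by the classifier and SGAN modules.

Implements exactly the layer vocabulary the compact CNN and the SGAN generator
need — 2-D convolution and transposed convolution (``same`` padding), batch
normalization, ceil-mode ``same`` pooling, dropout/spatial dropout, dense
layers and the usual activations — together with an Adam optimizer and the two
losses used in training (sparse softmax cross-entropy for the class head,
binary cross-entropy through the shared-logit real/fake squashing for the
discriminator head).

Conventions follow the common TensorFlow/Keras ones so that the printed layer
shape tables of the reference architecture propagate exactly: NHWC tensors,
``same`` padding computed as ``max((ceil(n/s)-1)*s + k - n, 0)`` split
low/high, pooling with ceil-mode output sizes and padding excluded from
average-pool counts. All arithmetic is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "Conv2D", "ConvTranspose2D", "BatchNorm", "ReLU",
    "LeakyReLU", "Sigmoid", "MaxPool2D", "AvgPool2D", "Dropout",
    "SpatialDropout2D", "Flatten", "Reshape", "Sequential", "Adam",
    "softmax", "sparse_softmax_xent", "dout_score", "dout_bce",
]

_F32 = np.float32


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """Return (pad_low, pad_high, n_out) for ``same`` padding."""
    n_out = -(-n // s)  # ceil division
    pad = max((n_out - 1) * s + k - n, 0)
    return pad // 2, pad - pad // 2, n_out


#: patch-matrix budget for the im2col fast path, bytes
_IM2COL_BUDGET = 200 * 1024 * 1024


def _im2col(xp: np.ndarray, kh: int, kw: int, s: int, ho: int,
            wo: int) -> np.ndarray:
    """(N*Ho*Wo, kh*kw*C) patch matrix from a padded NHWC input."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::s, ::s][:, :ho, :wo]
    return np.ascontiguousarray(np.moveaxis(win, 3, 5)).reshape(
        xp.shape[0] * ho * wo, kh * kw * xp.shape[3])


def _conv_fwd(xp: np.ndarray, w: np.ndarray, s: int, ho: int,
              wo: int) -> np.ndarray:
    """Correlate padded NHWC input with kernel w (kh, kw, c, co).

    Three regimes, chosen by patch-matrix size and stride: a single im2col
    GEMM when the patch matrix is small; one fat (c, kw*co) GEMM per kernel
    row for dense stride-1 maps; a plain per-offset loop otherwise (strided
    maps with many channels, where row grouping would waste stride^2 work).
    """
    kh, kw, c, co = w.shape
    n = xp.shape[0]
    wp = xp.shape[2]
    if n * ho * wo * kh * kw * c * 4 <= _IM2COL_BUDGET:
        cols = _im2col(xp, kh, kw, s, ho, wo)
        y = cols @ w.reshape(kh * kw * c, co)
        return y.reshape(n, ho, wo, co)
    if s == 1:
        y = np.zeros((n, ho, wo, co), dtype=_F32)
        for i in range(kh):
            rows = np.ascontiguousarray(xp[:, i:i + ho])
            z = (rows.reshape(-1, c) @
                 w[i].transpose(1, 0, 2).reshape(c, kw * co))
            z = z.reshape(n, ho, wp, kw, co)
            for j in range(kw):
                y += z[:, :, j:j + wo, j]
        return y
    yf = np.zeros((n * ho * wo, co), dtype=_F32)
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(
                xp[:, i:i + s * (ho - 1) + 1:s,
                   j:j + s * (wo - 1) + 1:s]).reshape(-1, c)
            yf += xs @ w[i, j]
    return yf.reshape(n, ho, wo, co)


def _conv_bwd_data(dy: np.ndarray, w: np.ndarray, s: int,
                   padded_shape: tuple[int, ...]) -> np.ndarray:
    """Scatter output gradients back onto the padded input grid."""
    kh, kw, c, co = w.shape
    n, ho, wo, _ = dy.shape
    dxp = np.zeros(padded_shape, dtype=_F32)
    dyf = dy.reshape(-1, co)
    for i in range(kh):
        z = (dyf @ w[i].transpose(2, 0, 1).reshape(co, kw * c))
        z = z.reshape(n, ho, wo, kw, c)
        for j in range(kw):
            dxp[:, i:i + s * (ho - 1) + 1:s,
                j:j + s * (wo - 1) + 1:s] += z[:, :, :, j]
    return dxp


def _conv_bwd_data_s1(dy: np.ndarray, w: np.ndarray,
                      padded_shape: tuple[int, ...]) -> np.ndarray:
    """Stride-1 input gradient as one im2col GEMM over dy.

    The input gradient of a stride-1 convolution is itself a full
    correlation of dy with the spatially flipped kernel; since dy usually
    has few channels the patch matrix stays small and the whole
    accumulation happens inside a single fat GEMM instead of kh*kw strided
    read-modify-write passes.
    """
    kh, kw, c, co = w.shape
    n, ho, wo, _ = dy.shape
    hp, wp = padded_shape[1], padded_shape[2]
    # pad dy so every padded-input position sees a full window
    dyp = np.zeros((n, hp + kh - 1, wp + kw - 1, co), dtype=_F32)
    dyp[:, kh - 1:kh - 1 + ho, kw - 1:kw - 1 + wo] = dy
    win = np.lib.stride_tricks.sliding_window_view(dyp, (kh, kw),
                                                   axis=(1, 2))
    cols = np.ascontiguousarray(np.moveaxis(win, 3, 5)).reshape(
        n * hp * wp, kh * kw * co)
    wrev = w[::-1, ::-1].transpose(0, 1, 3, 2).reshape(kh * kw * co, c)
    return (cols @ wrev).reshape(padded_shape)


def _conv_dw(xp: np.ndarray, dy: np.ndarray, s: int, kh: int,
             kw: int) -> np.ndarray:
    """Kernel gradient, with the same regime split as :func:`_conv_fwd`."""
    n, ho, wo, co = dy.shape
    wp = xp.shape[2]
    c = xp.shape[3]
    if n * ho * wo * kh * kw * c * 4 <= _IM2COL_BUDGET:
        cols = _im2col(xp, kh, kw, s, ho, wo)
        return (cols.T @ dy.reshape(-1, co)).reshape(kh, kw, c, co)
    dw = np.empty((kh, kw, c, co), dtype=_F32)
    if s == 1:
        dyf = None
        for i in range(kh):
            rows = np.ascontiguousarray(xp[:, i:i + ho])
            dsc = np.zeros((n, ho, wp, kw * co), dtype=_F32)
            for j in range(kw):
                dsc[:, :, j:j + wo, j * co:(j + 1) * co] = dy
            z = rows.reshape(-1, c).T @ dsc.reshape(-1, kw * co)
            dw[i] = z.reshape(c, kw, co).transpose(1, 0, 2)
        return dw
    dyf = dy.reshape(-1, co)
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(
                xp[:, i:i + s * (ho - 1) + 1:s,
                   j:j + s * (wo - 1) + 1:s]).reshape(-1, c)
            dw[i, j] = xs.T @ dyf
    return dw


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of ndarrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        w = rng.uniform(-limit, limit, (n_in, n_out)).astype(_F32)
        b = np.zeros(n_out, dtype=_F32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.params[0].T


class Conv2D(Layer):
    """NHWC convolution, ``same`` padding, square or rectangular kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 stride: int, rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        fan_in, fan_out = kh * kw * c_in, kh * kw * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, (kh, kw, c_in, c_out)).astype(_F32)
        b = np.zeros(c_out, dtype=_F32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.kernel, self.stride = (kh, kw), stride

    def forward(self, x, training):
        kh, kw = self.kernel
        s = self.stride
        n, h, w_, c = x.shape
        pt, pb, ho = _same_pad(h, kh, s)
        pl, pr, wo = _same_pad(w_, kw, s)
        xp = np.pad(x.astype(_F32, copy=False),
                    ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        y = _conv_fwd(xp, self.params[0], s, ho, wo) + self.params[1]
        self._cache = (xp, x.shape, pt, pl)
        return y

    def backward(self, dy):
        xp, xshape, pt, pl = self._cache
        kh, kw = self.kernel
        s = self.stride
        n, h, w_, c = xshape
        self.grads[0][...] = _conv_dw(xp, dy, s, kh, kw)
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        if s == 1:
            dxp = _conv_bwd_data_s1(dy, self.params[0], xp.shape)
        else:
            dxp = _conv_bwd_data(dy, self.params[0], s, xp.shape)
        return dxp[:, pt:pt + h, pl:pl + w_]


class ConvTranspose2D(Layer):
    """Transposed convolution, stride-s ``same`` semantics (out = in * s).

    Kernel is stored in the (kh, kw, c_out, c_in) layout of the equivalent
    forward convolution from the output back to the input, so the forward
    pass here is exactly that convolution's input-gradient.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 stride: int, rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        limit = np.sqrt(6.0 / (kh * kw * c_in + kh * kw * c_out))
        w = rng.uniform(-limit, limit, (kh, kw, c_out, c_in)).astype(_F32)
        b = np.zeros(c_out, dtype=_F32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.kernel, self.stride = (kh, kw), stride

    def forward(self, x, training):
        kh, kw = self.kernel
        s = self.stride
        n, h, w_, c_in = x.shape
        ho, wo = h * s, w_ * s
        c_out = self.params[0].shape[2]
        pt, pb, _ = _same_pad(ho, kh, s)
        pl, pr, _ = _same_pad(wo, kw, s)
        x = np.ascontiguousarray(x, dtype=_F32)
        # the transposed conv is the input-gradient of the equivalent
        # forward convolution (output -> input), so reuse its kernels
        yp = _conv_bwd_data(x, self.params[0], s,
                            (n, ho + pt + pb, wo + pl + pr, c_out))
        y = np.ascontiguousarray(yp[:, pt:pt + ho, pl:pl + wo])
        y += self.params[1]
        self._cache = (x, (ho, wo), (pt, pb, pl, pr))
        return y

    def backward(self, dy):
        x, (ho, wo), (pt, pb, pl, pr) = self._cache
        kh, kw = self.kernel
        s = self.stride
        dyp = np.pad(dy.astype(_F32, copy=False),
                     ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        self.grads[0][...] = _conv_dw(dyp, x, s, kh, kw)
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        return _conv_fwd(dyp, self.params[0], s, x.shape[1], x.shape[2])


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channels)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        gamma = np.ones(c, dtype=_F32)
        beta = np.zeros(c, dtype=_F32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mu
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, axes)
        return self.params[0] * xhat + self.params[1]

    def backward(self, dy):
        xhat, inv_std, axes = self._cache
        m = np.prod([dy.shape[a] for a in axes])
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        g = self.params[0] * inv_std
        return g * (dy - dy.mean(axis=axes)
                    - xhat * (dy * xhat).sum(axis=axes) / m)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training):
        self._scale = np.where(x > 0, _F32(1.0), _F32(self.alpha))
        return x * self._scale

    def backward(self, dy):
        return dy * self._scale


class Sigmoid(Layer):
    def forward(self, x, training):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class _Pool2D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def _pad_shape(self, x):
        p = self.pool
        n, h, w, c = x.shape
        ho, wo = -(-h // p), -(-w // p)
        return n, h, w, c, ho, wo, ho * p - h, wo * p - w


class MaxPool2D(_Pool2D):
    """Ceil-mode max pooling, pool == stride, ``same`` padding with -inf."""

    def forward(self, x, training):
        p = self.pool
        n, h, w, c, ho, wo, ph, pw = self._pad_shape(x)
        xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                    constant_values=-np.inf)
        r = xp.reshape(n, ho, p, wo, p, c)
        y = r.max(axis=(2, 4))
        mask = r == y[:, :, None, :, None, :]
        # split gradient across ties to keep backward well defined
        self._cache = (mask / mask.sum(axis=(2, 4), keepdims=True),
                       (h, w))
        return y

    def backward(self, dy):
        mask, (h, w) = self._cache
        n, ho, p, wo, _, c = mask.shape
        dxp = (mask * dy[:, :, None, :, None, :]).reshape(
            n, ho * p, wo * p, c)
        return np.ascontiguousarray(dxp[:, :h, :w])


class AvgPool2D(_Pool2D):
    """Ceil-mode average pooling; padded cells excluded from the mean."""

    def forward(self, x, training):
        p = self.pool
        n, h, w, c, ho, wo, ph, pw = self._pad_shape(x)
        xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)))
        ones = np.pad(np.ones((1, h, w, 1), dtype=_F32),
                      ((0, 0), (0, ph), (0, pw), (0, 0)))
        counts = ones.reshape(1, ho, p, wo, p, 1).sum(axis=(2, 4))
        y = xp.reshape(n, ho, p, wo, p, c).sum(axis=(2, 4)) / counts
        self._cache = (counts, (h, w), p)
        return y

    def backward(self, dy):
        counts, (h, w), p = self._cache
        d = (dy / counts)[:, :, None, :, None, :]
        n, ho, _, wo, _, c = d.shape
        dxp = np.broadcast_to(d, (n, ho, p, wo, p, c)).reshape(
            n, ho * p, wo * p, c)
        return np.ascontiguousarray(dxp[:, :h, :w])


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def _mask_shape(self, x):
        return x.shape

    def forward(self, x, training):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(self._mask_shape(x)) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class SpatialDropout2D(Dropout):
    """Drops whole feature maps (channels) of NHWC tensors."""

    def _mask_shape(self, x):
        return (x.shape[0], 1, 1, x.shape[3])


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential:
    """Ordered layer container with forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=_F32)
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Layer, int]]:
        return [(lay, i) for lay in self.layers
                for i in range(len(lay.params))]

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for lay in self.layers:
            out.extend(p.copy() for p in lay.params)
            if isinstance(lay, BatchNorm):
                out.extend([lay.running_mean.copy(), lay.running_var.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for lay in self.layers:
            for i in range(len(lay.params)):
                w = next(it)
                lay.params[i][...] = w.astype(_F32)
            if isinstance(lay, BatchNorm):
                lay.running_mean[...] = next(it)
                lay.running_var[...] = next(it)


class Adam:
    """Adam with the usual bias-corrected moment estimates."""

    def __init__(self, net: "Sequential", lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.slots = net.parameters()
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(lay.params[i]) for lay, i in self.slots]
        self.v = [np.zeros_like(lay.params[i]) for lay, i in self.slots]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (
            1 - self.b1 ** self.t)
        for k, (lay, i) in enumerate(self.slots):
            g = lay.grads[i]
            m, v = self.m[k], self.v[k]
            # in-place moment updates to avoid temporaries on large tensors
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            np.multiply(g, g, out=g)
            v += (1 - self.b2) * g
            np.sqrt(v, out=g)
            g += self.eps
            np.divide(m, g, out=g)
            g *= lr_t
            lay.params[i] -= g


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sparse_softmax_xent(logits: np.ndarray, labels: np.ndarray,
                        weight: float = 1.0):
    """Mean sparse categorical cross-entropy; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    idx = np.arange(n)
    loss = -np.mean(np.log(p[idx, labels] + 1e-12))
    d = p.copy()
    d[idx, labels] -= 1.0
    return weight * loss, (weight / n) * d.astype(_F32)


def dout_score(logits: np.ndarray) -> np.ndarray:
    """Real/fake score D = Z/(Z+1) with Z = sum_k exp(logit_k).

    Equivalent to a sigmoid of logsumexp over the shared class logits —
    the canonical way to reuse a classifier's output layer as an
    unsupervised discriminator head.
    """
    m = logits.max(axis=-1)
    lse = m + np.log(np.exp(logits - m[..., None]).sum(axis=-1))
    return 1.0 / (1.0 + np.exp(-lse))


def dout_bce(logits: np.ndarray, target: float, weight: float = 1.0):
    """BCE on the D_out score; returns (loss, dlogits)."""
    n = logits.shape[0]
    d = dout_score(logits)
    loss = -np.mean(target * np.log(d + 1e-12)
                    + (1 - target) * np.log(1 - d + 1e-12))
    dlogits = ((d - target) / n)[:, None] * softmax(logits)
    return weight * loss, weight * dlogits.astype(_F32)
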