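"""Minimal CNN layer zoo with hand-written backpropagation.

Only what the artifact-removal network needs: stride-1 zero-padded
convolutions, 2x2 max pooling, bilinear / transposed-convolution
up-sampling, batch normalization, ReLU and squeeze-and-excitation channel
gating.  All layers operate on (batch, channels, height, width) arrays,
keep the dtype of their input, and cache what backward needs.

Every backward pass is verified against finite differences in the test
suite; that, not framework parity, is the correctness contract.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base: parameter dict, gradient dict, forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> (B*Ho*Wo, C*kh*kw) patch matrix (copy)."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))   # B,C,Ho,Wo,kh,kw
    b, c, ho, wo = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw), (ho, wo)


class Conv2D(Layer):
    """Stride-1 convolution with explicit zero padding.

    ``pad`` is ((top, bottom), (left, right)); the defaults keep spatial
    size for the 3x3 ('same') case.
    """

    def __init__(self, in_ch, out_ch, kernel=3, pad=None, rng=None, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh = kw = kernel
        if pad is None:
            if kernel % 2 == 1:
                p = kernel // 2
                pad = ((p, p), (p, p))
            else:
                pad = ((kernel // 2, kernel // 2 - 1), (kernel // 2, kernel // 2 - 1))
        self.pad = pad
        self.kh, self.kw = kh, kw
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["W"] = _he_init(rng, (out_ch, in_ch, kh, kw), in_ch * kh * kw)
        if bias:
            self.params["b"] = np.zeros(out_ch, np.float32)

    def forward(self, x, training=True):
        (pt, pb), (pl, pr) = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        cols, (ho, wo) = _im2col(xp, self.kh, self.kw)
        W = self.params["W"]
        y = cols @ W.reshape(self.out_ch, -1).T
        y = y.reshape(x.shape[0], ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        if "b" in self.params:
            y = y + self.params["b"][None, :, None, None]
        self._cache = (xp, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        xp, x_shape = self._cache
        b = dy.shape[0]
        cols, (ho, wo) = _im2col(xp, self.kh, self.kw)
        dyr = dy.transpose(0, 2, 3, 1).reshape(b * ho * wo, self.out_ch)
        self.grads["W"] = (dyr.T @ cols).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2, 3))
        # full correlation of dy with the flipped kernel gives dx
        (pt, pb), (pl, pr) = self.pad
        dyp = np.pad(
            dy,
            ((0, 0), (0, 0),
             (self.kh - 1 - pt, self.kh - 1 - pb),
             (self.kw - 1 - pl, self.kw - 1 - pr)),
        )
        Wf = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # Ci,Co,kh,kw
        cols2, (hi, wi) = _im2col(dyp, self.kh, self.kw)
        dx = cols2 @ Wf.reshape(self.in_ch, -1).T
        dx = dx.reshape(b, hi, wi, self.in_ch).transpose(0, 3, 1, 2)
        assert dx.shape[2:] == x_shape[2:]
        return np.ascontiguousarray(dx)


class ReLU(Layer):
    def forward(self, x, training=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics.

    Training uses mini-batch moments and updates the running averages;
    inference uses the accumulated statistics only, so it is a pure
    function of its input.
    """

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, np.float32)
        self.params["beta"] = np.zeros(channels, np.float32)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x, training=True):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training, x.shape)
        g, b = self.params["gamma"], self.params["beta"]
        return g[None, :, None, None] * xhat + b[None, :, None, None]

    def backward(self, dy):
        xhat, inv_std, training, shape = self._cache
        g = self.params["gamma"]
        self.grads["gamma"] = np.sum(dy * xhat, axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * g[None, :, None, None]
        if not training:
            return dxhat * inv_std[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (dxhat - s1 / n - xhat * s2 / n) * inv_std[None, :, None, None]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, training=True):
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, c, h, w = self._shape
        flat = np.zeros((b, c, h // 2, w // 2, 4), dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(flat.reshape(b, c, h, w))


def _bilinear_matrix(n_out: int, n_in: int, dtype=np.float32) -> np.ndarray:
    """Row-stochastic interpolation matrix for x2 bilinear resizing."""
    A = np.zeros((n_out, n_in), dtype)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w = np.clip(src - i0, 0.0, 1.0)
    A[np.arange(n_out), i0] += 1.0 - w
    A[np.arange(n_out), i1] += w
    return A


class BilinearUp2(Layer):
    """Deterministic x2 bilinear up-sampling (no parameters)."""

    def forward(self, x, training=True):
        h, w = x.shape[2:]
        self._Ah = _bilinear_matrix(2 * h, h, x.dtype)
        self._Aw = _bilinear_matrix(2 * w, w, x.dtype)
        return self._Ah @ x @ self._Aw.T

    def backward(self, dy):
        return self._Ah.T @ dy @ self._Aw


class TransposedConv2x2(Layer):
    """2x2 transposed convolution, stride 2 (the checkerboard-prone
    up-sampling alternative the bilinear path is compared against)."""

    def __init__(self, in_ch, out_ch, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["W"] = _he_init(rng, (in_ch, out_ch, 2, 2), in_ch)
        self.params["b"] = np.zeros(out_ch, np.float32)

    def forward(self, x, training=True):
        self._x = x
        b, c, h, w = x.shape
        t = np.tensordot(x, self.params["W"], axes=([1], [0]))  # b,h,w,o,2,2
        t = t.transpose(0, 3, 1, 4, 2, 5).reshape(b, self.out_ch, 2 * h, 2 * w)
        return np.ascontiguousarray(t + self.params["b"][None, :, None, None])

    def backward(self, dy):
        x = self._x
        b, c, h, w = x.shape
        dyr = dy.reshape(b, self.out_ch, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        # dyr: b,h,w,o,2,2
        self.grads["W"] = np.tensordot(x, dyr, axes=([0, 2, 3], [0, 1, 2]))
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dyr, self.params["W"], axes=([3, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class SEBlock(Layer):
    """Squeeze-and-excitation channel recalibration.

    Global average pooling squeezes each channel to a scalar descriptor; a
    two-layer bottleneck (reduction ratio r, ReLU then sigmoid) produces a
    per-channel gate in (0, 1) that rescales the feature map channel-wise.
    Setting ``force_identity`` saturates the gates to exactly 1 (diagnostic
    mode).
    """

    def __init__(self, channels, reduction=16, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        hidden = max(1, channels // reduction)
        self.channels, self.hidden = channels, hidden
        self.params["W1"] = _he_init(rng, (channels, hidden), channels)
        self.params["b1"] = np.zeros(hidden, np.float32)
        self.params["W2"] = _he_init(rng, (hidden, channels), hidden)
        self.params["b2"] = np.zeros(channels, np.float32)
        self.force_identity = False

    def forward(self, x, training=True):
        if self.force_identity:
            self._cache = None
            return x
        s = x.mean(axis=(2, 3))                       # (B, C)
        z = s @ self.params["W1"] + self.params["b1"]
        a = np.maximum(z, 0.0)
        g = _sigmoid(a @ self.params["W2"] + self.params["b2"])
        self._cache = (x, s, z, a, g)
        return x * g[:, :, None, None]

    def backward(self, dy):
        if self._cache is None:
            return dy
        x, s, z, a, g = self._cache
        hw = x.shape[2] * x.shape[3]
        dg = np.sum(dy * x, axis=(2, 3))              # (B, C)
        dx = dy * g[:, :, None, None]
        dpre2 = dg * g * (1.0 - g)
        self.grads["W2"] = a.T @ dpre2
        self.grads["b2"] = dpre2.sum(axis=0)
        da = dpre2 @ self.params["W2"].T
        dz = da * (z > 0)
        self.grads["W1"] = s.T @ dz
        self.grads["b1"] = dz.sum(axis=0)
        ds = dz @ self.params["W1"].T
        return dx + ds[:, :, None, None] / hw


class Adam:
    """Adam over a list of layers, with optional decoupled-into-gradient L2
    weight decay applied to convolution/dense weight tensors only."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    @staticmethod
    def _decayable(name: str) -> bool:
        return name.startswith("W")

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k].astype(p.dtype)
                if self.weight_decay and self._decayable(k):
                    g = g + self.weight_decay * p
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**self.t)
                vhat = v[k] / (1 - b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
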