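"""Minimal NumPy neural-network engine backing the scalable U-net.

Implements exactly the layer set the segmentation architecture needs —
3x3/1x1 "same" convolutions (im2col), batch normalisation, the Mish
activation, 2x2 max pooling, 2x2 stride-2 transposed convolutions, channel
concatenation — with hand-written backward passes and an Adam optimiser.
Arrays are NCHW float32 throughout.  Single-threaded NumPy makes runs with a
fixed seed bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "BatchNorm2D", "Mish", "MaxPool2", "AvgPool2",
           "ConvTranspose2x2", "Adam", "softmax", "softmax_cross_entropy"]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base class: trainable layers expose params() as [(array, grad), ...]."""

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride 1, "same" zero padding, with bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("Conv2D supports odd kernels only")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.W = _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        if training:
            self._cols, self._xshape = cols, x.shape
        out = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, f, h, w = grad.shape
        gflat = grad.transpose(0, 2, 3, 1).reshape(-1, f)
        self.dW[...] = (gflat.T @ self._cols).reshape(self.W.shape)
        self.db[...] = gflat.sum(axis=0)
        dcols = gflat @ self.W.reshape(f, -1)  # (n*h*w, c*k*k)
        c, k, p = self.in_ch, self.k, self.k // 2
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2D(Layer):
    """Per-channel batch normalisation with affine parameters."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self._cache = None
        m = shape[0] * shape[2] * shape[3]
        axes = (0, 2, 3)
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        g = self.gamma[None, :, None, None]
        dxhat = grad * g
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )
        return dx.astype(np.float32)


class Mish(Layer):
    """Mish activation: x * tanh(softplus(x))."""

    def __init__(self):
        self._x = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        sp = np.logaddexp(0.0, x)
        return (x * np.tanh(sp)).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        sp = np.logaddexp(0.0, x)
        t = np.tanh(sp)
        sig = 1.0 / (1.0 + np.exp(-x))
        return (grad * (t + x * (1.0 - t * t) * sig)).astype(np.float32)


class Identity(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {(h, w)}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        if training:
            self._idx, self._shape = idx, x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(out, self._idx[..., None], grad[..., None], axis=-1)
        self._idx = None
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


class AvgPool2(Layer):
    """2x2 average pooling; geometry-identical stand-in for max pooling in
    receptive-field analysis (gradients flow to the whole window)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) * 0.25
        return g.astype(np.float32)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = _he_init(rng, (in_ch, out_ch, 2, 2), in_ch)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        n, c, h, w = x.shape
        y = np.einsum("nchw,cfab->nfhawb", x, self.W, optimize=True)
        return (y.reshape(n, self.out_ch, 2 * h, 2 * w) + self.b[None, :, None, None]).astype(
            np.float32
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        n, f, h2, w2 = grad.shape
        g = grad.reshape(n, f, h2 // 2, 2, w2 // 2, 2)
        self.dW[...] = np.einsum("nchw,nfhawb->cfab", x, g, optimize=True)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        return np.einsum("nfhawb,cfab->nchw", g, self.W, optimize=True).astype(np.float32)


# ---------------------------------------------------------------------------
# Loss and optimiser
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over all pixels.

    ``logits``: (N, k, H, W); ``targets``: (N, H, W) integer labels.
    Returns (loss, dlogits).
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    onehot_idx = targets[:, None, :, :]
    picked = np.take_along_axis(p, onehot_idx, axis=1)[:, 0]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    dlogits = p.copy()
    np.put_along_axis(dlogits, onehot_idx, np.take_along_axis(dlogits, onehot_idx, axis=1) - 1.0, axis=1)
    dlogits /= n * h * w
    return loss, dlogits.astype(np.float32)


class Adam:
    """Adam optimiser over a list of (param, grad) pairs."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
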