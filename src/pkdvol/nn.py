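"""Minimal numpy neural-network engine for 2-D semantic segmentation.

Implements exactly the layer set the kidney-segmentation network needs:
3x3 convolution (im2col + BLAS matmul), batch normalization, ReLU,
2x2/stride-2 max-pooling that records argmax locations, index-driven
unpooling, 1x1 convolution, and a fused softmax cross-entropy loss.
Every layer provides an explicit backward pass; the AdaGrad optimizer
updates parameters in place.

All tensors are float32 in (N, C, H, W) layout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "MaxUnpool2d",
    "softmax",
    "softmax_cross_entropy",
    "AdaGrad",
    "xavier_uniform",
]


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization: U(-a, a), a = sqrt(6/(fan_in+fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: holds named parameters and matching gradient buffers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' zero padding (k odd).

    Also serves as the decoder's deconvolution: with stride 1 and same
    padding a transposed convolution is an ordinary convolution with a
    flipped kernel, so the learned operation is identical.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.params["W"] = xavier_uniform(rng, (out_ch, in_ch * kernel * kernel),
                                          fan_in, fan_out)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        k, p = self.k, self.k // 2
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
            win = sliding_window_view(xp, (k, k), axis=(2, 3))
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                        ).reshape(n * h * w, c * k * k)
        out = cols @ self.params["W"].T + self.params["b"]
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._xshape is not None
        n, c, h, w = self._xshape
        k, p = self.k, self.k // 2
        gmat = gout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.grads["W"][...] = gmat.T @ self._cols
        self.grads["b"][...] = gmat.sum(axis=0)
        gcols = gmat @ self.params["W"]  # (N*H*W, C*k*k)
        if k == 1:
            gx = gcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        else:
            gcols = gcols.reshape(n, h, w, c, k, k)
            gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
            for ki in range(k):
                for kj in range(k):
                    gxp[:, :, ki:ki + h, kj:kj + w] += \
                        gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            gx = gxp[:, :, p:p + h, p:p + w]
        self._cols = None
        return np.ascontiguousarray(gx)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learned scale/shift.

    Batch statistics during training; exponential running statistics,
    frozen at evaluation.
    """

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(n_ch, dtype=np.float32)
        self.params["beta"] = np.zeros(n_ch, dtype=np.float32)
        self.grads["gamma"] = np.zeros(n_ch, dtype=np.float32)
        self.grads["beta"] = np.zeros(n_ch, dtype=np.float32)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self._cache: tuple | None = None
        #: when set to a list, eval-mode forward normalizes with fresh batch
        #: statistics and appends (mean, var) — used for recalibration sweeps
        self.capture_stats: list | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if self.capture_stats is not None and not train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.capture_stats.append((mean, var))
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            return (g * xhat + b).astype(np.float32)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv)
            return (g * xhat + b).astype(np.float32)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return (g * xhat + b).astype(np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv = self._cache
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        self.grads["gamma"][...] = (gout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = gout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        gxhat = gout * g
        gx = (inv[None, :, None, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        self._cache = None
        return gx.astype(np.float32)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        gx = gout * self._mask
        self._mask = None
        return gx


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2, recording the argmax location per window.

    The recorded index is the flat position within each window in row-major
    scan order; ties resolve to the first maximum encountered.
    """

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        return (x.reshape(n, c, h // 2, 2, w // 2, 2)
                 .transpose(0, 1, 2, 4, 3, 5)
                 .reshape(n, c, h // 2, w // 2, 4))

    def forward(self, x: np.ndarray, train: bool = True):
        win = self._windows(x)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
        return out, idx

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._idx is not None
        n, c, ho, wo = gout.shape
        gwin = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(gwin, self._idx[..., None], gout[..., None], axis=-1)
        self._idx = None
        return (gwin.reshape(n, c, ho, wo, 2, 2)
                    .transpose(0, 1, 2, 4, 3, 5)
                    .reshape(n, c, 2 * ho, 2 * wo))


class MaxUnpool2d(Layer):
    """Places each pooled value back at its recorded argmax position; zeros elsewhere."""

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None

    def forward(self, x: np.ndarray, idx: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape != idx.shape:
            raise ValueError(f"value/index shape mismatch: {x.shape} vs {idx.shape}")
        n, c, ho, wo = x.shape
        win = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(win, idx[..., None], x[..., None].astype(np.float32), axis=-1)
        if train:
            self._idx = idx
        return (win.reshape(n, c, ho, wo, 2, 2)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(n, c, 2 * ho, 2 * wo))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._idx is not None
        win = MaxPool2d._windows(gout)
        gx = np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]
        self._idx = None
        return np.ascontiguousarray(gx)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean per-pixel multinomial cross-entropy and its gradient w.r.t. logits.

    logits: (N, K, H, W); labels: (N, H, W) integer class ids.
    """
    if logits.shape[0] != labels.shape[0] or logits.shape[2:] != labels.shape[1:]:
        raise ValueError(f"logit/label shape mismatch: {logits.shape} vs {labels.shape}")
    p = softmax(logits, axis=1)
    n, k, h, w = logits.shape
    flat = p.transpose(0, 2, 3, 1).reshape(-1, k)
    lab = labels.astype(np.int64).ravel()
    eps = 1e-12
    loss = float(-np.log(flat[np.arange(flat.shape[0]), lab] + eps).mean())
    grad = flat.copy()
    grad[np.arange(flat.shape[0]), lab] -= 1.0
    grad /= flat.shape[0]
    return loss, grad.reshape(n, h, w, k).transpose(0, 3, 1, 2).astype(np.float32)


class AdaGrad:
    """AdaGrad with L2 weight decay: g <- g + wd*p; G <- G + g^2; p <- p - lr*g/sqrt(G+eps)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-4,
                 weight_decay: float = 5e-4, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.weight_decay = weight_decay
        self.eps = eps
        self._accum = [{k: np.zeros_like(v) for k, v in l.params.items()}
                       for l in self.layers]

    def step(self) -> None:
        for layer, acc in zip(self.layers, self._accum):
            for name, p in layer.params.items():
                g = layer.grads[name]
                if self.weight_decay and name not in ("b", "beta"):
                    g = g + self.weight_decay * p
                a = acc[name]
                a += g * g
                p -= self.lr * g / (np.sqrt(a) + self.eps)
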