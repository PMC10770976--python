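"""Minimal NumPy CNN building blocks with manual backpropagation.

Just enough machinery for the small pyramid detector: same-padded 3x3 and
1x1 convolutions (im2col), ReLU, 2x2 max pooling, nearest-neighbor x2
upsampling, sigmoid, and an Adam optimizer.  Layers cache the tensors of
the most recent ``forward`` call and consume them in ``backward``; the
training loop alternates the two strictly.

Runs on CPU; sizes are chosen so desk-scale training finishes in minutes.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv2d:
    """Stride-1, same-padded k x k convolution on (B, C, H, W) tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 bias_init: float = 0.0, zero_init: bool = False):
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        if zero_init:  # heads start at their bias prior; stabilizes early steps
            w[...] = 0.0
        self.w = Param(w.astype(DTYPE))
        self.b = Param(np.full(c_out, bias_init, dtype=DTYPE))
        self.k = k
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        B, C, H, W = x.shape
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(-1, C)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        y = cols @ wmat.T + self.b.value
        self._cache = (cols, x.shape)
        return y.reshape(B, H, W, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        self._cache = None
        B, C, H, W = xshape
        k, p = self.k, self.k // 2
        c_out = self.w.value.shape[0]
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, c_out)
        wmat = self.w.value.reshape(c_out, -1)
        self.w.grad += (dyf.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ wmat  # (B*H*W, C*k*k)
        if k == 1:
            return dcols.reshape(B, H, W, C).transpose(0, 3, 1, 2)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=DTYPE)
        dcols = dcols.reshape(B, H, W, C, k, k)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + H, dj:dj + W] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m, self._mask = self._mask, None
        return dy * m


class MaxPool2:
    """2x2 max pooling with stride 2 (even input dims required)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(B, C, H // 2, W // 2, 4)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (B, C, H, W) = self._cache
        self._cache = None
        dflat = np.zeros((B, C, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        return (dflat.reshape(B, C, H // 2, W // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W))


class Upsample2:
    """Nearest-neighbor x2 upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def clip_grad_norm(self, max_norm: float) -> float:
        total = float(np.sqrt(sum(float((p.grad**2).sum()) for p in self.params)))
        if total > max_norm > 0:
            scale = max_norm / total
            for p in self.params:
                p.grad *= scale
        return total

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.wd * p.value
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
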