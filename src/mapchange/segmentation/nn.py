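"""NumPy building blocks for the segmentation network.

Convolutions are im2col + GEMM in float32; each layer caches what its
backward pass needs. The only optimizer is Adam with an externally supplied
learning rate, which the trainer drives with a one-cycle schedule. This is
deliberately a small, deterministic CPU stack: sheets are lightweight RGB
images and the desk-scale networks stay under ~10^5 parameters.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2D", "ReLU", "MaxPool2", "Upsample2", "Adam",
           "one_cycle_lr"]


class Param:
    """A trainable tensor with gradient accumulator and freeze flag."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix, zero padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)
    return np.ascontiguousarray(cols, dtype=np.float32)


class Conv2D:
    """Same-size 2-D convolution (odd kernel, stride 1, zero padding)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU nets
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in * k * k)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.k // 2)
        self._cols, self._x_shape = cols, x.shape
        y = self.w.value @ cols  # (N, c_out, H*W) via broadcast matmul
        y += self.b.value[:, None]
        return y.reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._x_shape
        dyf = dy.reshape(n, self.c_out, h * w).astype(np.float32)
        self.w.grad += np.einsum("nop,ncp->oc", dyf, self._cols, optimize=True)
        self.b.grad += dyf.sum(axis=(0, 2))
        # dx = "transposed" convolution: correlate dy with the flipped
        # kernels, swapping input/output channel roles
        k = self.k
        w4 = self.w.value.reshape(self.c_out, self.c_in, k, k)
        w_rot = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.c_in, self.c_out * k * k
        )
        cols_dy = _im2col(dyf.reshape(n, self.c_out, h, w), k, k // 2)
        dx = (w_rot @ cols_dy).reshape(n, self.c_in, h, w)
        self._cols = None
        return dx


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2 (inputs must have even spatial size)."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        blocks = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam over a parameter list; frozen parameters are skipped."""

    def __init__(self, params: list[Param], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 pct_start: float = 0.25, div: float = 25.0,
                 final_div: float = 1e4) -> float:
    """Cosine one-cycle schedule: warm up to max_lr, anneal far below it."""
    if total_steps <= 1:
        return max_lr
    warm = max(1, int(round(pct_start * total_steps)))
    if step < warm:
        frac = step / warm
        lo = max_lr / div
        return lo + (max_lr - lo) * 0.5 * (1 - np.cos(np.pi * frac))
    frac = (step - warm) / max(1, total_steps - warm)
    lo = max_lr / final_div
    return lo + (max_lr - lo) * 0.5 * (1 + np.cos(np.pi * frac))
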