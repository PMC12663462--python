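"""Small 3-D convolutional network in plain numpy.

Forward/backward passes are built on ``sliding_window_view`` + ``tensordot``
with explicit gradient derivations, and parameters are updated with Adam.
Designed for desk-scale patch volumes (tens of thousands of voxels), not for
clinical 256x256x32 patches.

Tensors are channel-first: ``(C, X, Y, Z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3d", "ReLU", "AttributeBias", "ConvNet", "Adam", "masked_l1_and_grad"]


def _pad_spatial(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))


class Conv3d:
    """'Same'-padded 3-D convolution, kernel ``k`` odd, He-initialised."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        assert k % 2 == 1
        self.k = k
        scale = np.sqrt(2.0 / (c_in * k**3))
        self.W = rng.standard_normal((c_out, c_in, k, k, k)) * scale
        self.b = np.zeros(c_out)
        self._x_windows: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p = self.k // 2
        win = sliding_window_view(_pad_spatial(x, p), (self.k,) * 3, axis=(1, 2, 3))
        # win: (C_in, X, Y, Z, k, k, k)
        if train:
            self._x_windows = win
        y = np.tensordot(self.W, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
        return y + self.b[:, None, None, None]

    def backward(self, dy: np.ndarray):
        win = self._x_windows
        assert win is not None, "forward(train=True) must precede backward"
        dW = np.tensordot(dy, win, axes=([1, 2, 3], [1, 2, 3]))
        db = dy.sum(axis=(1, 2, 3))
        p = self.k // 2
        # dx: convolve dy with the spatially flipped kernel, channels swapped
        Wf = self.W[:, :, ::-1, ::-1, ::-1]
        dwin = sliding_window_view(_pad_spatial(dy, p), (self.k,) * 3, axis=(1, 2, 3))
        dx = np.tensordot(Wf, dwin, axes=([0, 2, 3, 4], [0, 4, 5, 6]))
        self._x_windows = None
        return dx, [dW, db]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray):
        return dy * self._mask, []


class AttributeBias:
    """Adds a learned linear map of a context vector as per-channel bias.

    The 16-d study-attribute encoding enters the network here, broadcast
    across the spatial dimensions of the deepest feature map.
    """

    def __init__(self, channels: int, context_dim: int, rng: np.random.Generator):
        self.A = rng.standard_normal((channels, context_dim)) * 0.01
        self._ctx: np.ndarray | None = None

    @property
    def params(self):
        return [self.A]

    def forward(self, x: np.ndarray, context: np.ndarray | None,
                train: bool = True) -> np.ndarray:
        if context is None:
            return x
        if train:
            self._ctx = context
        return x + (self.A @ context)[:, None, None, None]

    def backward(self, dy: np.ndarray):
        if self._ctx is None:
            return dy, [np.zeros_like(self.A)]
        dA = np.outer(dy.sum(axis=(1, 2, 3)), self._ctx)
        self._ctx = None
        return dy, [dA]


class ConvNet:
    """conv3-relu-conv3-relu-conv3(+attr bias)-relu-conv1 translator.

    Receptive field 7 voxels per axis.  ``context_dim`` > 0 enables the
    attribute bias at the third (deepest) convolution.
    """

    def __init__(self, c_in: int, channels: int = 12, context_dim: int = 0,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv1 = Conv3d(c_in, channels, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(channels, channels, 3, rng)
        self.relu2 = ReLU()
        self.conv3 = Conv3d(channels, channels, 3, rng)
        self.attr = AttributeBias(channels, context_dim, rng) if context_dim else None
        self.relu3 = ReLU()
        self.conv4 = Conv3d(channels, 1, 1, rng)

    @property
    def layers(self):
        layers = [self.conv1, self.relu1, self.conv2, self.relu2, self.conv3]
        if self.attr is not None:
            layers.append(self.attr)
        layers += [self.relu3, self.conv4]
        return layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, context: np.ndarray | None = None,
                train: bool = True) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.relu2.forward(h, train)
        h = self.conv3.forward(h, train)
        if self.attr is not None:
            h = self.attr.forward(h, context, train)
        h = self.relu3.forward(h, train)
        return self.conv4.forward(h, train)

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        grads: list[list[np.ndarray]] = []
        for layer in reversed(self.layers):
            dy, g = layer.backward(dy)
            grads.append(g)
        return [g for gs in reversed(grads) for g in gs]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def masked_l1_and_grad(pred: np.ndarray, target: np.ndarray,
                       mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error over masked voxels and its gradient w.r.t. pred."""
    m = mask.astype(bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty loss mask")
    diff = pred - target
    loss = float(np.abs(diff[m]).mean())
    grad = np.zeros_like(pred)
    grad[m] = np.sign(diff[m]) / n
    return loss, grad
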