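"""1-D network primitives in numpy: convolution, pooling, dense, softmax.

Two surfaces live here.  The plain functions ``conv1d`` / ``maxpool1d``
operate on single 1-D sequences and define the semantics (cross-correlation;
windowed maximum; TF-style same-padding where an even kernel pads one extra
element on the right).  The ``Layer`` classes implement the same operations
batched over ``(batch, channels, length)`` arrays with explicit backward
passes; they are the building blocks the inception networks are assembled
from.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["conv1d", "maxpool1d"]


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int]:
    """Left/right padding so output length is ceil(length / stride)."""
    out = -(-length // stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left


def conv1d(
    signal,
    kernel,
    stride: int = 1,
    padding: str = "valid",
) -> np.ndarray:
    """Cross-correlate a 1-D signal with a kernel.

    ``padding="valid"`` yields ``floor((L - K) / stride) + 1`` outputs;
    ``"same"`` zero-pads so that at stride 1 the output length equals the
    input length (even kernels pad one extra element on the right).
    """
    x = np.asarray(signal, dtype=float)
    w = np.asarray(kernel, dtype=float)
    if w.size == 0:
        raise ValueError("kernel must be nonempty")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if padding == "same":
        left, right = _same_pad(x.size, w.size, stride)
        x = np.pad(x, (left, right))
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    if x.size < w.size:
        return np.empty(0)
    windows = sliding_window_view(x, w.size)[::stride]
    return windows @ w


def maxpool1d(
    signal,
    pool_size: int,
    stride: int = 1,
    padding: str = "valid",
) -> np.ndarray:
    """Windowed maximum of a 1-D signal (same-padding pads with -inf)."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("signal must be nonempty")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if padding == "same":
        left, right = _same_pad(x.size, pool_size, stride)
        x = np.pad(x, (left, right), constant_values=-np.inf)
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    if x.size < pool_size:
        return np.empty(0)
    windows = sliding_window_view(x, pool_size)[::stride]
    return windows.max(axis=1)


# ---------------------------------------------------------------------------
# batched layers with backprop
# ---------------------------------------------------------------------------

class Layer:
    """Minimal layer protocol: forward caches, backward returns input grad."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1D(Layer):
    """Batched 1-D cross-correlation, ``(N, C_in, L) -> (N, C_out, L')``.

    Glorot-uniform initialization with fan-in ``C_in * K`` and fan-out
    ``C_out * K``.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        padding: str = "same",
        rng: np.random.Generator | None = None,
    ):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.stride, self.padding = stride, padding
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))
        self.W = rng.uniform(-limit, limit, size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "same":
            left, right = _same_pad(x.shape[2], self.kernel, self.stride)
            xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
            self._left = left
        else:
            xp = x
            self._left = 0
        self._in_shape = x.shape
        self._xp = xp
        windows = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride]
        self._windows = windows
        return np.einsum("nclk,ock->nol", windows, self.W, optimize=True) + self.b[
            :, None
        ]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW += np.einsum("nclk,nol->ock", self._windows, grad, optimize=True)
        self.db += grad.sum(axis=(0, 2))
        dxp = np.zeros_like(self._xp)
        l_out = grad.shape[2]
        for k in range(self.kernel):
            dxp[:, :, k : k + self.stride * l_out : self.stride] += np.einsum(
                "nol,oc->ncl", grad, self.W[:, :, k], optimize=True
            )
        left = self._left
        return dxp[:, :, left : left + self._in_shape[2]]

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class MaxPool1D(Layer):
    """Batched windowed maximum over the temporal axis."""

    def __init__(self, pool_size: int, stride: int, padding: str = "valid"):
        self.pool_size, self.stride, self.padding = pool_size, stride, padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "same":
            left, right = _same_pad(x.shape[2], self.pool_size, self.stride)
            xp = np.pad(x, ((0, 0), (0, 0), (left, right)), constant_values=-np.inf)
            self._left = left
        else:
            xp = x
            self._left = 0
        self._in_shape = x.shape
        self._padded_len = xp.shape[2]
        windows = sliding_window_view(xp, self.pool_size, axis=2)[
            :, :, :: self.stride
        ]
        self._argmax = windows.argmax(axis=3)
        return windows.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, l_out = grad.shape
        dxp = np.zeros((n, c, self._padded_len))
        starts = np.arange(l_out) * self.stride
        idx = starts[None, None, :] + self._argmax
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dxp, (ni, ci, idx), grad)
        left = self._left
        return dxp[:, :, left : left + self._in_shape[2]]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer, Glorot-uniform initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class InceptionLayer(Layer):
    """Parallel conv branches + a stride-1 max-pool branch, channel-concat.

    Every branch preserves the temporal length (same-padding), so outputs
    concatenate along channels: ``C_out = n_branches * filters + C_in``
    (the pool branch passes its channels through untouched).  Each conv
    branch is followed by a ReLU.
    """

    def __init__(
        self,
        c_in: int,
        branch_kernel_sizes: list[int],
        filters_per_branch: int,
        pool_size: int,
        rng: np.random.Generator,
    ):
        self.convs = [
            Conv1D(c_in, filters_per_branch, ks, stride=1, padding="same", rng=rng)
            for ks in branch_kernel_sizes
        ]
        self.relus = [ReLU() for _ in self.convs]
        self.pool = MaxPool1D(pool_size, stride=1, padding="same")
        self.c_in = c_in
        self.c_out = filters_per_branch * len(self.convs) + c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [r.forward(c.forward(x)) for c, r in zip(self.convs, self.relus)]
        outs.append(self.pool.forward(x))
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        parts = np.split(grad, self._splits, axis=1)
        dx = self.pool.backward(parts[-1])
        for conv, relu, g in zip(self.convs, self.relus, parts[:-1]):
            dx = dx + conv.backward(relu.backward(g))
        return dx

    def params(self) -> list[np.ndarray]:
        return [p for c in self.convs for p in c.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for c in self.convs for g in c.grads()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    probs: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = probs.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), targets] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n
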