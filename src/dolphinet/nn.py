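"""A minimal CNN engine on numpy.

Implements exactly the layers the spectrogram classifier needs — 2-D
convolution with TensorFlow-style "same" padding, 2x2 max pooling with
floor semantics, dense layers, ReLU, softmax cross-entropy and Adam — in
float32, NHWC layout. Convolutions are lowered to matrix multiplication
(im2col) so the heavy lifting runs in BLAS. Everything is seeded through
``numpy.random.Generator``, so training is bit-reproducible on a given
platform.
"""

from __future__ import annotations

import ctypes

import numpy as np

# Large numpy temporaries otherwise go through mmap/munmap on every layer,
# paying page-fault costs each training step; keep them on the heap so the
# allocator reuses them.
try:  # pragma: no cover - platform-specific tuning
    ctypes.CDLL("libc.so.6").mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
except OSError:
    pass

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "SequentialNet",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.sum(onehot * np.log(probs + 1e-12)) / n)
    grad = (probs - onehot) / n
    return loss, grad.astype(logits.dtype)


class Layer:
    """Base class: stateless layers override forward/backward only."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded 2-D convolution (cross-correlation), NHWC.

    Padding follows the TensorFlow convention for even kernel dimensions:
    ``(k - 1) // 2`` before, the remainder after, so output spatial dims
    equal input dims.

    The convolution is evaluated as a sum over the ``kh * kw`` kernel
    offsets of channel-mixing matrix products on contiguous input slices,
    which keeps all heavy operations in BLAS without materializing an
    im2col patch matrix.
    """

    def __init__(
        self, in_channels: int, out_channels: int, kernel: tuple[int, int],
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        kh, kw = kernel
        fan_in = kh * kw * in_channels
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        w = (rng.standard_normal((kh, kw, in_channels, out_channels)) * scale).astype(np.float32)
        b = np.zeros(out_channels, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._xp: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def _pad_widths(self) -> tuple[tuple[int, int], tuple[int, int]]:
        kh, kw = self.kernel
        return ((kh - 1) // 2, kh - 1 - (kh - 1) // 2), ((kw - 1) // 2, kw - 1 - (kw - 1) // 2)

    def _offset_rows(self, xp: np.ndarray, n: int, h: int, wd: int) -> np.ndarray:
        """Single-channel fast path: stack the kh*kw shifted copies as rows."""
        kh, kw = self.kernel
        rows = np.empty((kh * kw, n * h * wd), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                rows[i * kw + j] = xp[:, i : i + h, j : j + wd, 0].reshape(-1)
        return rows

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        w, b = self.params
        kh, kw = self.kernel
        (pt, pb), (pl, pr) = self._pad_widths()
        xp = np.pad(np.asarray(x, dtype=np.float32), ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        n, h, wd = x.shape[0], x.shape[1], x.shape[2]
        wm = w.reshape(kh, kw, self.in_channels, self.out_channels)
        if self.in_channels == 1:
            rows = self._offset_rows(xp, n, h, wd)
            y = rows.T @ w.reshape(kh * kw, self.out_channels)
            y += b
            if train:
                self._rows = rows
                self._in_shape = x.shape
                self._xp_shape = xp.shape
            return y.reshape(n, h, wd, self.out_channels)
        y = np.empty((n * h * wd, self.out_channels), dtype=np.float32)
        y[:] = b
        tmp = np.empty_like(y)
        for i in range(kh):
            for j in range(kw):
                a = np.ascontiguousarray(xp[:, i : i + h, j : j + wd, :])
                np.matmul(a.reshape(-1, self.in_channels), wm[i, j], out=tmp)
                y += tmp
        if train:
            self._xp = xp
            self._in_shape = x.shape
        return y.reshape(n, h, wd, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._in_shape is not None
        w, _ = self.params
        kh, kw = self.kernel
        n, h, wd = self._in_shape[0], self._in_shape[1], self._in_shape[2]
        dy_mat = np.ascontiguousarray(dy.reshape(n * h * wd, self.out_channels))
        self.grads[1][...] = dy_mat.sum(axis=0)
        (pt, _), (pl, _) = self._pad_widths()
        if self.in_channels == 1:
            np.matmul(self._rows, dy_mat, out=self.grads[0].reshape(kh * kw, self.out_channels))
            drows = w.reshape(kh * kw, self.out_channels) @ dy_mat.T
            dxp = np.zeros(self._xp_shape, dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + h, j : j + wd, 0] += drows[i * kw + j].reshape(n, h, wd)
            self._rows = None
            return dxp[:, pt : pt + h, pl : pl + wd, :]
        wm = w.reshape(kh, kw, self.in_channels, self.out_channels)
        dwm = self.grads[0].reshape(kh, kw, self.in_channels, self.out_channels)
        dxp = np.zeros_like(self._xp)
        tmp = np.empty((n * h * wd, self.in_channels), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                a = np.ascontiguousarray(self._xp[:, i : i + h, j : j + wd, :])
                np.matmul(a.reshape(-1, self.in_channels).T, dy_mat, out=dwm[i, j])
                np.matmul(dy_mat, wm[i, j].T, out=tmp)
                dxp[:, i : i + h, j : j + wd, :] += tmp.reshape(n, h, wd, self.in_channels)
        self._xp = None
        return dxp[:, pt : pt + h, pl : pl + wd, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, np.float32(0.0))
        if train:
            self._mask = np.greater(x, 0).astype(np.float32)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2D(Layer):
    """Max pooling with floor semantics (trailing odd rows/columns dropped).

    The backward pass routes the gradient to every entry equal to the window
    maximum; exact ties (common where ReLU zeroes a whole window) each
    receive the full gradient, a valid subgradient choice that keeps the
    pass branch-free.
    """

    def __init__(self, pool: tuple[int, int] = (2, 2)) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # reduce along H first (long contiguous runs), then along W
        ph, pw = self.pool
        h2, w2 = x.shape[1] // ph, x.shape[2] // pw
        xh = x[:, 0 : h2 * ph : ph]
        for i in range(1, ph):
            xh = np.maximum(xh, x[:, i : h2 * ph : ph])
        out = xh[:, :, 0 : w2 * pw : pw]
        for j in range(1, pw):
            out = np.maximum(out, xh[:, :, j : w2 * pw : pw])
        if train:
            self._x, self._xh, self._out = x, xh, out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ph, pw = self.pool
        n, h, w, c = self._x.shape
        h2, w2 = h // ph, w // pw
        dxh = np.empty_like(self._xh)
        for j in range(pw):
            window = self._xh[:, :, j : w2 * pw : pw]
            dxh[:, :, j : w2 * pw : pw] = dy * (window == self._out)
        if w2 * pw < w:
            dxh[:, :, w2 * pw :] = 0.0
        dx = np.zeros_like(self._x)
        for i in range(ph):
            window = self._x[:, i : h2 * ph : ph]
            dx[:, i : h2 * ph : ph] = dxh * (window == self._xh)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        w = (rng.standard_normal((in_features, out_features)) * scale).astype(np.float32)
        b = np.zeros(out_features, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        np.matmul(self._x.T, dy, out=self.grads[0])
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.params[0].T


class SequentialNet:
    """A plain layer stack mapping an NHWC batch to class logits."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != parameter shape {p.shape}")
            p[...] = w


class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
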