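"""Minimal CPU neural-network primitives used by the segmentation U-Net.

Implements exactly the operations the architecture needs - 2-D convolution
(same padding), ReLU, 2x2 max pooling, x2 bilinear upsampling, dropout and
the Adam optimizer - as numpy forward/backward pairs.  Convolutions use an
im2col formulation so the heavy lifting is a single BLAS matmul; gradients
with respect to inputs are folded back with nine shifted views.

Everything is float32 and batch-first (N, C, H, W).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "BilinearUp2", "Dropout", "Adam",
           "kaiming_uniform"]


def kaiming_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Kaiming-uniform draw for ReLU networks: U(-b, b) with b = sqrt(6/fan_in)."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d:
    """k x k convolution with same padding (k odd), stride 1.

    Weights are Kaiming-uniform initialized; biases start at zero.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        self.w = kaiming_uniform(rng, (cout, cin, k, k), fan_in)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        if k == 1:
            xr = x.transpose(0, 2, 3, 1).reshape(-1, c)
            out = xr @ self.w.reshape(self.cout, c).T + self.b
            if train:
                self._cache = (xr, (n, h, w))
            return np.ascontiguousarray(
                out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (N, C, H, W, k, k) -> cols: (N*H*W, C*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k)
        wmat = self.w.reshape(self.cout, c * k * k)
        out = cols @ wmat.T + self.b
        if train:
            self._cache = (cols, (n, h, w))
        return np.ascontiguousarray(out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, h, w) = self._cache
        k, c = self.k, self.cin
        dr = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.gb[:] = dr.sum(axis=0)
        self.gw[:] = (dr.T @ cols).reshape(self.w.shape)
        if k == 1:
            dx = dr @ self.w.reshape(self.cout, c)
            return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))
        # input gradient of a same-padded conv = full conv of dout with the
        # channel-transposed, 180-degree-rotated kernel; reuse im2col + gemm
        p = k // 2
        doutp = np.pad(dout.astype(self.w.dtype, copy=False),
                       ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(doutp, (k, k), axis=(2, 3))
        cols2 = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, self.cout * k * k)
        wflip = np.ascontiguousarray(
            self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)).reshape(c, self.cout * k * k)
        dx = (cols2 @ wflip.T).reshape(n, h, w, c)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, np.float32(0.0))
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, np.float32(0.0))


class MaxPool2:
    """2x2 max pooling with stride 2; requires even spatial dimensions."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dimensions must be even for 2x2 pooling")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D linear-interpolation matrix for a x2 (or arbitrary) resize.

    Output sample i reads continuous source coordinate (i + 0.5) * n_in /
    n_out - 0.5, with edge clamping (half-pixel-centres convention).
    """
    m = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    j0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    j1 = np.clip(j0 + 1, 0, n_in - 1)
    t = np.clip(src - np.floor(src), 0.0, 1.0)
    t = np.where(j1 == j0, 0.0, t)
    m[np.arange(n_out), j0] += (1.0 - t)
    m[np.arange(n_out), j1] += t
    return m


class BilinearUp2:
    """x2 bilinear upsampling via separable interpolation matrices."""

    def __init__(self):
        self._mats: dict[int, np.ndarray] = {}
        self._shape = None

    def params(self):
        return []

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _interp_matrix(2 * n_in, n_in)
        return self._mats[n_in]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        mh, mw = self._mat(h), self._mat(w)
        if train:
            self._shape = (h, w)
        y = np.matmul(mh, x)            # (N, C, 2H, W)
        return np.matmul(y, mw.T)       # (N, C, 2H, 2W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._shape
        mh, mw = self._mat(h), self._mat(w)
        return np.matmul(np.matmul(mh.T, dout), mw)


class Dropout:
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, prob: float):
        if not 0 <= prob < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.prob = prob
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.prob == 0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.prob
        self._mask = (rng.uniform(size=x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Adam:
    """Adam optimizer over a list of (param, grad) array pairs."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
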