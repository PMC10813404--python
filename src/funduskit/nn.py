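"""Minimal neural-network layers with explicit forward/backward passes.

A small, self-contained layer library (conv, ReLU, 2x2 max-pool, nearest
upsampling, the SCM attention block, Adam) sufficient to build and train
the vessel-segmentation network on a CPU.  Layers operate on single
samples shaped ``(C, H, W)``; gradients are accumulated into ``.grads``
and consumed by :class:`Adam`.

Every backward pass is validated against central-difference numerical
gradients in the test suite.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import convolve as _nd_convolve
from scipy.ndimage import correlate as _nd_correlate
from scipy.signal import correlate2d as _sig_corr2d

from .attention import AttentionConfig, AttentionWeights, sigmoid

__all__ = [
    "Layer", "Conv2d", "ReLU", "MaxPool2", "Upsample2", "InstanceNorm",
    "SCMBlock", "Adam",
]


class Layer:
    """Base layer: ``params``/``grads`` are dicts of named arrays."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C, H, W) -> (C*k*k, H*W) column matrix with zero padding."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C, H, W, k, k)
    return win.transpose(0, 3, 4, 1, 2).reshape(c * k * k, h * w)


def _col2im(cols: np.ndarray, shape: Tuple[int, int, int], k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add)."""
    c, h, w = shape
    xp = np.zeros((c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(c, k, k, h, w)
    for di in range(k):
        for dj in range(k):
            xp[:, di:di + h, dj:dj + w] += cols[:, di, dj]
    return xp[:, pad:pad + h, pad:pad + w]


class Conv2d(Layer):
    """Zero-padded, size-preserving convolution (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        bound = np.sqrt(6.0 / fan_in)
        self.params["W"] = rng.uniform(-bound, bound, size=(c_out, c_in, k, k))
        self.params["b"] = np.zeros(c_out)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.k // 2)
        w = self.params["W"].reshape(self.c_out, -1)
        y = w @ self._cols + self.params["b"][:, None]
        return y.reshape(self.c_out, x.shape[1], x.shape[2])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy_mat = dy.reshape(self.c_out, -1)
        self.grads["W"] += (dy_mat @ self._cols.T).reshape(self.params["W"].shape)
        self.grads["b"] += dy_mat.sum(axis=1)
        dcols = self.params["W"].reshape(self.c_out, -1).T @ dy_mat
        return _col2im(dcols, self._x_shape, self.k, self.k // 2)

    @property
    def n_params(self) -> int:
        return self.params["W"].size + self.params["b"].size


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 needs even spatial dimensions")
        xr = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
        flat = xr.reshape(c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=3)
        self._x_shape = x.shape
        return flat.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._x_shape
        dflat = np.zeros((c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=3)
        return dflat.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4) \
                    .reshape(c, h, w)


class InstanceNorm(Layer):
    """Per-channel spatial standardization (no learned affine).

    Stabilizes activation scales so the small nets train in few epochs.
    """

    eps = 1e-5

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._std = np.sqrt(x.var(axis=(1, 2), keepdims=True) + self.eps)
        self._xh = (x - x.mean(axis=(1, 2), keepdims=True)) / self._std
        return self._xh

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy - dy.mean(axis=(1, 2), keepdims=True)
                - self._xh * (dy * self._xh).mean(axis=(1, 2), keepdims=True)
                ) / self._std


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = dy.shape
        return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class SCMBlock(Layer):
    """Trainable SCM attention block (sequential arrangement).

    Forward matches :func:`funduskit.attention.scm_block`; the backward
    pass propagates gradients through both gates (including the pyramid
    pooling and the shared two-layer network) and accumulates gradients
    for ``W0``, ``W1`` and the 9x9 spatial kernel.
    """

    def __init__(self, channels: int, cfg: AttentionConfig, rng: np.random.Generator) -> None:
        super().__init__()
        if cfg.arrangement != "sequential":
            raise ValueError("the trainable block implements the sequential arrangement")
        from .attention import init_attention_weights

        self.cfg = cfg
        self.channels = channels
        w = init_attention_weights(channels, cfg, rng)
        self.params["W0"] = w.W0
        self.params["W1"] = w.W1
        self.params["K"] = w.conv_kernel
        self.zero_grad()

    # -- pyramid pooling with caches -----------------------------------
    def _pool(self, M: np.ndarray):
        C, H, W = M.shape
        bins = []
        maxs, avgs = [], []
        for L in self.cfg.pyramid_levels:
            re_ = (np.arange(L + 1) * H) // L
            ce_ = (np.arange(L + 1) * W) // L
            for i in range(L):
                for j in range(L):
                    rs, rend, cs, cend = re_[i], re_[i + 1], ce_[j], ce_[j + 1]
                    patch = M[:, rs:rend, cs:cend].reshape(C, -1)
                    arg = patch.argmax(axis=1)
                    maxs.append(patch[np.arange(C), arg])
                    avgs.append(patch.mean(axis=1))
                    bins.append((rs, rend, cs, cend, arg))
        return np.stack(maxs, 1), np.stack(avgs, 1), bins

    def _act(self, x):
        if self.cfg.activation == "relu":
            return np.maximum(x, 0.0)
        return np.exp(-(x ** 2))

    def _act_grad(self, pre, dh):
        if self.cfg.activation == "relu":
            return dh * (pre > 0)
        return dh * (-2.0 * pre * np.exp(-(pre ** 2)))

    def forward(self, M: np.ndarray) -> np.ndarray:
        self._M = M
        C, H, W = M.shape
        dmax2d, davg2d, self._bins = self._pool(M)
        self._dmax, self._davg = dmax2d.ravel(), davg2d.ravel()
        W0, W1 = self.params["W0"], self.params["W1"]
        self._pre_m = W0 @ self._dmax
        self._pre_a = W0 @ self._davg
        self._h_m = self._act(self._pre_m)
        self._h_a = self._act(self._pre_a)
        z = W1 @ (self._h_m + self._h_a)
        self._DC = sigmoid(z)
        self._M1 = self._DC[:, None, None] * M

        self._avgmap = self._M1.mean(axis=0)
        self._amax = self._M1.argmax(axis=0)
        self._maxmap = np.take_along_axis(self._M1, self._amax[None], axis=0)[0]
        K = self.params["K"]
        u = _nd_correlate(self._avgmap, K[0], mode="constant", cval=0.0) \
            + _nd_correlate(self._maxmap, K[1], mode="constant", cval=0.0)
        self._DS = sigmoid(u)
        return self._DS[None] * self._M1

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, H, W = self._M.shape
        k = self.cfg.spatial_kernel
        pad = k // 2
        # spatial gate
        dDS = (dy * self._M1).sum(axis=0)
        dM1 = self._DS[None] * dy
        dU = dDS * self._DS * (1.0 - self._DS)
        for j, plane in enumerate((self._avgmap, self._maxmap)):
            pp = np.pad(plane, pad)
            self.grads["K"][j] += _sig_corr2d(pp, dU, mode="valid")
        davgmap = _nd_convolve(dU, self.params["K"][0], mode="constant", cval=0.0)
        dmaxmap = _nd_convolve(dU, self.params["K"][1], mode="constant", cval=0.0)
        dM1 += davgmap[None] / C
        dmax_routed = np.zeros_like(dM1)
        np.put_along_axis(dmax_routed, self._amax[None], dmaxmap[None], axis=0)
        dM1 += dmax_routed
        # channel gate
        dDC = (dM1 * self._M).sum(axis=(1, 2))
        dM = self._DC[:, None, None] * dM1
        dz = dDC * self._DC * (1.0 - self._DC)
        W0, W1 = self.params["W0"], self.params["W1"]
        self.grads["W1"] += np.outer(dz, self._h_m + self._h_a)
        dh = W1.T @ dz
        dpre_m = self._act_grad(self._pre_m, dh)
        dpre_a = self._act_grad(self._pre_a, dh)
        self.grads["W0"] += np.outer(dpre_m, self._dmax) + np.outer(dpre_a, self._davg)
        dd_max = (W0.T @ dpre_m).reshape(C, -1)
        dd_avg = (W0.T @ dpre_a).reshape(C, -1)
        for b, (rs, rend, cs, cend, arg) in enumerate(self._bins):
            patch = dM[:, rs:rend, cs:cend].reshape(C, -1)
            patch += dd_avg[:, b, None] / patch.shape[1]
            patch[np.arange(C), arg] += dd_max[:, b]
            dM[:, rs:rend, cs:cend] = patch.reshape(C, rend - rs, cend - cs)
        return dM

    def as_weights(self) -> AttentionWeights:
        return AttentionWeights(W0=self.params["W0"], W1=self.params["W1"],
                                conv_kernel=self.params["K"])


class Adam:
    """Adam over the parameter dicts of a list of layers."""

    def __init__(self, layers: List[Layer], lr: float = 1e-2,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = b1 * self.m[i][k] + (1 - b1) * g
                self.v[i][k] = b2 * self.v[i][k] + (1 - b2) * g * g
                mhat = self.m[i][k] / (1 - b1 ** self.t)
                vhat = self.v[i][k] / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()
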