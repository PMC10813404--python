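"""Spatial convolution attention module (SCM).

A convolutional-block-attention-style gate pair for feature maps
``M`` of shape ``(C, H, W)``:

* **Channel attention** answers *what* to emphasize.  The spatial plane of
  each channel is summarized by spatial-pyramid pooling (multi-level
  ``LxL`` grids whose bin count is independent of H and W), separately
  with average- and max-pooling.  Both descriptors pass through a shared
  two-layer network ``W1 . act(W0 . d)`` (hidden size ``C/e`` for
  reduction ratio ``e``), the two outputs are summed element-wise and
  squashed: ``DC = sigmoid(W1 act(W0 d_avg) + W1 act(W0 d_max))``,
  one gate per channel.
* **Spatial attention** answers *where*.  The channel axis is reduced by
  mean- and max-pooling to a 2-plane map, convolved with a single 9x9
  kernel (zero-padded, size-preserving) and squashed:
  ``DS = sigmoid(K * [mean_c M; max_c M])``, one gate per pixel.

The default arrangement is sequential — ``M' = DC(M) (x) M`` then
``M'' = DS(M') (x) M'`` — with a parallel variant
``M'' = (DC(M) (x) M + DS(M) (x) M)/2`` available.  All gates lie in
(0, 1), so the block can only attenuate magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import correlate as _nd_correlate

__all__ = [
    "AttentionConfig",
    "AttentionWeights",
    "init_attention_weights",
    "spatial_pyramid_pool",
    "pyramid_descriptor_length",
    "channel_attention",
    "spatial_attention",
    "scm_block",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class AttentionConfig:
    """Hyper-parameters of the SCM block."""

    reduction_ratio: int = 4
    pyramid_levels: Tuple[int, ...] = (1, 2, 4)
    spatial_kernel: int = 9
    arrangement: str = "sequential"       # or "parallel"
    activation: str = "relu"              # or "rbf" (Gaussian unit exp(-x^2))

    def __post_init__(self) -> None:
        if self.spatial_kernel % 2 != 1 or self.spatial_kernel < 1:
            raise ValueError("spatial_kernel must be a positive odd integer")
        if self.arrangement not in ("sequential", "parallel"):
            raise ValueError("arrangement must be 'sequential' or 'parallel'")
        if self.activation not in ("relu", "rbf"):
            raise ValueError("activation must be 'relu' or 'rbf'")
        if any(l < 1 for l in self.pyramid_levels):
            raise ValueError("pyramid levels must be >= 1")

    def hidden_size(self, channels: int) -> int:
        return max(1, channels // self.reduction_ratio)

    @property
    def bins(self) -> int:
        """Bins per pooling branch: sum of L^2 over the pyramid levels."""
        return int(sum(l * l for l in self.pyramid_levels))


@dataclass
class AttentionWeights:
    """Learnable state of one SCM block.

    ``W0``/``W1`` are shared between the average- and max-pooled
    descriptors; ``conv_kernel`` has shape ``(2, k, k)`` for the two
    channel-pooled input maps.
    """

    W0: np.ndarray
    W1: np.ndarray
    conv_kernel: np.ndarray


def init_attention_weights(channels: int, cfg: AttentionConfig,
                           rng: np.random.Generator) -> AttentionWeights:
    """He-uniform initialization of the block's weights."""
    hidden = cfg.hidden_size(channels)
    d_in = channels * cfg.bins
    k = cfg.spatial_kernel

    def he(shape, fan_in):
        bound = np.sqrt(6.0 / fan_in)
        return rng.uniform(-bound, bound, size=shape)

    return AttentionWeights(
        W0=he((hidden, d_in), d_in),
        W1=he((channels, hidden), hidden),
        conv_kernel=he((2, k, k), 2 * k * k),
    )


# ----------------------------------------------------------------------


def _bin_edges(n: int, level: int) -> np.ndarray:
    """Half-open bin boundaries floor(i*n/L) for i = 0..L."""
    return (np.arange(level + 1) * n) // level


def spatial_pyramid_pool(M: np.ndarray, levels: Sequence[int]) -> np.ndarray:
    """Fixed-length per-channel descriptor via multi-level grid pooling.

    For each level ``L`` the ``HxW`` plane is split into an ``LxL`` grid
    with half-open boundaries ``floor(i*H/L) .. floor((i+1)*H/L)``; each
    bin contributes its max and its mean.  The output has shape
    ``(C, 2 * sum(L^2))`` regardless of H and W.

    Raises ``ValueError`` when a level exceeds ``min(H, W)`` (bins would
    be empty).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 3:
        raise ValueError("expected a (C, H, W) feature map")
    C, H, W = M.shape
    if any(l > min(H, W) for l in levels):
        raise ValueError("pyramid level exceeds the spatial extent (empty bins)")
    maxs: List[np.ndarray] = []
    avgs: List[np.ndarray] = []
    for L in levels:
        re_, ce_ = _bin_edges(H, L), _bin_edges(W, L)
        for i in range(L):
            for j in range(L):
                patch = M[:, re_[i]:re_[i + 1], ce_[j]:ce_[j + 1]]
                maxs.append(patch.max(axis=(1, 2)))
                avgs.append(patch.mean(axis=(1, 2)))
    return np.concatenate(
        [np.stack(maxs, axis=1), np.stack(avgs, axis=1)], axis=1
    )


def pyramid_descriptor_length(levels: Sequence[int]) -> int:
    """Per-channel descriptor length ``2 * sum(L^2)``."""
    return 2 * int(sum(l * l for l in levels))


def _activation(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    return np.exp(-(x ** 2))  # Gaussian RBF unit


def channel_attention(M: np.ndarray, w: AttentionWeights,
                      cfg: AttentionConfig) -> np.ndarray:
    """Per-channel gate ``DC`` of shape ``(C,)`` with values in (0, 1).

    The max- and average-pooled pyramid descriptors each pass through the
    shared two-layer network; the outputs are summed element-wise before
    the sigmoid.
    """
    M = np.asarray(M, dtype=float)
    C = M.shape[0]
    desc = spatial_pyramid_pool(M, cfg.pyramid_levels)   # (C, 2B)
    B = cfg.bins
    d_max = desc[:, :B].ravel()
    d_avg = desc[:, B:].ravel()
    if w.W0.shape[1] != C * B or w.W1.shape[0] != C:
        raise ValueError("attention weight shapes inconsistent with the input")
    z = w.W1 @ _activation(w.W0 @ d_max, cfg.activation) \
        + w.W1 @ _activation(w.W0 @ d_avg, cfg.activation)
    return sigmoid(z)


def channel_pool(M: np.ndarray) -> np.ndarray:
    """Stack the channel-axis mean and max maps: ``(2, H, W)``."""
    M = np.asarray(M, dtype=float)
    return np.stack([M.mean(axis=0), M.max(axis=0)], axis=0)


def spatial_attention(M: np.ndarray, w: AttentionWeights) -> np.ndarray:
    """Per-pixel gate ``DS`` of shape ``(H, W)`` with values in (0, 1).

    Convolves the 2-plane channel-pooled map with the 9x9 kernel
    (zero-padded, same size) and applies the sigmoid.
    """
    pooled = channel_pool(M)
    u = np.zeros(pooled.shape[1:])
    for j in range(pooled.shape[0]):
        u += _nd_correlate(pooled[j], w.conv_kernel[j], mode="constant", cval=0.0)
    return sigmoid(u)


def scm_block(M: np.ndarray, w: AttentionWeights, cfg: AttentionConfig) -> np.ndarray:
    """Apply the full attention block; output shape equals input shape."""
    M = np.asarray(M, dtype=float)
    if cfg.arrangement == "sequential":
        m1 = channel_attention(M, w, cfg)[:, None, None] * M
        return spatial_attention(m1, w)[None, :, :] * m1
    dc = channel_attention(M, w, cfg)[:, None, None] * M
    ds = spatial_attention(M, w)[None, :, :] * M
    return 0.5 * (dc + ds)
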