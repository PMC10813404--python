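"""Fundus pre-processing chain.

Low, uneven contrast between vessels and background is the main obstacle
to segmenting retinal vasculature, so the raw RGB image is enhanced
before segmentation:

1. **Gaussian contrast gain** — per channel, a Gaussian response
   ``G = 1/(2*pi*s) * exp(-(o - m)^2 / s)`` (with ``m``/``s`` the channel
   mean and standard deviation, denominators kept as ``2*pi*s`` and ``s``)
   drives a multiplicative gain ``1 + f/g`` with ``g = 1 + G/lam``
   (``lam`` = 0.2 by default) and ``f`` an image-level probability-weighted
   darkness score.  ``g`` is large where a pixel sits near the channel
   mean, so the gain selectively amplifies pixels far from the mean —
   lesions and vessels — while leaving the background nearly untouched.
2. **HSV transform** on chromaticities ``beta_r = r/(r+g+b)`` etc., with
   the hue from the arccos form, saturation ``(max-min)/max`` and value
   ``max`` of the chromaticities.
3. **Doane normalization** — each plane is mapped through
   ``psi = 1 + log2(plane) + log2(|k|)`` where ``k`` is the plane's
   skewness, then min-max rescaled to [0, 1].
4. **Channel selection** — per pixel, the empirical histogram probability
   of each plane's intensity is compared with the mean probability of the
   three planes; the first plane in the cascade h, s, v whose probability
   falls below the mean is selected (v accepts on <=, so the cascade is
   total).

The whole chain is deterministic and every intermediate raster stays in
[0, 1] (or is rescaled there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "DegenerateChannelError",
    "ChannelStats",
    "ContrastGain",
    "HSVImage",
    "DoaneRecord",
    "ChannelSelection",
    "EnhancedImage",
    "gaussian_response",
    "contrast_gain",
    "apply_gain",
    "rgb_to_hsv_paper",
    "doane_normalize",
    "channel_probability",
    "select_channel",
    "preprocess",
]

_EPS = 1e-12


class DegenerateChannelError(ValueError):
    """Raised when a channel is constant (zero standard deviation)."""


@dataclass
class ChannelStats:
    """First two moments of a channel plus its per-pixel Gaussian response."""

    m: float
    s: float
    n: int
    G: np.ndarray


@dataclass
class ContrastGain:
    f: float
    g: np.ndarray       # scaling raster 1 + G/lam
    lam: float
    gain: np.ndarray    # per-pixel raster 1 + f/g
    F: Optional[float] = None  # "unique value" marker: recorded, unused


@dataclass
class HSVImage:
    beta_h: np.ndarray
    beta_s: np.ndarray
    beta_v: np.ndarray
    beta_r: np.ndarray
    beta_g: np.ndarray
    beta_b: np.ndarray
    hue_valid: np.ndarray  # False where the hue is undefined (achromatic)


@dataclass
class DoaneRecord:
    psi_h: np.ndarray
    skew: float


@dataclass
class ChannelSelection:
    selected_plane: np.ndarray
    choice_map: np.ndarray  # per-pixel tag in {'h','s','v'}
    mp: np.ndarray          # mean probability threshold per pixel


@dataclass
class EnhancedImage:
    plane: np.ndarray
    choice_map: np.ndarray
    provenance: Dict[str, object] = field(default_factory=dict)


# ----------------------------------------------------------------------


def _check_plane(plane: np.ndarray) -> np.ndarray:
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ValueError("empty raster")
    return plane


def gaussian_response(channel: np.ndarray, textbook: bool = False) -> ChannelStats:
    """Per-pixel Gaussian response of a channel around its own mean.

    Uses population moments ``m = mean(o)``, ``s = sqrt(mean(o^2) - m^2)``
    and ``G = 1/(2*pi*s) * exp(-(o - m)^2 / s)``.  With ``textbook=True``
    the standard density ``1/sqrt(2*pi*s^2) * exp(-(o-m)^2 / (2 s^2))``
    is used instead.

    Raises :class:`DegenerateChannelError` for a constant channel.
    """
    o = _check_plane(channel)
    n = o.size
    m = float(o.mean())
    s = float(np.sqrt(max(np.mean(o ** 2) - m ** 2, 0.0)))
    if s == 0.0:
        raise DegenerateChannelError("constant channel: s = 0")
    if textbook:
        G = 1.0 / np.sqrt(2 * np.pi * s ** 2) * np.exp(-((o - m) ** 2) / (2 * s ** 2))
    else:
        G = 1.0 / (2 * np.pi * s) * np.exp(-((o - m) ** 2) / s)
    return ChannelStats(m=m, s=s, n=n, G=G)


def channel_probability(plane: np.ndarray) -> np.ndarray:
    """Empirical histogram probability of each pixel's own intensity.

    Intensities are quantized to 256 levels; the probability of a pixel is
    the fraction of pixels in the plane sharing its level, so the unique
    levels' probabilities sum to 1.
    """
    p = _check_plane(plane)
    q = np.clip(np.round(p * 255.0), 0, 255).astype(np.int64)
    counts = np.bincount(q.ravel(), minlength=256)
    return counts[q] / p.size


def contrast_gain(channel: np.ndarray, stats: ChannelStats, lam: float = 0.2) -> ContrastGain:
    """Per-pixel contrast gain ``1 + f/g``.

    ``f = (1/n) * sum_xy p_xy * (1 - o_xy)`` is a probability-weighted
    darkness score of the whole channel (a scalar in [0, 1]) and
    ``g = 1 + G/lam`` a per-pixel scaling raster, large near the channel
    mean.  Pixels far from the mean therefore receive the largest gain.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    o = _check_plane(channel)
    p = channel_probability(o)
    f = float(np.sum(p * (1.0 - o)) / o.size)
    g = 1.0 + stats.G / lam
    gain = 1.0 + f / g
    return ContrastGain(f=f, g=g, lam=lam, gain=gain)


def apply_gain(channel: np.ndarray, cg: ContrastGain) -> np.ndarray:
    """Multiply the channel by the per-pixel gain and clip to [0, 1]."""
    return np.clip(np.asarray(channel, dtype=float) * cg.gain, 0.0, 1.0)


def rgb_to_hsv_paper(image: np.ndarray) -> HSVImage:
    """HSV planes computed from RGB chromaticities.

    Chromaticities ``beta_c = c / (r+g+b)`` (0 where the pixel is black);
    hue via ``arccos`` in radians [0, pi], set to the sentinel 0 where
    undefined (achromatic pixels, flagged in ``hue_valid``); saturation
    ``(max - min)/max`` with 0 where max = 0; value = chromaticity max.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    total = r + g + b
    safe = np.where(total > 0, total, 1.0)
    br, bg, bb = r / safe, g / safe, b / safe

    num = 0.5 * (2 * br - bg - bb)
    den_sq = (br - bg) ** 2 + (br - bb) * (bg - bb)
    valid = den_sq > _EPS
    den = np.sqrt(np.where(valid, den_sq, 1.0))
    arg = np.clip(np.where(valid, num / den, 0.0), -1.0, 1.0)
    beta_h = np.where(valid, np.arccos(arg), 0.0)

    mx = np.maximum(np.maximum(br, bg), bb)
    mn = np.minimum(np.minimum(br, bg), bb)
    beta_s = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return HSVImage(beta_h=beta_h, beta_s=beta_s, beta_v=mx,
                    beta_r=br, beta_g=bg, beta_b=bb, hue_valid=valid)


def skewness(plane: np.ndarray) -> float:
    """Population skewness ``E[(x - m)^3] / s^3`` (0 for a constant plane)."""
    x = _check_plane(plane).ravel()
    m = x.mean()
    s = x.std()
    if s == 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / s ** 3)


def doane_normalize(plane: np.ndarray) -> DoaneRecord:
    """Doane-style logarithmic normalization of a plane.

    ``psi = 1 + log2(plane) + log2(|k|)`` with ``k`` the plane's skewness;
    log arguments are clamped below at machine epsilon so zeros and
    symmetric planes stay finite.  The result is min-max rescaled to
    [0, 1] (a constant plane maps to 0).
    """
    p = _check_plane(plane)
    k = skewness(p)
    psi = 1.0 + np.log2(np.maximum(p, _EPS)) + np.log2(max(abs(k), _EPS))
    lo, hi = float(psi.min()), float(psi.max())
    if hi > lo:
        psi = (psi - lo) / (hi - lo)
    else:
        psi = np.zeros_like(psi)
    return DoaneRecord(psi_h=psi, skew=k)


def select_channel(hsv: HSVImage) -> ChannelSelection:
    """Pick, per pixel, the plane whose intensity is rarest.

    Each plane's per-pixel histogram probability is compared with the
    pixel's mean probability over the three planes; the cascade h, s, v
    selects the first plane with probability strictly below the mean,
    and v accepts on <= (at least one of three values is <= their mean,
    so every pixel is tagged).
    """
    planes = {"h": hsv.beta_h, "s": hsv.beta_s, "v": hsv.beta_v}
    probs = {k: channel_probability(v) for k, v in planes.items()}
    mp = (probs["h"] + probs["s"] + probs["v"]) / 3.0

    choice = np.full(hsv.beta_v.shape, "v", dtype="<U1")
    selected = planes["v"].copy()
    take_s = probs["s"] < mp
    choice[take_s] = "s"
    selected[take_s] = planes["s"][take_s]
    take_h = probs["h"] < mp
    choice[take_h] = "h"
    selected[take_h] = planes["h"][take_h]
    return ChannelSelection(selected_plane=selected, choice_map=choice, mp=mp)


def preprocess(
    image: np.ndarray,
    lam: float = 0.2,
    resize: Optional[Tuple[int, int]] = None,
    textbook_gaussian: bool = False,
) -> EnhancedImage:
    """Full enhancement chain: gain -> HSV -> Doane -> channel selection.

    Parameters
    ----------
    image
        RGB raster in [0, 1].
    lam
        Sampling parameter of the contrast gain (default 0.2).
    resize
        Optional ``(height, width)`` working size, e.g. ``(250, 300)``;
        ``None`` keeps the native size.
    textbook_gaussian
        Use the standard normal density in the Gaussian response.

    A constant channel cannot support the Gaussian gain; it is passed
    through unchanged with a warning.  The output plane is in [0, 1] and
    carries the per-channel provenance (m, s, f, lam) plus the per-pixel
    choice map.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if resize is not None:
        img = _sk_resize(img, resize, order=1, anti_aliasing=True)
    img = np.clip(img, 0.0, 1.0)

    prov: Dict[str, object] = {"lam": lam, "channels": {}}
    gained = np.empty_like(img)
    for i, name in enumerate(("r", "g", "b")):
        ch = img[..., i]
        try:
            stats = gaussian_response(ch, textbook=textbook_gaussian)
            cg = contrast_gain(ch, stats, lam=lam)
            gained[..., i] = apply_gain(ch, cg)
            prov["channels"][name] = {"m": stats.m, "s": stats.s, "f": cg.f}
        except DegenerateChannelError:
            warnings.warn(f"channel {name!r} is constant; identity gain applied",
                          RuntimeWarning)
            gained[..., i] = ch
            prov["channels"][name] = {"m": float(ch.mean()), "s": 0.0, "f": 0.0}

    hsv = rgb_to_hsv_paper(gained)
    planes = HSVImage(
        beta_h=doane_normalize(hsv.beta_h).psi_h,
        beta_s=doane_normalize(hsv.beta_s).psi_h,
        beta_v=doane_normalize(hsv.beta_v).psi_h,
        beta_r=hsv.beta_r, beta_g=hsv.beta_g, beta_b=hsv.beta_b,
        hue_valid=hsv.hue_valid,
    )
    sel = select_channel(planes)
    return EnhancedImage(plane=sel.selected_plane, choice_map=sel.choice_map,
                         provenance=prov)
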