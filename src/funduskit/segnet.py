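"""Vessel segmentation: attention U-net, training loop, optic-disc removal.

The segmenter is a shallow U-shaped encoder--decoder.  Each encoder stage
is ``conv 3x3 -> ReLU -> SCM attention block``, followed by 2x2
max-pooling; the decoder mirrors the encoder with nearest-neighbour
upsampling and skip connections, and a 1x1 convolution head produces a
per-pixel vessel logit.  The convolutional layers run once over the full
image, and the spatial-pyramid-pooled bottleneck yields a fixed-length
descriptor whatever the input size, so the same weights apply to images
of any (even moderately sized) resolution.

Training minimizes Dice + binary cross-entropy with Adam; everything is
deterministic under a fixed seed.

The optic disc — the bright round entry region of the vessels, whose
brightness confounds vessel statistics — is located by k-means clustering
on (intensity, blurred intensity) pixel features: the brightest cluster's
largest connected component, morphologically closed, is taken as the disc
and removed from the working image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, warp
from sklearn.cluster import KMeans

from .attention import AttentionConfig, pyramid_descriptor_length, spatial_pyramid_pool
from .nn import (Adam, Conv2d, InstanceNorm, Layer, MaxPool2, ReLU,
                 SCMBlock, Upsample2)

__all__ = [
    "SegNetConfig", "SegNet", "DiscRegion",
    "augment", "build_network", "train", "segment", "remove_optic_disc",
    "dice_coefficient",
]


@dataclass(frozen=True)
class SegNetConfig:
    """Architecture and training hyper-parameters of the segmenter."""

    depth: int = 3
    base_channels: int = 16
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    threshold: float = 0.5
    epochs: int = 30
    batch_size: int = 1
    learning_rate: float = 1e-2
    dice_weight: float = 2.0
    pos_weight: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie strictly between 0 and 1")


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-7) -> float:
    """Soft/binary Dice overlap ``2|P∩T| / (|P|+|T|)``."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    return float((2.0 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps))


class SegNet:
    """U-shaped vessel segmenter with an SCM block after each encoder stage."""

    def __init__(self, cfg: SegNetConfig) -> None:
        self.cfg = cfg
        self.trained = False
        rng = np.random.default_rng(cfg.seed)
        att = cfg.attention
        d, base = cfg.depth, cfg.base_channels

        self.enc_convs: List[Conv2d] = []
        self.enc_norms: List[InstanceNorm] = []
        self.enc_relus: List[ReLU] = []
        self.enc_scms: List[SCMBlock] = []
        self.pools: List[MaxPool2] = []
        c_in = 1
        chans = []
        for i in range(d):
            c_out = base * (2 ** i)
            self.enc_convs.append(Conv2d(c_in, c_out, 3, rng))
            self.enc_norms.append(InstanceNorm())
            self.enc_relus.append(ReLU())
            self.enc_scms.append(SCMBlock(c_out, att, rng))
            self.pools.append(MaxPool2())
            chans.append(c_out)
            c_in = c_out
        self.bott_conv = Conv2d(c_in, c_in, 3, rng)
        self.bott_norm = InstanceNorm()
        self.bott_relu = ReLU()

        self.ups: List[Upsample2] = []
        self.dec_convs: List[Conv2d] = []
        self.dec_norms: List[InstanceNorm] = []
        self.dec_relus: List[ReLU] = []
        c_cur = c_in
        for i in reversed(range(d)):
            c_out = max(base, chans[i] // 2) if i > 0 else base
            self.ups.append(Upsample2())
            self.dec_convs.append(Conv2d(c_cur + chans[i], c_out, 3, rng))
            self.dec_norms.append(InstanceNorm())
            self.dec_relus.append(ReLU())
            c_cur = c_out
        self.head = Conv2d(c_cur, 1, 1, rng)

    # ------------------------------------------------------------------
    def layers(self) -> List[Layer]:
        out: List[Layer] = []
        out.extend(self.enc_convs)
        out.extend(self.enc_scms)
        out.append(self.bott_conv)
        out.extend(self.dec_convs)
        out.append(self.head)
        return out

    @property
    def n_params(self) -> int:
        return sum(int(sum(p.size for p in l.params.values())) for l in self.layers())

    def _pad(self, x: np.ndarray) -> Tuple[np.ndarray, Tuple[int, int]]:
        mult = 2 ** self.cfg.depth
        h, w = x.shape[-2:]
        ph = (-h) % mult
        pw = (-w) % mult
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (h, w)

    def forward_logits(self, plane: np.ndarray) -> np.ndarray:
        """Logit raster for a single-plane input in [0, 1]."""
        x = np.asarray(plane, dtype=float)
        if x.ndim == 2:
            x = x[None]
        x, (h, w) = self._pad(x)
        skips = []
        for conv, norm, relu, scm, pool in zip(self.enc_convs, self.enc_norms,
                                               self.enc_relus, self.enc_scms,
                                               self.pools):
            x = scm.forward(relu.forward(norm.forward(conv.forward(x))))
            skips.append(x)
            x = pool.forward(x)
        x = self.bott_relu.forward(self.bott_norm.forward(self.bott_conv.forward(x)))
        self._bottleneck = x
        self._skip_shapes = [s.shape for s in skips]
        for up, conv, norm, relu, skip in zip(self.ups, self.dec_convs,
                                              self.dec_norms, self.dec_relus,
                                              reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([x, skip], axis=0)
            x = relu.forward(norm.forward(conv.forward(x)))
        logits = self.head.forward(x)[0]
        return logits[:h, :w]

    def backward(self, dlogits: np.ndarray) -> None:
        mult = 2 ** self.cfg.depth
        h, w = dlogits.shape
        ph, pw = (-h) % mult, (-w) % mult
        d = np.pad(dlogits, ((0, ph), (0, pw)))  # padded border got no loss
        d = self.head.backward(d[None])
        dskips = []
        for up, conv, norm, relu, shape in zip(reversed(self.ups),
                                               reversed(self.dec_convs),
                                               reversed(self.dec_norms),
                                               reversed(self.dec_relus),
                                               self._skip_shapes):
            d = conv.backward(norm.backward(relu.backward(d)))
            c_skip = shape[0]
            dskips.append(d[-c_skip:])
            d = up.backward(d[:-c_skip])
        # dskips currently ordered deepest-first along decoder traversal:
        # decoder consumed skips in reversed(skips) order, and we walked the
        # decoder backwards, so dskips[0] pairs with skips[0], etc.
        d = self.bott_conv.backward(self.bott_norm.backward(self.bott_relu.backward(d)))
        for conv, norm, relu, scm, pool, dskip in zip(
            reversed(self.enc_convs), reversed(self.enc_norms),
            reversed(self.enc_relus), reversed(self.enc_scms),
            reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = d + dskip
            d = conv.backward(norm.backward(relu.backward(scm.backward(d))))

    def predict_proba(self, plane: np.ndarray) -> np.ndarray:
        """Vessel probability raster in (0, 1)."""
        if not self.trained:
            warnings.warn("model has not been trained", RuntimeWarning)
        return 1.0 / (1.0 + np.exp(-np.clip(self.forward_logits(plane), -60, 60)))

    def bottleneck_descriptor(self, plane: np.ndarray) -> np.ndarray:
        """Fixed-length spatial-pyramid descriptor of the bottleneck map."""
        self.forward_logits(plane)
        return spatial_pyramid_pool(self._bottleneck,
                                    self.cfg.attention.pyramid_levels).ravel()

    @property
    def descriptor_length(self) -> int:
        c_deep = self.cfg.base_channels * 2 ** (self.cfg.depth - 1)
        return c_deep * pyramid_descriptor_length(self.cfg.attention.pyramid_levels)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                arrays[f"{i}:{k}"] = v
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = asdict(self.cfg)
        cfg["attention"]["pyramid_levels"] = list(cfg["attention"]["pyramid_levels"])
        cfg["trained"] = self.trained
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, path) -> "SegNet":
        path = Path(path)
        cfg_d = json.loads(path.with_suffix(".json").read_text())
        trained = cfg_d.pop("trained", False)
        att = cfg_d.pop("attention")
        att["pyramid_levels"] = tuple(att["pyramid_levels"])
        cfg = SegNetConfig(attention=AttentionConfig(**att), **cfg_d)
        model = cls(cfg)
        data = np.load(path.with_suffix(".npz"))
        for i, layer in enumerate(model.layers()):
            for k in layer.params:
                layer.params[k] = data[f"{i}:{k}"]
            layer.zero_grad()
        model.trained = trained
        return model


def build_network(cfg: SegNetConfig) -> SegNet:
    """Construct the attention U-net from its configuration."""
    return SegNet(cfg)


# ----------------------------------------------------------------------


def _dice_bce_loss(logits: np.ndarray, target: np.ndarray,
                   eps: float = 1e-7,
                   dice_weight: float = 2.0,
                   pos_weight: float = 3.0) -> Tuple[float, np.ndarray]:
    """Weighted Dice + BCE loss and its gradient w.r.t. the logits.

    Vessels cover only a few percent of the pixels, so plain BCE
    under-segments them: probabilities at thin-vessel pixels settle just
    below the decision threshold.  Two counterweights address this — the
    Dice term is weighted up relative to BCE, and vessel pixels carry
    ``pos_weight`` inside the BCE itself.
    """
    t = target.astype(float)
    p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
    n = p.size
    w = np.where(t > 0, pos_weight, 1.0)
    bce = float(-(w * (t * np.log(p + eps)
                       + (1 - t) * np.log(1 - p + eps))).mean())
    inter = (p * t).sum()
    denom = p.sum() + t.sum() + eps
    dice = (2.0 * inter + eps) / denom
    loss = bce + dice_weight * (1.0 - dice)
    dbce_dp = w * (p - t) / np.clip(p * (1 - p), eps, None) / n
    ddice_dp = (2.0 * t * denom - (2.0 * inter + eps)) / (denom ** 2)
    dp = dbce_dp - dice_weight * ddice_dp
    return loss, dp * p * (1 - p)


def train(
    model: SegNet,
    samples: Sequence[Tuple[np.ndarray, np.ndarray]],
    cfg: Optional[SegNetConfig] = None,
) -> List[float]:
    """Train the segmenter on (plane, mask) pairs; returns per-epoch losses.

    ``plane`` is a single-channel [0, 1] raster (e.g. the enhanced plane
    or the green channel); ``mask`` a binary raster of the same size.
    """
    cfg = cfg or model.cfg
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples")
    for _, m in samples:
        vals = np.unique(np.asarray(m))
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("masks must be binary")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.layers(), lr=cfg.learning_rate)
    trace: List[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            for idx in batch:
                plane, mask = samples[idx]
                logits = model.forward_logits(plane)
                loss, dlogits = _dice_bce_loss(logits, np.asarray(mask),
                                               dice_weight=cfg.dice_weight,
                                               pos_weight=cfg.pos_weight)
                model.backward(dlogits / len(batch))
                epoch_loss += loss
            opt.step()
        trace.append(epoch_loss / len(samples))
    if cfg.epochs > 0:
        model.trained = True
    return trace


def segment(
    model: SegNet,
    plane: np.ndarray,
    threshold: Optional[float] = None,
    fov: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Binary vessel mask and probability raster for one image plane."""
    thr = model.cfg.threshold if threshold is None else threshold
    prob = model.predict_proba(plane)
    mask = prob >= thr
    if fov is not None:
        mask &= np.asarray(fov, dtype=bool)
    return mask, prob


# ----------------------------------------------------------------------
# paired augmentation


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    seed: Optional[int] = None,
    rotation: Optional[float] = None,
    shear: Optional[float] = None,
    translation: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one random rotation/shear/translation to an image/mask pair.

    Angles are drawn in +-25 degrees, shear in +-0.15 rad, translation in
    +-10% of each dimension; explicit values override the draw.  The image
    is interpolated bilinearly, the mask with nearest neighbour so it stays
    binary.  Deterministic under ``seed``.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask sizes differ")
    rng = np.random.default_rng(seed)
    if rotation is None:
        rotation = rng.uniform(-25.0, 25.0)
    if shear is None:
        shear = rng.uniform(-0.15, 0.15)
    if translation is None:
        h, w = mask.shape[:2]
        translation = (rng.uniform(-0.1, 0.1) * w, rng.uniform(-0.1, 0.1) * h)
    if rotation == 0 and shear == 0 and tuple(translation) == (0, 0):
        return image.copy(), mask.copy()
    h, w = mask.shape[:2]
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (AffineTransform(translation=-centre)
          + AffineTransform(rotation=np.deg2rad(rotation), shear=shear)
          + AffineTransform(translation=centre)
          + AffineTransform(translation=translation))
    img_out = warp(image, tf.inverse, order=1, mode="constant", cval=0.0,
                   preserve_range=True)
    mask_out = warp(mask.astype(float), tf.inverse, order=0, mode="constant",
                    cval=0.0, preserve_range=True).astype(mask.dtype)
    return img_out, mask_out


# ----------------------------------------------------------------------
# optic-disc removal


@dataclass
class DiscRegion:
    """Detected optic disc: centre, mask and mean brightness."""

    center: Tuple[float, float]
    mask: np.ndarray
    mean_brightness: float
    vessel_mask_without_disc: Optional[np.ndarray] = None


def remove_optic_disc(
    image: np.ndarray,
    vessel_mask: Optional[np.ndarray] = None,
    k: int = 3,
    fov: Optional[np.ndarray] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, Optional[DiscRegion]]:
    """Locate the optic disc by k-means and zero it out of the image.

    Pixel features are (intensity, Gaussian-blurred intensity) inside the
    field of view; the brightest of the ``k`` clusters is the disc
    candidate.  Its largest connected component is closed morphologically
    and its filled hull becomes the disc mask; those pixels are zeroed in
    the returned working image.  When ``vessel_mask`` is supplied, the
    returned :class:`DiscRegion` carries ``vessel_mask_without_disc`` for
    downstream vessel analysis (never larger than the input mask).

    Returns ``(image, None)`` unchanged when no cluster is brighter than
    the image mean (no-disc condition).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    img = np.asarray(image, dtype=float)
    intensity = img.mean(axis=2) if img.ndim == 3 else img
    h, w = intensity.shape
    if fov is None:
        fov = np.ones((h, w), dtype=bool)
    fov = np.asarray(fov, dtype=bool)
    blurred = ndi.gaussian_filter(intensity, sigma=3.0)
    feats = np.stack([intensity[fov], blurred[fov]], axis=1)
    km = KMeans(n_clusters=k, n_init=3, random_state=seed)
    labels = km.fit_predict(feats)
    means = np.array([intensity[fov][labels == i].mean() for i in range(k)])
    bright = int(np.argmax(means))

    def _nodisc():
        return img.copy(), None

    if means[bright] <= intensity[fov].mean():
        return _nodisc()

    cand = np.zeros((h, w), dtype=bool)
    cand[fov] = labels == bright
    # close before labelling: vessels leaving the disc cut the bright
    # region into pieces, and the closing bridges those cuts
    r = max(2, int(round(0.025 * min(h, w))))
    selem = np.hypot(*np.mgrid[-r:r + 1, -r:r + 1]) <= r
    closed = ndi.binary_closing(cand, structure=selem)
    lab, n = ndi.label(closed)
    if n == 0:
        return _nodisc()
    sizes = ndi.sum(closed, lab, index=np.arange(1, n + 1))
    comp = ndi.binary_fill_holes(lab == (int(np.argmax(sizes)) + 1))
    # fit an ellipse to the component via its second moments
    # (for a filled ellipse, semi-axis = 2 * std along each principal axis)
    pts = np.argwhere(comp).astype(float)
    ctr = pts.mean(axis=0)
    cov = np.cov((pts - ctr).T) + 1e-9 * np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    axes = 2.0 * np.sqrt(np.maximum(evals, 1e-9))
    coords = np.stack(np.mgrid[0:h, 0:w], axis=-1).astype(float) - ctr
    proj = coords @ evecs
    disc = ((proj[..., 0] / axes[0]) ** 2 + (proj[..., 1] / axes[1]) ** 2) <= 1.0
    disc |= comp
    disc &= fov
    mean_b = float(intensity[disc].mean())
    if mean_b < intensity[fov].mean():
        return _nodisc()
    r, c = ndi.center_of_mass(disc)
    out = img.copy()
    out[disc] = 0.0
    region = DiscRegion(center=(float(r), float(c)), mask=disc,
                        mean_brightness=mean_b)
    if vessel_mask is not None:
        region.vessel_mask_without_disc = np.asarray(vessel_mask, dtype=bool) & ~disc
    return out, region
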