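"""Vessel graph analysis and the 24-feature image descriptor.

From a binary vessel mask the module derives a :class:`VesselGraph`
(1-pixel centerlines, per-segment widths from the distance transform,
bifurcations and crossovers), labels each segment artery or vein, and
condenses image + graph into a fixed, versioned vector of 24 scalar
features in four groups:

* texture (8) — grey-level co-occurrence contrast, correlation, energy,
  homogeneity and entropy of the enhanced plane (distance 1, four
  symmetric angles averaged, 32 grey levels), plus mean, variance and
  skewness of the uniform LBP histogram (radius 1, 8 neighbours);
* color (6) — mean and standard deviation of the hue, saturation and
  value planes inside the vessel mask;
* disc (4) — optic-disc area fraction, mean disc brightness, disc
  boundary blur (mean gradient magnitude on the boundary ring), and the
  disc obscuration ratio (vessel pixels inside the disc / disc area);
* vascular (6) — vessel density, mean and standard deviation of vessel
  width, mean tortuosity (arc/chord per segment), junction density
  (junctions per centerline pixel) and the artery-to-vein mean-width
  ratio (AVR proxy, the classic marker of arteriolar narrowing).

Arteriovenous crossings appear on centerlines as 4-way junctions; a
small neighbourhood around each crossover is eroded from the working
skeleton before per-segment measurements so that crossing vessels are
not fused into one segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern
from skimage.morphology import skeletonize

from .enhancement import HSVImage, rgb_to_hsv_paper

__all__ = [
    "FEATURE_NAMES",
    "VesselGraph",
    "AVLabel",
    "skeletonize_vessels",
    "detect_junctions",
    "classify_av",
    "extract_features",
    "tortuosity",
]

#: canonical, versioned order of the 24 features (v1)
FEATURE_NAMES: Tuple[str, ...] = (
    # texture (8)
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
    "glcm_entropy", "lbp_hist_mean", "lbp_hist_var", "lbp_hist_skew",
    # color (6)
    "hue_mean", "hue_std", "sat_mean", "sat_std", "val_mean", "val_std",
    # disc (4)
    "disc_area_fraction", "disc_mean_brightness", "disc_boundary_blur",
    "disc_obscuration",
    # vascular (6)
    "vessel_density", "mean_vessel_width", "vessel_width_std",
    "mean_tortuosity", "junction_density", "artery_vein_width_ratio",
)

_CROSSOVER_ERODE_RADIUS = 3  # px removed around each crossover


@dataclass
class VesselGraph:
    """Centerline representation of a vessel mask."""

    centerline: np.ndarray                       # bool raster
    segments: List[np.ndarray]                   # ordered (n_i, 2) pixel chains
    junctions: List[Tuple[int, int, str]]        # (row, col, 'bifurcation'|'crossover')
    widths: List[float]                          # mean caliber per segment, px
    segment_widths: List[np.ndarray] = field(default_factory=list)


@dataclass
class AVLabel:
    labels: List[str]                            # 'artery' | 'vein' per segment
    confidence: np.ndarray
    degenerate: bool = False                     # all segments fell in one class


# ----------------------------------------------------------------------
# skeleton & graph


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3)); kernel[1, 1] = 0
    return ndi.convolve(skel.astype(int), kernel, mode="constant")


def _order_chain(pixels: np.ndarray) -> np.ndarray:
    """Order a connected set of skeleton pixels into a walkable chain."""
    pix = {tuple(p) for p in pixels}
    nbrs: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for (r, c) in pix:
        nbrs[(r, c)] = [(r + dr, c + dc)
                        for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                        if (dr or dc) and (r + dr, c + dc) in pix]
    ends = [p for p, ns in nbrs.items() if len(ns) <= 1]
    start = min(ends) if ends else min(pix)
    chain = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [p for p in nbrs[cur] if p not in seen]
        if not nxt:
            break
        cur = nxt[0]
        chain.append(cur)
        seen.add(cur)
    return np.array(chain)


def detect_junctions(skel: np.ndarray) -> List[Tuple[int, int, str]]:
    """Junction pixels of a skeleton, merged over 3x3 clusters and typed.

    A merged cluster whose total branch count is 3 is a bifurcation; 4 or
    more branches mark an arteriovenous crossover.
    """
    counts = _neighbor_count(skel) * skel
    jmask = counts >= 3
    if not jmask.any():
        return []
    lab, n = ndi.label(jmask, structure=np.ones((3, 3)))
    out: List[Tuple[int, int, str]] = []
    for i in range(1, n + 1):
        comp = lab == i
        r, c = ndi.center_of_mass(comp)
        # branches leaving the merged cluster
        dil = ndi.binary_dilation(comp, structure=np.ones((3, 3)))
        outside = skel & dil & ~comp
        _, nb = ndi.label(outside, structure=np.ones((3, 3)))
        kind = "crossover" if nb >= 4 else "bifurcation"
        out.append((int(round(r)), int(round(c)), kind))
    return out


def skeletonize_vessels(mask: np.ndarray) -> VesselGraph:
    """Thin a vessel mask to centerlines and split it into segments.

    Widths are twice the Euclidean distance transform sampled along the
    centerline.  Crossover neighbourhoods are eroded from the working
    skeleton before segment splitting, so crossing vessels do not merge.
    An empty mask yields an empty graph.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return VesselGraph(centerline=np.zeros_like(mask), segments=[],
                           junctions=[], widths=[])
    skel = skeletonize(mask)
    dt = ndi.distance_transform_edt(mask)
    junctions = detect_junctions(skel)

    work = skel.copy()
    h, w = mask.shape
    for (r, c, kind) in junctions:
        rad = _CROSSOVER_ERODE_RADIUS if kind == "crossover" else 1
        rr = slice(max(0, r - rad), min(h, r + rad + 1))
        cc = slice(max(0, c - rad), min(w, c + rad + 1))
        work[rr, cc] = False

    lab, n = ndi.label(work, structure=np.ones((3, 3)))
    segments, widths, seg_widths = [], [], []
    for i in range(1, n + 1):
        pix = np.argwhere(lab == i)
        if len(pix) < 3:  # too short to measure
            continue
        chain = _order_chain(pix)
        wline = 2.0 * dt[chain[:, 0], chain[:, 1]]
        segments.append(chain)
        widths.append(float(wline.mean()))
        seg_widths.append(wline)
    return VesselGraph(centerline=skel, segments=segments, junctions=junctions,
                       widths=widths, segment_widths=seg_widths)


def tortuosity(chain: np.ndarray) -> float:
    """Arc length over chord length of an ordered pixel chain (>= 1)."""
    if len(chain) < 2:
        return 1.0
    steps = np.diff(chain.astype(float), axis=0)
    arc = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    chord = float(np.hypot(*(chain[-1] - chain[0]).astype(float)))
    if chord < 1e-9:
        return 1.0
    return max(arc / chord, 1.0)


# ----------------------------------------------------------------------
# artery/vein labelling


def _segment_features(plane: np.ndarray, hsv: Optional[HSVImage],
                      graph: VesselGraph) -> np.ndarray:
    """Per-segment cue bundle: intensity, width, central reflex, hue spread."""
    feats = []
    for chain, wd in zip(graph.segments, graph.widths):
        r, c = chain[:, 0], chain[:, 1]
        inten = float(np.median(plane[r, c]))
        # central reflex: centerline brightness minus flank brightness
        off = max(1, int(round(wd / 2)))
        h, w = plane.shape
        flank_vals = []
        for dr, dc in ((off, 0), (-off, 0), (0, off), (0, -off)):
            rr = np.clip(r + dr, 0, h - 1)
            cc = np.clip(c + dc, 0, w - 1)
            flank_vals.append(plane[rr, cc])
        reflex = inten - float(np.median(np.concatenate(flank_vals)))
        hue_spread = float(hsv.beta_h[r, c].std()) if hsv is not None else 0.0
        feats.append([inten, wd, reflex, hue_spread])
    return np.asarray(feats, dtype=float)


def classify_av(
    image: np.ndarray,
    graph: VesselGraph,
    model=None,
    labels_for_fit: Optional[Sequence[str]] = None,
) -> AVLabel:
    """Label each vessel segment artery or vein.

    Arteries are brighter, thinner and carry a central light reflex;
    veins are darker, wider and show more colour fluctuation.  With a
    classifier ``model`` (any sklearn-style estimator, optionally fitted
    here when ``labels_for_fit`` is given) the per-segment cue bundle
    (median centerline intensity, width, reflex contrast, hue spread) is
    scored by the model; otherwise a majority-of-cues threshold rule
    against the across-segment medians is applied.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        plane = img[..., 1]  # green-equivalent plane
        hsv = rgb_to_hsv_paper(img)
    else:
        plane = img
        hsv = None
    if not graph.segments:
        return AVLabel(labels=[], confidence=np.zeros(0), degenerate=True)
    X = _segment_features(plane, hsv, graph)

    if model is not None:
        if labels_for_fit is not None:
            model.fit(X, list(labels_for_fit))
        pred = list(model.predict(X))
        conf = np.ones(len(pred))
        degenerate = len(set(pred)) < 2
        return AVLabel(labels=pred, confidence=conf, degenerate=degenerate)

    # quartile-midpoint thresholds are robust when many segments share a
    # cue value (the median can land exactly on one class's value)
    thr = (np.quantile(X, 0.25, axis=0) + np.quantile(X, 0.75, axis=0)) / 2.0
    votes = (1.0 * (X[:, 0] > thr[0])        # brighter (primary cue)
             + 0.5 * (X[:, 1] < thr[1])      # thinner
             + 0.5 * (X[:, 2] > thr[2]))     # reflex-positive
    labels = ["artery" if v >= 1.0 else "vein" for v in votes]
    conf = np.clip(np.abs(votes - 1.0) / 1.0, 0.0, 1.0)
    degenerate = len(set(labels)) < 2
    if degenerate:
        warnings.warn("artery/vein labelling degenerated to a single class",
                      RuntimeWarning)
    return AVLabel(labels=labels, confidence=conf, degenerate=degenerate)


# ----------------------------------------------------------------------
# the 24-feature descriptor


def _glcm_features(plane: np.ndarray, levels: int = 32) -> List[float]:
    q = np.clip((plane * levels).astype(int), 0, levels - 1)
    glcm = graycomatrix(q, distances=[1],
                        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=levels, symmetric=True, normed=True)
    contrast = float(graycoprops(glcm, "contrast").mean())
    correlation = float(graycoprops(glcm, "correlation").mean())
    energy = float((graycoprops(glcm, "ASM")).mean())
    homogeneity = float(graycoprops(glcm, "homogeneity").mean())
    p = glcm.mean(axis=(2, 3))
    p = p / p.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return [contrast, correlation, energy, homogeneity, entropy]


def _lbp_features(plane: np.ndarray) -> List[float]:
    lbp = local_binary_pattern(np.round(plane * 255).astype(np.uint8),
                               P=8, R=1, method="uniform")
    hist, _ = np.histogram(lbp, bins=10, range=(0, 10), density=True)
    m = float(hist.mean())
    v = float(hist.var())
    s = float(np.mean((hist - m) ** 3) / (v ** 1.5)) if v > 0 else 0.0
    return [m, v, s]


def extract_features(
    image: np.ndarray,
    enhanced: np.ndarray,
    vessel_mask: np.ndarray,
    disc_mask: Optional[np.ndarray],
    graph: VesselGraph,
    av: Optional[AVLabel] = None,
    fov: Optional[np.ndarray] = None,
) -> np.ndarray:
    """The 24-feature vector, in :data:`FEATURE_NAMES` order.

    ``image`` is the RGB raster, ``enhanced`` the single enhanced plane,
    both in [0, 1].  An empty vessel mask zeroes the vascular features
    with a warning.  All entries are finite; density and fraction
    features lie in [0, 1].
    """
    img = np.asarray(image, dtype=float)
    enh = np.asarray(enhanced, dtype=float)
    vessel = np.asarray(vessel_mask, dtype=bool)
    h, w = enh.shape
    if fov is None:
        fov = np.ones((h, w), dtype=bool)
    fov = np.asarray(fov, dtype=bool)

    out: List[float] = []
    out += _glcm_features(enh)
    out += _lbp_features(enh)

    hsv = rgb_to_hsv_paper(img)
    sel = vessel if vessel.any() else fov
    for plane in (hsv.beta_h, hsv.beta_s, hsv.beta_v):
        out.append(float(plane[sel].mean()))
        out.append(float(plane[sel].std()))

    gray = img.mean(axis=2)
    if disc_mask is not None and np.asarray(disc_mask).any():
        disc = np.asarray(disc_mask, dtype=bool)
        area = float(disc.sum())
        out.append(area / float(fov.sum()))
        out.append(float(gray[disc].mean()))
        boundary = ndi.binary_dilation(disc) ^ ndi.binary_erosion(disc)
        gr, gc = np.gradient(gray)
        gmag = np.hypot(gr, gc)
        out.append(float(gmag[boundary].mean()) if boundary.any() else 0.0)
        out.append(float((vessel & disc).sum()) / area)
    else:
        out += [0.0, 0.0, 0.0, 0.0]

    if not vessel.any():
        warnings.warn("empty vessel mask: vascular features set to 0",
                      RuntimeWarning)
        out += [0.0] * 6
    else:
        out.append(float(vessel[fov].sum()) / float(fov.sum()))
        if graph.widths:
            out.append(float(np.mean(graph.widths)))
            out.append(float(np.std(graph.widths)))
            out.append(float(np.mean([tortuosity(s) for s in graph.segments])))
            ncl = max(int(graph.centerline.sum()), 1)
            out.append(min(len(graph.junctions) / ncl, 1.0))
        else:
            out += [0.0, 0.0, 1.0, 0.0]
        if av is not None and av.labels:
            aw = [wd for wd, lab in zip(graph.widths, av.labels) if lab == "artery"]
            vw = [wd for wd, lab in zip(graph.widths, av.labels) if lab == "vein"]
            if aw and vw and np.mean(vw) > 0:
                out.append(float(np.mean(aw) / np.mean(vw)))
            else:
                out.append(1.0)
        else:
            out.append(1.0)

    vec = np.asarray(out, dtype=float)
    assert vec.shape == (24,)
    return np.where(np.isfinite(vec), vec, 0.0)
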