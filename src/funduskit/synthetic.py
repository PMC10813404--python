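"""Synthetic fundus image generator.

Produces fundus-like RGB images with exact ground truth (vessel, artery,
vein, optic-disc and lesion masks) so that every stage of the pipeline —
enhancement, segmentation, disc removal, feature extraction, grading —
can be exercised and validated without any external dataset.

The renderer is a geometric fixture, not a vascular model: a dark circular
field of view, a bright elliptical optic disc, and a recursively branching
vessel tree grown from the disc centre as two arcades.  Veins are drawn
wider and darker; arteries thinner and brighter with a central light
reflex.  Segment width halves at each branching generation.

Grades follow the clinical five-level convention for hypertensive
retinopathy and control the rendered findings:

* ``normal``    — no abnormality;
* ``mild``      — generalised arteriolar narrowing (lower artery/vein
  width ratio);
* ``moderate``  — narrowing plus focal arteriolar constrictions;
* ``severe``    — further narrowing, focal constrictions and dark
  retinal hemorrhage blobs;
* ``malignant`` — hard exudates (bright yellow blobs) and optic-disc
  edema (enlarged, blurred disc).

Identical :class:`SyntheticSpec` values give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

__all__ = [
    "GRADES",
    "SyntheticSpec",
    "SyntheticSample",
    "spec_for_grade",
    "generate_fundus",
    "generate_feature_table",
]

#: the five gradable severity levels, in increasing order
GRADES: Tuple[str, ...] = ("normal", "mild", "moderate", "severe", "malignant")

#: default artery/vein width ratio per grade; decreases normal -> severe
_GRADE_AVR = {
    "normal": 0.75,
    "mild": 0.62,
    "moderate": 0.52,
    "severe": 0.40,
    "malignant": 0.48,
}

_GRADE_PRESET = {
    "normal": dict(n_hemorrhages=0, n_exudates=0, disc_edema=False, focal_constrictions=0),
    "mild": dict(n_hemorrhages=0, n_exudates=0, disc_edema=False, focal_constrictions=0),
    "moderate": dict(n_hemorrhages=0, n_exudates=0, disc_edema=False, focal_constrictions=3),
    "severe": dict(n_hemorrhages=6, n_exudates=0, disc_edema=False, focal_constrictions=4),
    "malignant": dict(n_hemorrhages=2, n_exudates=5, disc_edema=True, focal_constrictions=0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of one synthetic fundus image.

    ``width``/``height`` must be >= 64.  The default canvas is 300x250,
    the working size used throughout the pipeline.  ``noise_sd`` is the
    standard deviation of the additive Gaussian pixel noise (intensity
    units on the [0, 1] scale) applied last, before clipping.
    """

    seed: int = 0
    width: int = 300
    height: int = 250
    grade: str = "normal"
    vessel_tree_depth: int = 4
    artery_vein_width_ratio: float = 0.75
    n_hemorrhages: int = 0
    n_exudates: int = 0
    disc_edema: bool = False
    noise_sd: float = 0.01
    focal_constrictions: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("canvas must be at least 64x64 pixels")
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}; expected one of {GRADES}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.vessel_tree_depth < 1:
            raise ValueError("vessel_tree_depth must be >= 1")


@dataclass
class SyntheticSample:
    """A rendered fundus image together with its exact ground truth."""

    image: np.ndarray            # (H, W, 3) float64 in [0, 1]
    vessel_mask: np.ndarray      # (H, W) bool, artery | vein
    artery_mask: np.ndarray
    vein_mask: np.ndarray
    disc_mask: np.ndarray
    fov_mask: np.ndarray
    hemorrhage_mask: np.ndarray
    exudate_mask: np.ndarray
    grade: str
    branch_points: List[Tuple[float, float]] = field(default_factory=list)
    spec: Optional[SyntheticSpec] = None


def spec_for_grade(grade: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """Grade preset: the rendering parameters implied by a severity level."""
    if grade not in GRADES:
        raise ValueError(f"unknown grade {grade!r}")
    kw = dict(
        seed=seed,
        grade=grade,
        artery_vein_width_ratio=_GRADE_AVR[grade],
        **_GRADE_PRESET[grade],
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


# ----------------------------------------------------------------------
# rendering helpers


def _stamp_path(mask: np.ndarray, pts: np.ndarray, widths: np.ndarray) -> None:
    """Rasterize a polyline with per-point width into a boolean mask."""
    h, w = mask.shape
    for (r, c), wd in zip(pts, widths):
        rad = max(float(wd) / 2.0, 0.5)
        rr, cc = draw_disk((r, c), rad, shape=(h, w))
        mask[rr, cc] = True


def _wiggly_polyline(rng: np.random.Generator, p0: np.ndarray, p1: np.ndarray,
                     amplitude: float, n: Optional[int] = None) -> np.ndarray:
    """Dense samples of a segment with a smooth perpendicular displacement."""
    if n is None:  # ~2 samples per pixel so thin stamped strokes stay connected
        n = max(24, int(2 * np.hypot(*(p1 - p0))))
    t = np.linspace(0.0, 1.0, n)
    base = p0[None, :] * (1 - t[:, None]) + p1[None, :] * t[:, None]
    d = p1 - p0
    length = float(np.hypot(*d))
    if length < 1e-9:
        return base
    perp = np.array([-d[1], d[0]]) / length
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.3, 1.0) * amplitude
    wiggle = amp * np.sin(np.pi * t + phase) * np.sin(np.pi * t)
    return base + wiggle[:, None] * perp[None, :]


def _grow_tree(rng: np.random.Generator, start: np.ndarray, angle: float,
               length: float, width: float, depth: int,
               segments: list, branch_points: list) -> None:
    """Recursive bifurcating growth; width halves per generation."""
    p1 = start + length * np.array([np.sin(angle), np.cos(angle)])
    pts = _wiggly_polyline(rng, start, p1, amplitude=0.12 * length)
    segments.append((pts, width, depth))
    if depth <= 1:
        return
    branch_points.append((float(p1[0]), float(p1[1])))
    spread = rng.uniform(0.35, 0.65)
    for sign in (+1.0, -1.0):
        child_angle = angle + sign * spread + rng.normal(0, 0.08)
        _grow_tree(rng, p1, child_angle, length * 0.72, width * 0.5,
                   depth - 1, segments, branch_points)


def _paint(image: np.ndarray, mask: np.ndarray, color: Tuple[float, float, float]) -> None:
    image[mask] = np.asarray(color, dtype=float)


def _place_blobs(rng: np.random.Generator, n: int, radius_range: Tuple[float, float],
                 allowed: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Place n disjoint round blobs on pixels where ``allowed`` is True."""
    out = np.zeros(shape, dtype=bool)
    avail = allowed.copy()
    for _ in range(n):
        rr_all, cc_all = np.nonzero(avail)
        if rr_all.size == 0:
            break
        i = rng.integers(rr_all.size)
        r0, c0 = int(rr_all[i]), int(cc_all[i])
        rad = rng.uniform(*radius_range)
        rr, cc = draw_disk((r0, c0), rad, shape=shape)
        out[rr, cc] = True
        # forbid a margin around the new blob so components stay disjoint
        block = np.zeros(shape, dtype=bool)
        rr2, cc2 = draw_disk((r0, c0), rad + max(radius_range) + 3, shape=shape)
        block[rr2, cc2] = True
        avail &= ~block
    return out


# ----------------------------------------------------------------------


def generate_fundus(spec: SyntheticSpec) -> SyntheticSample:
    """Render one synthetic fundus image with full ground truth.

    Deterministic: the same spec always yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    scale = min(h, w) / 250.0

    rows, cols = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    fov = (((rows - cy) / (0.48 * h)) ** 2 + ((cols - cx) / (0.48 * w)) ** 2) <= 1.0

    image = np.full((h, w, 3), 0.02)
    # reddish background with a mild radial vignette
    radial = np.sqrt(((rows - cy) / h) ** 2 + ((cols - cx) / w) ** 2)
    bg = np.stack([
        0.55 - 0.25 * radial,
        0.26 - 0.12 * radial,
        0.10 - 0.05 * radial,
    ], axis=-1)
    image[fov] = bg[fov]

    # --- optic disc (nasal side) -------------------------------------
    disc_r = 0.085 * min(h, w) * (1.4 if spec.disc_edema else 1.0)
    dc_r = cy + rng.uniform(-0.03, 0.03) * h
    dc_c = 0.72 * w + rng.uniform(-0.02, 0.02) * w
    disc = (((rows - dc_r) / (1.15 * disc_r)) ** 2 +
            ((cols - dc_c) / disc_r) ** 2) <= 1.0
    disc &= fov
    _paint(image, disc, (0.95, 0.82, 0.55))

    # --- vessel tree: two arcades, artery+vein pairs ------------------
    vein_w0 = 6.0 * scale
    artery_w0 = vein_w0 * spec.artery_vein_width_ratio
    origin = np.array([dc_r, dc_c])
    vein_segments: list = []
    artery_segments: list = []
    branch_points: list = []
    base_len = 0.30 * min(h, w)
    for arc_sign in (+1.0, -1.0):
        base_angle = -np.pi / 2 + arc_sign * 1.05  # pointing temporal, up/down
        off = np.array([arc_sign * 4.0 * scale, 0.0])
        _grow_tree(rng, origin + off, base_angle + 0.10, base_len, vein_w0,
                   spec.vessel_tree_depth, vein_segments, branch_points)
        _grow_tree(rng, origin - off, base_angle - 0.10, base_len * 0.95, artery_w0,
                   spec.vessel_tree_depth, artery_segments, branch_points)

    # focal constrictions: pinch artery width locally (moderate/severe)
    constrict = []
    if spec.focal_constrictions > 0:
        candidates = [s for s in artery_segments if s[2] >= spec.vessel_tree_depth - 1]
        for _ in range(spec.focal_constrictions):
            pts, wd, _d = candidates[rng.integers(len(candidates))]
            lo, hi = len(pts) // 4, max(len(pts) // 4 + 1, 3 * len(pts) // 4)
            constrict.append(tuple(pts[rng.integers(lo, hi)]))

    vein_mask = np.zeros((h, w), dtype=bool)
    for pts, wd, _d in vein_segments:
        _stamp_path(vein_mask, pts, np.full(len(pts), wd))
    artery_mask = np.zeros((h, w), dtype=bool)
    reflex_mask = np.zeros((h, w), dtype=bool)
    for pts, wd, _d in artery_segments:
        widths = np.full(len(pts), wd)
        for (pr, pc) in constrict:
            d2 = (pts[:, 0] - pr) ** 2 + (pts[:, 1] - pc) ** 2
            widths = np.where(d2 < (4.0 * scale) ** 2, widths * 0.4, widths)
        _stamp_path(artery_mask, pts, widths)
        if wd >= 2.0:  # central light reflex on the larger arteries
            _stamp_path(reflex_mask, pts, np.maximum(widths / 3.0, 0.8))
    vein_mask &= fov
    artery_mask &= fov
    reflex_mask &= artery_mask
    vessel_mask = vein_mask | artery_mask

    _paint(image, vein_mask, (0.30, 0.07, 0.06))
    _paint(image, artery_mask, (0.62, 0.22, 0.15))
    _paint(image, reflex_mask, (0.80, 0.42, 0.30))

    # --- lesions ------------------------------------------------------
    margin = ndi.binary_erosion(fov, iterations=max(3, int(6 * scale)))
    hem_allowed = margin & ~ndi.binary_dilation(disc, iterations=3)
    hemorrhage = _place_blobs(rng, spec.n_hemorrhages, (3.0 * scale, 5.0 * scale),
                              hem_allowed, (h, w))
    _paint(image, hemorrhage, (0.22, 0.03, 0.03))

    ex_r = (2.0 * scale, 3.5 * scale)
    ex_allowed = margin & ~ndi.binary_dilation(vessel_mask | disc | hemorrhage,
                                               iterations=int(np.ceil(ex_r[1] + 2)))
    exudate = _place_blobs(rng, spec.n_exudates, ex_r, ex_allowed, (h, w))
    _paint(image, exudate, (0.95, 0.92, 0.55))

    if spec.disc_edema:
        # blur the disc boundary to emulate edema
        blurred = ndi.gaussian_filter(image, sigma=(2.5 * scale, 2.5 * scale, 0))
        ring = ndi.binary_dilation(disc, iterations=int(4 * scale) + 2) & \
            ~ndi.binary_erosion(disc, iterations=int(2 * scale) + 1)
        image[ring] = blurred[ring]

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)

    return SyntheticSample(
        image=image,
        vessel_mask=vessel_mask,
        artery_mask=artery_mask,
        vein_mask=vein_mask,
        disc_mask=disc,
        fov_mask=fov,
        hemorrhage_mask=hemorrhage,
        exudate_mask=exudate,
        grade=spec.grade,
        branch_points=branch_points,
        spec=spec,
    )


# ----------------------------------------------------------------------
# class-separable feature tables (classifier test harness)

#: indices (into the 24-feature order of funduskit.features.FEATURE_NAMES)
#: that move with severity, and their direction of change
_GRADE_AXES = {
    19: -1.0,   # mean vessel width shrinks with narrowing
    23: -1.0,   # artery/vein width ratio falls
    0: +1.0,    # GLCM contrast rises with lesions
    4: +1.0,    # GLCM entropy rises
    16: +1.0,   # disc boundary blur rises (edema)
    21: +1.0,   # tortuosity rises
}


def generate_feature_table(
    seed: int, n_per_class: int, class_shift: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw a balanced, grade-labelled 24-feature Gaussian table.

    Class-conditional means are separated by ``class_shift`` standard
    deviations between consecutive grades along grade-relevant axes
    (vessel width and AVR decreasing, texture contrast/entropy, disc
    blur and tortuosity increasing).  Noise is unit-variance Gaussian.

    Returns ``(X, y)``: an ``(5*n_per_class, 24)`` float array and the
    matching grade-string array, shuffled deterministically by ``seed``.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if class_shift < 0:
        raise ValueError("class_shift must be non-negative")
    rng = np.random.default_rng(seed)
    direction = np.zeros(24)
    for idx, sign in _GRADE_AXES.items():
        direction[idx] = sign
    direction /= np.linalg.norm(direction)

    X_parts, y_parts = [], []
    for level, grade in enumerate(GRADES):
        mean = class_shift * level * direction
        X_parts.append(mean + rng.standard_normal((n_per_class, 24)))
        y_parts.append(np.full(n_per_class, grade, dtype=object))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]
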