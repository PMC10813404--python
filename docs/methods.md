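# Methods

This note documents the models and procedures implemented in
`funduskit`, the parameter choices that matter, what the synthetic test
bed does and does not emulate, and the package's known limitations.

## Enhancement chain

The pre-processing operates per RGB channel and then in a derived HSV
space.

**Gaussian contrast gain.** For a channel `o` with population mean `m`
and standard deviation `s`, the response is

    G(x,y) = 1/(2πs) · exp(−(o(x,y) − m)² / s)

Note the denominators: `2πs` and `s`, not the textbook `√(2πs²)` and
`2s²`.  This non-standard form is kept deliberately as the package's
canonical definition; the standard density is available behind
`textbook_gaussian=True`.  The gain is

    gain(x,y) = 1 + f / g(x,y),   g = 1 + G/λ,
    f = (1/n) · Σ p(x,y) · (1 − o(x,y))

with `λ = 0.2` (sampling parameter) and `p` the 256-bin histogram
probability of the pixel's own intensity.  `f` is a scalar in [0, 1], a
probability-weighted darkness score of the channel; `g` is largest where
a pixel sits at the channel mean, so the multiplicative gain is largest
for pixels *far* from the mean — vessels and lesions — and near 1 for
the background.  The gained channel is clipped to [0, 1].  A constant
channel (s = 0) cannot support the gain and passes through with a
warning.

**HSV on chromaticities.** `β_c = c/(r+g+b)`; hue from the arccos form
(radians in [0, π], sentinel 0 with a validity flag where the
denominator vanishes — achromatic pixels); saturation `(max−min)/max`
(0 at black); value = chromaticity max (so a gray pixel has value 1/3).

**Doane normalization.** Each plane is mapped through
`ψ = 1 + log₂(plane) + log₂|k|` where `k` is the plane's population
skewness `E[(x−m)³]/s³`.  Log arguments are clamped at 1e−12, and ψ is
min-max rescaled to [0, 1].  Skewness is computed from the plane's own
moments; it is exactly 0 for symmetric data.

**Channel selection.** Each plane's per-pixel histogram probability is
compared against the mean probability of the three planes at that pixel;
the cascade h → s → v takes the first plane strictly below the mean, and
v accepts on ≤.  Since at least one of three values is ≤ their mean, the
cascade is total.  The selected plane plus the per-pixel choice map is
the enhancement output.

The chain is fully deterministic; every stage's output lives in [0, 1].

## SCM attention block

For a feature map `M ∈ R^(C×H×W)`:

* **Spatial pyramid pooling**: for levels L ∈ {1, 2, 4} (default) the
  plane is split into L×L bins with half-open boundaries
  `⌊iH/L⌋ .. ⌊(i+1)H/L⌋`; each bin contributes its max and mean, giving
  a per-channel descriptor of length 2·ΣL² = 42 independent of H, W.
* **Channel gate**: the max- and mean-pooled descriptors each pass
  through a shared two-layer network (`W₀: C/e·… input`, hidden size
  `max(1, C/e)` with reduction ratio e = 4, ReLU by default or a
  Gaussian RBF unit `exp(−x²)`), the two outputs are summed element-wise
  and squashed by a sigmoid — one gate per channel.
* **Spatial gate**: channel-axis mean and max maps (2×H×W) convolved
  with a single 9×9 kernel, zero-padded to size, then a sigmoid — one
  gate per pixel.
* **Arrangement**: sequential by default (channel gate, then spatial
  gate on the gated map); a parallel variant
  `(D_C⊗M + D_S⊗M)/2` is available via configuration.

All gates lie strictly in (0, 1), so the block can only attenuate:
‖M″‖∞ ≤ ‖M‖∞.  Weights are He-uniform initialized from a seeded
generator.  A vectorized implementation is checked against a naive
nested-loop oracle in the tests.

## Vessel segmentation network

A shallow U-shaped encoder–decoder hosts the attention block:

    encoder stage i:  conv3×3 → instance-norm → ReLU → SCM block → maxpool2
    bottleneck:       conv3×3 → instance-norm → ReLU  (+ pyramid descriptor)
    decoder stage i:  upsample×2 → concat skip → conv3×3 → instance-norm → ReLU
    head:             conv1×1 → sigmoid

Defaults: depth 3, base 16 channels (16/32/64), ~141k parameters.
Inputs of any size are reflect-padded to a multiple of 2^depth and
cropped back.  The spatial-pyramid-pooled bottleneck gives a
fixed-length descriptor (64·42 = 2688) regardless of input size.

Everything — including backpropagation through both attention gates, the
pyramid pooling (mean bins are linear; max bins route gradients to their
argmax) and the 9×9 spatial convolution — is implemented in numpy and
verified against central-difference numerical gradients.

**Training.** Adam (lr 1e-2), batch size 1, loss

    L = BCE_w + 2 · (1 − softDice),

where vessel pixels carry weight 3 inside the BCE.  Both counterweights
address the ~5% positive-pixel imbalance: with plain BCE the predicted
probabilities at thin-vessel pixels settle just below the 0.5 decision
threshold and the mask under-segments (false negatives dominate the
error by an order of magnitude over false positives).  The decision
threshold itself stays at the neutral 0.5.  Input planes are
standardized to zero mean and unit variance per image; instance
normalization keeps activation scales stable so the network converges in
tens of epochs on a CPU.  Training is deterministic under the config
seed.

**Scaled-down problem size.** The shipped experiments train on 20
synthetic 128×128 pairs for 30 epochs (about two minutes on one CPU),
reaching training Dice ≈ 0.88–0.91 and held-out Dice ≈ 0.78–0.82 across
seeds.  128 px keeps the narrowest rendered vessels above the 1-pixel
rasterization floor; at 64 px the deepest branches collapse to single
pixels and Dice saturates lower for any model.

**Augmentation.** Paired random rotation (±25°), shear (±0.15 rad) and
translation (±10%), bilinear for the image and nearest-neighbour for the
mask so it stays binary.  Augmentation is exposed as its own operation;
the default scaled-down training run uses the clean pairs.

## Optic-disc removal

k-means (k = 3, seeded) on (intensity, Gaussian-blurred intensity)
features inside the field of view.  The brightest cluster is the disc
candidate; it is morphologically **closed before** connected-component
labelling because vessels leaving the disc cut the bright region into
fragments.  An ellipse is then fitted to the largest component via its
second moments (for a filled ellipse the semi-axis equals twice the
standard deviation along each principal axis), which restores the
disc's smooth boundary.  If no cluster is brighter than the image mean,
a no-disc condition is reported and the image is returned unchanged.
Disc pixels are zeroed in the working image and excluded from the
vessel mask.

## Vessel graph and the 24 features

Centerlines come from morphological thinning; per-pixel caliber is twice
the Euclidean distance transform sampled on the centerline.  Skeleton
pixels with ≥3 skeleton neighbours are junction candidates, merged over
3×3 clusters; a merged cluster with three outgoing branches is a
bifurcation, four or more mark an arteriovenous crossover.  A 3-px
neighbourhood around each crossover is eroded from the working skeleton
before segment splitting so crossing vessels are not fused into one
segment.  Segments shorter than 3 px are dropped as unmeasurable.

Artery/vein labelling uses per-segment cues: median centerline
intensity, caliber, central-reflex contrast (centerline minus flank
intensity) and hue spread.  The default rule is a weighted vote against
quartile-midpoint thresholds (brighter = primary cue, thinner and
reflex-positive = half-weight each); quartile midpoints rather than
medians because many segments share identical cue values and the median
can land exactly on one class's value.  Any sklearn-style classifier can
replace the rule.

The 24-feature descriptor (order fixed and versioned in
`FEATURE_NAMES`):

| group | features |
|---|---|
| texture (8) | GLCM contrast, correlation, energy, homogeneity, entropy (distance 1, four symmetric angles averaged, 32 grey levels) + LBP histogram mean/var/skew (radius 1, 8 neighbours, uniform) |
| color (6) | mean and std of hue, saturation, value inside the vessel mask |
| disc (4) | disc area fraction, mean disc brightness, boundary blur (mean gradient on the boundary ring), obscuration ratio (vessel∩disc / disc) |
| vascular (6) | vessel density, mean width, width std, mean tortuosity (arc/chord), junction density (junctions per centerline pixel), artery-to-vein mean-width ratio |

The four group names are fixed by the pipeline's design; the concrete
24-item enumeration is this package's canonical choice, constructed to
cover every cue the grading task uses (narrowing/AVR, obscuration,
texture of lesions, disc edema).  An empty vessel mask zeroes the
vascular group with a warning; all features are finite by construction.

## Classifiers

**Improved SVM** — rounds of one-vs-rest linear SVC fitted on sample
weights; after each round the per-sample multiclass hinge loss
`max(0, 1 + max_{j≠y} s_j − s_y)` multiplies the weights through
`exp(loss)` (clamped, renormalized).  The final decision function
averages the rounds' score matrices with weights proportional to each
round's weighted training accuracy.  With `n_rounds=1` the model is
exactly the plain linear variant.

**Improved KNN** — boosting over weak KNN learners: each learner is a
KNN with k drawn from {1, 3, 5} on a random √d-feature subset, fitted to
a weighted bootstrap resample.  Rounds use multiclass AdaBoost (SAMME)
vote weights `log((1−e)/e) + log(K−1)` and the matching sample
reweighting; prediction is the weighted vote, and the weak learner with
the lowest weighted training error is recorded.  With `n_learners=1` the
ensemble degenerates to that single KNN fitted on the unweighted data.

**Plain variants** — SVM: linear; polynomial `(x·z+1)^d` for d = 2, 3;
Gaussian with γ = 4/24, 1/24, 0.25/24 (fine/medium/coarse — the ordering
is specified, the values are this package's choice).  KNN: k = 1
(fine), 10 (medium), 100 (coarse, clipped to n with a warning), cosine
distance (k = 10), inverse-distance-weighted votes (k = 10).

**Cross-validation** — stratified k-fold (k = 10 by default), each fold
used once as test; the aggregate is the mean of per-fold metrics.
`accuracy` in the aggregate is the plain classification accuracy
(fraction correct); macro-averaged one-vs-rest accuracy is kept under
`accuracy_ovr_macro`.  With a class smaller than k the driver falls back
to unstratified folds with a warning.  The 80:20 split is stratified per
class with the test count rounded to the nearest integer and the
remainder to train.

## Metrics

From one-vs-rest confusion counts per class plus a pooled (micro) tally:
accuracy, precision, recall, F1 = 2PR/(P+R) (macro mean across classes;
the halved-sum variant is reported as `f1_paper`), Dice and Jaccard.
The default `dice` is `2TP/(2TP+FN)` — note the missing FP term — with
the conventional `2TP/(2TP+FP+FN)` behind `standard_dice=True`;
segmentation mask overlap always uses the conventional form.  Zero
denominators yield 0 with a warning.

## Synthetic test bed

The generator renders: a dark elliptical field of view with a reddish
vignetted background; a bright elliptical optic disc on the nasal side;
a vessel tree grown recursively from the disc as two arcades, one
artery/vein pair each, with midpoint-displacement wiggle, width halving
per generation, veins wider and darker, arteries thinner and brighter
with a central reflex stripe; grade-dependent findings (AVR presets
0.75/0.62/0.52/0.40 for normal→severe; focal constrictions from
moderate; dark hemorrhage blobs for severe; bright exudate blobs plus an
enlarged, boundary-blurred disc for malignant); additive Gaussian noise
(σ = 0.01 by default) and a final clip to [0, 1].  Identical specs give
bit-identical images, and all ground-truth masks are exact by
construction.

The class-separable feature tables draw 24-dimensional unit-variance
Gaussians whose consecutive class means are `class_shift` standard
deviations apart along grade-relevant axes (vessel width and AVR
decreasing; texture contrast/entropy, disc blur and tortuosity
increasing).

What the bed does **not** emulate: camera optics and illumination
fields, photoreceptor texture, real lesion morphology, inter-patient
anatomical variability, or annotation noise.  Tests passing on this bed
demonstrate that the pipeline's machinery is correct and internally
consistent — not that its accuracy transfers to clinical fundus
photographs.

## Numerical choices and degenerate inputs

* Coordinates are row-major, 0-based, origin top-left, everywhere.
* All randomness flows through seeded `numpy.random.Generator`s; every
  trainer and the pipeline are bit-reproducible under fixed seeds.
* Log arguments clamped at 1e−12; sigmoids evaluated on clipped inputs;
  boosting errors clamped to (1e−12, 1−1e−12).
* Constant channels, empty masks, absent discs and single-class label
  sets all degrade gracefully (warnings or flags, never NaNs).

## Known limitations

* The enhancement's printed-form Gaussian and the no-FP Dice are kept
  for fidelity to the pipeline's definition even where they differ from
  textbook forms; both have standard alternatives behind flags.
* The numpy network is CPU-bound and single-sample; it is sized for
  hundreds of images at ≤300 px, not for large clinical archives.
* Artery/vein labelling by threshold rule assumes arteries are brighter
  and thinner with a visible reflex — true of the synthetic bed and of
  typical fundus photographs, but not of pathologies that invert those
  cues.
* Junction typing by skeleton degree mislabels closely spaced
  bifurcations as crossovers when their 3×3 clusters merge.
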