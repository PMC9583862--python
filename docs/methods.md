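# Methods

## Scope and data model

The package compares three supervised benthic-cover mappers on co-registered
(RGB orthoimage, categorical label map) pairs over five classes — ZM
(*Zostera marina*), ZJ (*Z. japonica*), GA (green algae), BA (brown algae),
NV (no vegetation) — plus three ZM brightness subclasses (ZM1–ZM3) that
exist only inside cGAN training targets, and an UNLABELED sentinel excluded
from all accuracy computations. Labels are stored as small-integer rasters;
on disk they are paletted PNGs. The display palette is chosen with all
decodable colors pairwise ≥ 80 apart in Euclidean RGB so the continuous
output of the translation network decodes unambiguously by nearest color
(ties broken by the fixed class order ZM < ZJ < GA < BA < NV).

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the statistical core of the mapping problem:

* **Region geometry.** One smoothed Gaussian random field per class
  (sigma = patch_scale/2, wrap-around boundary), argmax assignment, with
  per-class biases tuned iteratively until realized areal fractions sit
  within half a percentage point of the targets. An optional along-row
  gradient biases ZJ toward one scene edge and ZM away from it, a
  qualitative stand-in for depth zonation in a real bed.
* **Color overlap.** Default per-class RGB means are green-dominant for
  ZM/ZJ/GA with wide spreads (SDs of 22–45 digital numbers), BA has an
  elevated red mean, NV is grey. Regression tests pin the consequences:
  ZM/ZJ green-channel histogram intersection > 0.5, and a per-pixel Bayes
  classifier on RGB alone (3-D histogram, 16 bins/channel, built from the
  truth itself) stays below OA 0.9 — so *no* per-pixel color method can
  excel, which is the precondition for the pixel baseline coming last.
* **Texture.** Per class: ZM — a sinusoidal stripe at the texture scale
  under a slow multiplicative brightness field (the stripe carries most of
  the structured spectral power, so the dominant spatial frequency equals
  1/texture_scale); ZJ — smooth blotches blended toward a substrate color;
  GA — gentle low-frequency variation only; BA — thin filaments along the
  zero set of a smooth field with a red-shifted color boost; NV — hard
  shell-like bright disks on grey. At texture_contrast 0 every kind
  degenerates to i.i.d. Gaussian color noise truncated to [0, 255].
* **Default mixture.** ZM 0.55, NV 0.23, ZJ 0.12, GA 0.06, BA 0.04 on a
  512×512 scene with patch_scale 48 — a strongly ZM-dominated bed with
  small BA patches, matching the dominance structure the methods are
  sensitive to (many ZM-only training tiles trigger the mode-collapse fix;
  training polygons are imbalanced accordingly).

Not modeled: water-column radiometry (attenuation, waves, sun glint), real
bathymetry, within-class species mixtures. A green end-to-end test
therefore establishes that the pipeline reproduces the *relative* behavior
of the three methods under color-ambiguous, texture-distinct conditions —
not absolute accuracies on real imagery.

Seeding: one master seed; every class field and every texture draws from
its own `numpy` sub-stream keyed by (seed, class, purpose), so adding or
removing a class leaves the others bit-identical.

## Tiling, split, augmentation, posterization

Scenes are cut into non-overlapping square tiles (floor grid; residual
right/bottom margins dropped — training pairs stay clean, and whole-map
translation output covers the cropped extent). The train/validation split
runs along one axis, default 54% of rows for training, with the boundary
snapped to the nearest tile multiple so no tile straddles it.

Training tiles are expanded exactly four-fold by horizontal, vertical, and
combined flips (originals first, then h, v, hv), applied after the split
and only to training tiles. No other augmentation is performed.

Mode-collapse mitigation: a training tile whose pixels are entirely ZM
(threshold configurable, default 1.0) has its luminance
(0.299 R + 0.587 G + 0.114 B) quantized to three levels and its labels
replaced by ZM1–ZM3 (darkest to brightest). Quantization is *exact*
1-D k-means — a dynamic program over the ≤ 256 discrete luminance levels
that finds the globally optimal contiguous partition. An exact DP was
preferred over Lloyd iterations with quantile initialization because it is
deterministic, optimal, and directly verifiable against exhaustive
enumeration; Lloyd can stall in local optima on multimodal histograms.
Default is per-tile quantization; a `global` mode pools the histogram over
all eligible tiles first (the choice is not determinable from the original
description, so both are provided). Posterizing validation tiles is
forbidden and asserted. After translation, subclasses merge back to ZM
before any assessment.

## The translation model

pix2pix-style conditional GAN on numpy (`benthoscope._nn`, a ~300-line
reverse-mode autograd with im2col convolutions, validated in the test suite
by exact adjoint identities):

* **Generator.** U-Net: stride-2 4×4 convolutions (batchnorm from the
  second level, leaky ReLU 0.2) down to tile_size/2^depth, mirrored
  transposed convolutions with skip concatenation, tanh output. It
  regresses palette-*color* images (the ground truth as trained on is a
  colored map), not per-class scores; nearest-palette decoding discretizes.
* **Discriminator.** PatchGAN on the channel-concatenated (input, map)
  pair: two stride-2 and two stride-1 4×4 convolution levels ending in a
  logit map (receptive field ≈ 34 px at the defaults).
* **Objective.** Generator: BCE-with-logits toward "real" plus
  `lambda_l1` × mean absolute error to the target colors (default 100).
  Discriminator: average BCE on real-vs-translated pairs. Adam with
  lr 2e-4, β₁ 0.5, batch 4. These are the customary values for this model
  family; none are dictated by the problem, and all sit in `GanConfig`.
* **Scale.** Default desk-scale config: tile 64, base_channels 16, depth 3,
  25 epochs — about a minute of CPU time on the default scene (32 training
  tiles × 4 flips). A 256-px-tile GPU-scale configuration is expressible
  but is not the test default.
* **Numerics.** float32 throughout; batchnorm always uses batch statistics
  (no running averages — translation is deterministic given the trained
  weights and input batching); training aborts with epoch/batch diagnostics
  on any non-finite loss; initialization is N(0, 0.02) from a seeded
  generator, so identical seeds give identical initial parameters.

## Baselines

* **Pixel SVM.** RBF kernel, C = 1, gamma = "scale", standardized inputs,
  balanced class weights (training polygons are deliberately imbalanced),
  at most 3,000 training pixels subsampled with a fixed seed. Training
  polygons are auto-digitized rectangles: per class, pure-class windows are
  drawn around random class pixels until a per-class pixel budget is met;
  budgets mimic a hand-digitized set in a ZM-dominated bed (ZM ≈ 3000 px
  down to BA ≈ 40 px). The window side shrinks if pure windows cannot be
  found, so fragmented classes still contribute.
* **Object SVM.** Segmentation is skimage Felzenszwalb with the merge
  threshold mapped monotonically from spectral detail (20 = finest) and a
  Gaussian pre-smoothing sigma from spatial detail, followed by iterative
  absorption of undersized segments into their most color-similar neighbor
  (union-find over the region adjacency graph) until every segment has at
  least min_segment_size pixels (default 500). The proprietary segmenter
  behind the published parameter names is not reproducible; this keeps the
  same three knobs and the same contracts (connected, disjoint, exhaustive,
  min-size-guaranteed). "Converged color" has no reproducible public
  definition and is implemented as the segment's median color. Features:
  median color, mean color, per-channel SD, pixel count, compactness
  (perimeter via skimage, clipped to ≤ 1 against discretization), and
  rectangularity. Training segments are labeled by majority overlap with
  the polygons; prediction paints each segment with its predicted class.

## Assessment

Random points are drawn uniformly *without replacement* by default (a
"points extracted in the area" protocol; a with-replacement switch exists).
All methods in a run share one point set, so comparisons are paired.
Metrics are reported raw and rounded half-up to 3 decimals. UA/PA of an
empty margin are explicitly undefined (rendered "NA"), never zero. The
Landis–Koch mapping is: k < 0 poor, ≤ 0.20 slight, ≤ 0.40 fair, ≤ 0.60
moderate, ≤ 0.80 substantial, else "almost perfect" (a standard extension;
the quoted scale stops at 0.80). The salt-and-pepper metric is the fraction
of interior pixels that disagree with all 8 neighbors.

The printed reference matrices ship as CSV fixtures in a simple dialect
(empty first cell, truth classes across, mapped classes down, optional
Total margins cross-checked at parse time) and reproduce all their printed
OA/K/UA/PA values to 3 decimal places; the metric functions are
additionally cross-checked against a brute-force recount that expands each
matrix into labeled point pairs.

## Known limitations

* The cGAN is CPU-scale by default; absolute accuracies on the synthetic
  default scene (OA ≈ 0.9 for the translation map) are not comparable to
  any real-imagery figure — only the method *ordering* and the structural
  properties (speckle, subclass containment) are asserted.
* Felzenszwalb's segment count is monotone in the mapped threshold only in
  practice, not by proof; the monotonicity tests pin it on fixed scenes.
* GA vs ZJ confusion in the synthetic world is milder than in real imagery
  (no species-level within-class color shifts are simulated).
* No kappa variance/confidence intervals and no area-weighted accuracy
  estimators; the assessment mirrors the plain random-point protocol.
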