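# Methods

This note records the modelling assumptions, numerical choices, and open
design decisions behind `myoseg`, in the spirit of a model-description
document rather than an API reference.

## Problem setting

Two-channel fluorescence micrographs of differentiating skeletal muscle
cultures: channel 0 carries elongated, branched, mutually overlapping
myotubes (myosin heavy chain stain), channel 1 carries clustered and
overlapping nuclei (DAPI). The quantities of biological interest are
per-myotube **diameter**, **length**, and **nuclei count** — proxies for
myoblast fusion and for atrophy/hypertrophy responses. Three obstacles
motivate the design: global thresholds fail under uneven illumination;
semantic segmentation alone cannot split touching nuclei; and diameter is
ill-defined without a branch-aware medial axis.

## Segmentation network

A fully convolutional residual encoder–decoder with three sigmoid heads
emitting per-pixel probabilities for myotube mask, nuclei mask, and
nuclei-centroid map. For a (2, 512, 512) input with the default width
(`base_channels=64`):

| block | layers | output |
|---|---|---|
| down 1 | 3×3 conv stride 2, instance norm, ReLU | 64×256×256 |
| down 2 | 3×3 conv stride 2, instance norm, ReLU | 128×128×128 |
| residual ×5 | conv–BN–ReLU–conv–BN + identity | 256×128×128 |
| up 1 | 3×3 transposed conv stride 2, instance norm, LeakyReLU | 128×256×256 |
| up 2 | 3×3 transposed conv stride 2, instance norm, LeakyReLU | 64×512×512 |
| heads ×3 | 5×5 conv stride 1, sigmoid | 1×512×512 each |

The residual stack runs at 256 channels although the second down-block
emits 128; a 1×1 projection (128→256) reconciles the two, and the first
up-block halves 256→128. A `strict_128` switch instead keeps 128 channels
throughout for users who prefer no projection. Instance norms are
non-affine (configurable); batch norms are affine with running statistics;
convolutions use Kaiming initialisation. Inputs must have spatial dims
divisible by 4 (two stride-2 stages); the network is otherwise
size-agnostic.

Training: per-class mean binary cross-entropy (probabilities clamped to
[1e−7, 1−1e−7]), weighted sum with λ = (1, 1, 1) by default (the weights
are exposed because no principled setting is known), Adam with lr 0.001,
β₁ = 0.5, β₂ = 0.999, mini-batches of 4, seeded shuffling, best-loss
checkpointing. Single-pixel centroid targets make BCE learning degenerate
(a constant-zero prediction is near-optimal), so centroid training targets
are dilated by a 2 px disk; downstream marker construction uses connected
components, so the dilation radius only needs to keep neighbouring
centroids separate.

The layer engine (`myoseg._nn`) implements conv / transposed conv /
norms / activations with explicit backward passes on numpy, lowering
convolutions to BLAS matrix products via im2col (cached scatter indices
for the adjoint). Eval-mode forward passes are cache-free and chunked so
full-frame inference stays within a few hundred MB. Correctness is
enforced by finite-difference gradient checks in the test suite.

## Marker-controlled watershed

Markers: connected components of the centroid map labelled 2..K+1 (dots
falling outside the nuclei mask are dropped with a warning); background
marker = complement of a 3 px dilation of the nuclei mask, leaving an
"unknown" band around every nucleus. Relief: negated Euclidean distance
transform of the nuclei mask, so flooding rises from nucleus centres.
Flooding assigns unknown pixels in non-decreasing relief order
(4-connectivity); a pixel whose already-labelled neighbours carry two or
more distinct labels becomes the watershed line (WL). Ties in relief are
broken row-major, making the result deterministic; the implementation is
a heap-based priority flood proven equal, pixel for pixel, to a
brute-force scan oracle in the tests. The returned label map is restricted
to the nuclei foreground: instances 1..K, background 0, WL −1.

## Skeleton morphometry

Skeletonization uses Lee-style medial-axis thinning (iterative
topology-preserving boundary peeling until stability); it is idempotent
and contained in the source mask. Branch decomposition: junctions are
skeleton pixels with ≥3 8-neighbours, endpoints have exactly 1; branches
are maximal junction-free 8-connected paths (cycles yield a single closed
branch). Local width at a skeleton pixel is `2·EDT − 1` pixels — the −1
makes a one-pixel line width 1 and is exact for odd-width digital strokes,
whereas `2·EDT` overestimates odd widths by one. Samples within 2 px of a
junction are excluded (the distance transform inflates where branches
meet). Branch length sums unit steps and √2 diagonal steps. Branches
shorter than 5 px are flagged and excluded from per-myotube means.
Nucleus-to-myotube assignment: a nucleus belongs to the myotube whose mask
contains its watershed-instance centroid pixel. Per-(myotube, branch)
records are emitted alongside per-myotube rollups, since it is unknown
whether published per-myotube diameters are branch-averaged.

## Synthetic scenes

The generator emulates the statistical structure the pipeline assumes,
with exact ground truth:

- **Tubes**: constant-width strokes along smooth random-walk splines
  (per-step heading change ~ N(0, `tube_curvature`)), entering from a
  random border and traversing the frame; with probability `branch_prob` a
  fork diverges mid-path, giving the skeleton nontrivial junctions.
  Staining intensity starts at 0.7–1.0 and fades linearly along the fibre
  to 60–85 % of its start value, emulating uneven staining.
- **Nuclei**: filled ellipses (radii from `nucleus_radius_range`); a
  target fraction of them is placed to overlap an existing nucleus
  (centres at 0.8 of the summed minor radii), the rest with ≥1 px
  clearance so components stay countable. Instance labels resolve overlap
  by normalised elliptical distance to each centre; the single-pixel
  centroid always belongs to its own nucleus.
- **Background**: base 0.05–0.15 plus a linear illumination ramp of
  amplitude `background_gradient` in a random direction; Gaussian noise
  (`noise_sigma`) is added to the image only — ground truth is
  noise-independent. Identical spec + seed reproduces scenes bit-exactly.

`gradient_scene_spec` fixes the benchmark conditions used by the learning
tests: 128×128 scenes, 2 tubes of width 5–11 px, 12 nuclei (20 % of them
overlapping), noise σ = 0.04, and gradient amplitude 0.5. At that
amplitude the brightest background exceeds the dimmest fibre ends, so no
global histogram threshold can separate the classes — the regime in which
learned segmentation is expected to dominate — while local contrast keeps
the task learnable. What these scenes do **not** model: PSF blur,
shot-noise statistics, out-of-focus light, stain bleed-through, or 3D
structure; passing tests demonstrate pipeline correctness and the
qualitative learned-vs-threshold ordering, not clinical-grade accuracy on
real micrographs.

Pixel pitch is recorded explicitly as `um_per_px` (default 1.0) in
manifests and reports rather than assuming any particular magnification.

## Scaled study conditions

Published pipelines of this kind train ~6M-parameter networks for ~150
epochs on dozens of annotated 2048×2048 frames with multi-GPU hardware.
The in-repo training benchmark instead uses 50 synthetic 128×128 scenes,
20 epochs, and a width-reduced network (`base_channels=16`,
five residual blocks — depth, the ablated quantity, is kept at its
reference value). These sizes are the package's own desk-scale choice so
the full train→evaluate loop runs in minutes on one CPU core; the
architecture checks (layer dimensions, parameter-count monotonicity) are
performed at full width.

## Numerical conventions and degenerate inputs

- Per-image min–max normalisation to [0, 1] per channel; constant channels
  map to zero (per-dataset normalisation is a documented alternative).
- Rotation augmentation is counter-clockwise in multiples of 90° only —
  no interpolation, foreground counts preserved.
- Inference tiling: zero overlap by default; overlapping tiles are
  mean-blended; `stitch(tile(x)) = x` at overlap 0.
- Binarisation threshold 0.5 on sigmoid outputs.
- IoU/Dice: empty-vs-empty = 1.0 (logged), empty-vs-nonempty = 0.
- Thresholds follow the classical criterion definitions (scikit-image);
  the Minimum method requires a histogram that smooths to bimodality and
  fails on pure two-spike histograms, in which case an empty mask and a
  warning are returned.
- Otsu on an empty/constant channel yields empty labels with a warning.
- Group summaries use the sample (n−1) standard deviation; single-image
  groups report std 0 with a flag. A Welch t-test helper is provided as a
  convenience only.
- Every pipeline output embeds a config hash; truth-mask-mode reruns are
  byte-identical.

## Known limitations

- The watershed runs a Python-level priority queue: fine for desk-scale
  scenes, slow for dense 2048² nuclei fields.
- Transposed-conv upsampling can introduce checkerboard artefacts at very
  low training budgets.
- The branch decomposition reports junction clusters as several short
  branches when three skeleton lines meet orthogonally within a 2 px
  radius (inherent to 8-neighbour junction definitions); diameter
  sampling is shielded from this by the junction-exclusion zone.
- Centroid-head IoU is sensitive to the dilation radius convention; any
  comparison across tools must fix that radius first.
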