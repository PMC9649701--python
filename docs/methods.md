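# Methods

This note records the models, conventions and design choices behind
`lsilearn`, in the spirit of a lab notebook for maintainers: what is
computed, why the defaults are what they are, and what the desk-scale
experiments do and do not demonstrate.

## Directional-derivative analysis of local structure

The filter bank consists of first- and second-order directional derivatives
of an anisotropic Gaussian steered to orientation θ:

    g(x; σ, ρ, θ) = 1/(2πσ²) · exp(−(ρ²u² + v²/ρ²)/(2σ²)),
    u = x·cosθ + y·sinθ,  v = −x·sinθ + y·cosθ,
    FOAGDD kernel = ∂g/∂u = −(ρ²u/σ²)·g,
    SOAGDD kernel = ∂²g/∂u² = (ρ²/σ²)(ρ²u²/σ² − 1)·g.

The envelope is *compressed* along the derivative direction (std σ/ρ) and
stretched across it (std σρ), the standard construction in the anisotropic
directional-derivative literature: the filter integrates along a candidate
edge while differentiating across it. The alternative convention (elongated
along the derivative direction) was evaluated and rejected — it never
produces the three-lobed junction profile at any anisotropy.

Conventions and discretization:

* row-major 0-based pixel indices; x along columns, y *upward* (the y-flip
  is applied inside kernel sampling), θ counterclockwise from +x;
* kernels are the analytic derivative sampled on the integer grid, then
  mean-subtracted so they sum exactly to zero — constant images respond
  with exactly zero and brightness offsets are invisible by construction;
* `support_radius` defaults to ⌈4σρ⌉ (truncated envelope mass < 1e−6 at the
  default scale); the validator requires at least ⌈3σρ⌉;
* P = 64 orientations, even so θ and θ+π are both sampled; profile parity
  (order 1 odd, order 2 even under θ → θ+π) is asserted in tests;
* defaults σ = ρ = √1.5.

Point analysis (`directional_response`) refuses locations closer than the
support radius to a border — no implicit padding. Whole-image stacks
(`response_map`) use reflect padding, with a `"valid"` mode that masks the
unsupported border band with NaN.

**Extrema counting.** Circular local extrema are counted after plateau
merging: circularly adjacent samples whose consecutive differences are
within ε (default 1e−3·max|profile|) collapse into one representative, so a
flat-topped lobe counts once. An effectively constant profile has no
extrema. A slow drift whose steps are all below ε also collapses — at the
default ε this requires a pathological profile that does not arise from the
filter bank.

**Structure classification** is a fixed two-threshold rule: blob if the
first-order peak is below t₁ *and* the second-order peak at least t₂;
otherwise ≥ 2 first-order maxima → corner, exactly 1 → edge, else none.
The source analyses mark structures by hand and state no detection rule, so
the rule and its calibration are this package's own: t₁ is 10% of the
canonical step-edge fixture's first-order peak and t₂ 50% of the canonical
blob fixture's second-order center response, both computed at run time from
the generators rather than hard-coded.

### The T-junction fixture

A three-sector wedge junction (three homogeneous sectors meeting at a
point) does **not** produce three maximum/minimum pairs at σ = ρ = √1.5:
at this mild anisotropy the angular response of an edge is close to a
cosine, the first angular harmonic of any wedge-T dominates, and an
exhaustive scan over sector gray levels finds only single-lobed profiles
(three lobes appear for wedges only from ρ ≈ 2 upward). What does carry the
three-lobed signature at the stated parameters is a junction between
contrasting *strips* — the geometry of window frames, mullions and wall
junctions in photographs, where such T-corners actually occur. The fixture
is therefore a stroke T: a bar (gray `levels[1]`) with a perpendicular stem
(`levels[2]`) on a background (`levels[0]`), half-width 1.5 px, anti-aliased
by 4× supersampling. The (3, 3) extrema signature is robust across all
tested 3-distinct-level combinations, bar widths 1–3 px, and junction
rotations. Degenerate level choices are reflected in the recorded truth:
bar == stem (uniform stroke) and bar == background (terminating line)
remain corner-type; stem == background leaves a symmetric ridge whose
first-order center response vanishes ("none").

The step edge uses an analytic one-pixel linear ramp; the blob is an
isotropic Gaussian bump (σ_b = 6 px, amplitude 0.6 on background 0.2).
Fixtures default to 129×129 with the feature point at the exact center.

## Information preprocessing

* **Blocks.** Images are center-cropped to the largest size divisible by N,
  then cut into N² equal blocks. Centered indices take the N values
  {−(N−1)/2, …, (N−1)/2} per axis (half-integers for even N): exactly N
  symmetric values, closed under quarter-turn rotation. i is horizontal
  (rightward), j vertical (upward).
* **Shuffle.** A seeded uniform draw over all (N²)! permutations
  (Fisher–Yates via `numpy`); the permutation is recorded, so the shuffle
  is invertible and the pixel multiset conserved bit-exactly. A fresh
  permutation is drawn per sample per epoch during training.
* **Rotation.** `rotate_image` rotates counterclockwise about the exact
  center with bilinear interpolation, zero fill and unchanged output size;
  0 and π are exact index operations. Rotated images keep their full frame
  (no re-crop), so every block position persists and corner blocks of
  rotated views contain partial fill — the labels remain well defined.
* **Index labels.** Rotating by angle a maps indices by the row-vector
  product [u, v] = [i, j]·R(a); labels are continuous and never snapped
  back to the grid (π/6 and π/4 produce irrational coordinates; the loss is
  a regression). The shuffled image's labels come from mean-gray matching:
  candidate (original block, shuffled position) pairs are visited in
  ascending |mean difference| (ties broken by raster order) and greedily
  accepted one-to-one. With distinct means this equals the naive
  closest-mean rule and recovers the true inverse permutation; unlike the
  naive rule it always yields a bijection. Rotated shuffles compose the
  matched labels with R(a).
* **Normalization.** Labels are divided by Z = √2·(N−1)/2 before the loss,
  so every reachable rotated label lies in [−1, 1] componentwise — the
  range of the tanh prediction head. One luminance rule (plain channel
  mean) serves both filtering and block-mean matching.
* **Schedules.** Both the uniform spacing (angles kπ/K over [0, (K−1)π/K])
  and explicit angle lists are supported; an explicit list wins. The
  default is the ablation-selected group {I, I_{π/6}, I_{π/4}, S}. The
  first angle of each list must be 0 so the unrotated original and
  unrotated shuffle are always present.

## Heads, losses, and the training objective

Per view: one shared-backbone forward pass feeds both heads (the cheaper of
the two possible wirings, and consistent with a single feature-extraction
stage).

* Classification head: global average pool → fully connected → softmax;
  loss is the cross-entropy against the one-vs-all label summed over all
  K₁+K₂ views and, at epoch level, over the training set. A probability
  floor of 1e−12 inside the log is a numerical guard, not part of the
  model.
* Index head: per-cell linear (1×1) projection to two channels → tanh →
  adaptive average pooling onto the N×N grid → axis reordering to (N, N, 2).
  The similarity loss is the sum over views and blocks of the per-block
  Euclidean distance in normalized units (a sum of 2-D distances, not one
  global norm, hence additive over views and blocks). Multiplying by Z
  recovers raw index units.
* Total objective: L_c + λ·L_sm. The default λ = 1/N² (≈ 0.028 at N = 6):
  L_sm sums N² per-block terms whose gradients have unit magnitude, so at
  λ = 1 the similarity gradient outweighs the per-view cross-entropy by
  roughly an order of magnitude and measurably degrades classification at
  desk scale; 1/N² enters the similarity term at per-block scale. λ is a
  config field; λ = 0 disables the index path entirely.

**Per-view projections.** The index predictions carry a view subscript
(τ_k, ε_d), and whether the 1×1 projection is shared across views is an
open choice. This implementation gives each view its own projection weights
(`n_views = 1` recovers full sharing). The reason is representational: the
rotation of view k turns the label map into a view-specific linear function
of position, and a single position-local linear-plus-tanh map cannot encode
K different linear maps at once — with a shared head the label-recovery
experiment is unattainable by construction, with per-view heads it
converges.

**Toy backbone.** Three stride-2 3×3 conv + leaky-ReLU stages (widths
8/16/32) and one stride-1 stage, with two fixed coordinate channels
(x, y ∈ [−1, 1]) appended to the output grid so a per-cell linear head can
express positional targets; inputs are centered by subtracting 0.5. Leaky
slopes (0.1) keep units recoverable — plain ReLU nets of this size died
irrecoverably at workable learning rates. The backbone contract is just
image → (C, H, W) grid; heavier backbones plug in unchanged, and the 1×1
index projection and pooling adapt to any grid at least N×N.

## Optimization and the desk-scale configuration

SGD with classical momentum 0.9, global gradient-norm clipping at 5, and
per-group learning rates: backbone 0.01, heads 0.3. (Global-average-pooled
features have ≈ 0.1 std, so the softmax head needs a much larger rate than
the convolutions; clipping keeps the summed multi-view gradient from
destabilizing early epochs.) Batch 5, 100 epochs, rate ×0.1 at epoch 60.
Dataset: 5 classes × 10 images of 48×48, split 5 train / 5 test per class.
48 matters: three stride-2 stages give a 6×6 feature grid that aligns 1:1
with the N = 6 block grid, making the index head's pooling the identity and
its coordinate channels uniformly spaced per block. (At 64×64 the 8×8→6×6
adaptive pooling has irregular bins whose pooled coordinates are not affine
in the block index, which alone leaves ≈ 0.1 mean index error.) With these
defaults the toy run reaches 100% train accuracy in ≈ 20 s on one CPU and
is bit-reproducible under a fixed seed. A full-scale configuration
(384×384, batch 16, lr 0.001, 160 epochs, decay every 60) is expressible in
the same config but untested at that scale.

**Head-only label recovery.** The experiment that isolates the index head
freezes a randomly initialized backbone, builds 50 fixed rotation-augmented
groups (angles 0, π/6, π/4), and trains only the head. Rotation views are
used because their rotation-mapped labels are deterministic functions of
position and view; a shuffled view's labels depend on each image's private
permutation, which no head can predict across images — including shuffles
would put a floor under the error that says nothing about the head.
Because the unsquared Euclidean loss has unit-magnitude gradients until a
block's distance reaches zero, plain SGD stalls at an error floor
proportional to the learning rate; the head trainer therefore halves its
rate every 50 of 400 epochs (start 0.05). Final mean per-block error:
≈ 0.04 normalized units.

## What the synthetic data does and does not show

The toy datasets emulate the *regime* of ultra-fine-grained leaf
classification — few classes, very few training images per class, subtle
within-class jitter (position ≤ 5% of the frame, rotation ≤ 10°, pixel
noise σ = 0.02) — with one parametric silhouette family per class
(disk, cross, triangle, star, annulus, square, ellipse, diamond) at fixed
foreground/background grays (0.85/0.15). They are linearly separable by
design (a pixel-space 1-NN oracle is perfect on two maximally distinct
classes), so passing the end-to-end checks demonstrates that the pipeline
wiring, losses, gradients and determinism are correct — not that the method
improves accuracy on natural images, which requires real cultivar
photographs and a pretrained deep backbone. Natural-image properties the
generator deliberately omits: texture, clutter, lighting variation, scale
variation, and class boundaries defined by genotype rather than geometry.

## Numerical choices and degenerate inputs

* Kernel zero-sum enforced by mean subtraction (≤ 1e−16 residual).
* Extrema ε default 1e−3·max|profile|; all-constant profiles → (0, 0).
* Gray-matching ties broken by raster order; rerun-stable.
* Rotation angles 0 and π short-circuit to exact index operations.
* N = 1: a single block with index (0, 0), Z defined as 1.
* Distances of exactly 0 in the similarity loss get zero gradient (the
  distance is non-differentiable there; 0 is the minimum-norm subgradient).
* Non-finite losses abort training with the offending epoch/batch/sample.
* Checkpoints are single `.npz` archives holding every parameter plus the
  full serialized configuration; training logs are CSV per epoch.

## Known limitations

* The NumPy network is single-device, float64, and sized for desk-scale
  problems; no mixed precision, no multi-GPU, no pretrained weights.
* Structure classification is a fixed-threshold rule on one pixel, not a
  full detector: no non-maximum suppression, no scale-space search over σ.
* The stroke-T geometry is one realization of a T-type junction; wedge
  junctions need higher anisotropy (ρ ≳ 2) before their three-lobed
  signature appears, and their analysis is left to the filter functions.
* Mean-gray matching degrades gracefully but non-uniquely when block means
  collide (e.g., heavily textured images at large N); the bijection is then
  tie-break-determined rather than content-determined.
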