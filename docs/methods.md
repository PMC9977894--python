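# Methods

## The model

GroupCapsNet is a U-shaped capsule network for binary segmentation of
intracranial hemorrhage in non-contrast CT slices.  Its activation unit is
the *capsule*: a vector v whose length ‖v‖ ∈ [0, 1) encodes the probability
that an entity is present at a location and whose orientation encodes the
entity's properties.  A layer carries a spatial grid of T capsule *types*,
each a d-vector.  Forwarding between layers has three steps:

1. **Voting.**  Each input capsule v_t inside the receptive field predicts
   each output capsule through a trainable matrix: u_{t′|t} = W_{t′|t} · v_t.
   Matrices are shared across spatial positions (convolutional capsules).
2. **Clustering.**  Votes are combined with coupling weights,
   v̂_{t′} = Σ_t c_{t′|t} u_{t′|t}, where the couplings come from
   agreement-based dynamic routing: logits start at zero, are normalised by
   a softmax across output types (per contributing capsule), and each of the
   3 iterations adds the scalar product between a vote and the squashed
   current output.
3. **Nonlinear mapping.**  The dominant capsule is squashed,
   squash(v̂) = (‖v̂‖²/(1+‖v̂‖²)) · v̂/‖v̂‖, or through the cheaper modified
   form v̂/(1+‖v̂‖).  Both keep direction, bound length into [0, 1), and
   coincide exactly at lengths 0 and 1; the modified form needs strictly
   fewer floating-point operations per capsule (no squared-norm ratio), and
   is the network-wide default.

**Grouping.**  A grouped layer splits the T input types and the T′ output
types into g equal, disjoint, contiguous index blocks; output block i is
routed only from input block i.  This divides both the number of weight
matrices and the number of intermediate vote capsules exactly by g (the
analytic `count_votes` obeys count(g)·g = count(1) identically).  A grouped
layer with g = 1 is the ordinary non-grouped layer, and for any g the output
equals the concatenation of g independently computed sub-layers — this
block-diagonal equivalence is enforced by tests at 1e-6 in float64.

## Architecture

Variant G#g (g ∈ {1, 2, 4, 8}): a two-convolution stem (16 channels, 3×3,
biases, ReLU between, none after the second — the capsule squashing
follows) is reinterpreted as g initial capsule types of 16/g dims.  Four
encoder stages follow; stage k holds 2·2^(k−1) grouped capsule layers
(2, 4, 8, 16 — doubling stage to stage), the first of which downsamples
with a 2×2 stride-2 kernel.  Types per stage are (g, 2g, 4g, 8g) with
stage 1 keeping the initial g.  The bottleneck of a 256×256 input is 16×16.
Each of the four decoder stages starts with a 2×2 stride-2 deconvolutional
capsule layer doubling resolution, concatenates the matching encoder stage
output along the type axis (group-interleaved, so each group receives its
own decoder and skip sub-blocks), and applies 16, 8, 4, 2 grouped layers
(halving stage to stage).  A 1×1 capsule layer forms the head: one 8-dim
segmentation capsule per pixel; the mask is `length > threshold` (strict
inequality; default threshold 0.5, the midpoint of the attainable range).

**Dimension schedule and weight-total calibration.**  The published stage
rules fix the type schedule but underdetermine the capsule dims, the layer
counts and the kernel bookkeeping, and the literal reading — dims doubling
from 16/g alongside the types — cannot reproduce the published per-variant
weight totals (14.86 M / 22.77 M / 41.75 M / 81.34 M for G1/G2/G4/G8): it
makes totals shrink as 1/g, the opposite ordering, and a single deepest-
stage layer at 128 dims would already exceed G1's entire printed budget.
Interval analysis shows no three-term a + b·g + c/g decomposition can hit
all four printed values within rounding, so some residual is unavoidable.
The resolution pinned here, found by systematic search over dim schedules,
layer counts and kernel-sharing conventions, is:

* encoder dims double from 16 and cap at 32 (16/g, then 16, 32, 32, 32),
  with per-offset 3×3 matrices;
* decoder dims at pyramid level l are (16/g)·2^l, with one matrix shared
  across the kernel per type pair (in both the 3×3 decoder layers and the
  2×2 deconvs);
* head: g·(16/g)·8 = 128 weights.

This yields 14.77 M / 22.73 M / 41.95 M / 82.04 M — residuals of
−0.6%, −0.2%, +0.5%, +0.9% against the published column (max 0.86%).  The
totals remain exact, deterministic functions of the spec and always match a
walk over the instantiated model's arrays.

## Compute core

The forward and backward passes run on a small reverse-mode automatic
differentiation core over NumPy (`groupcapsnet.autodiff`): voting is a
batched matrix product over im2col patches, routing is differentiated
through all iterations, and gradients are validated against central finite
differences in float64, including end-to-end through a grouped layer and a
deconv layer.  Two exact algebraic shortcuts keep CPU training tractable:

* when a group has a single output type, the routing softmax across output
  types is identically 1 whatever the logits, so the dominant capsule is the
  plain vote sum and the whole layer collapses to one batched GEMM over
  (kernel offset × in-group type × dim) — bit-compatible with the general
  path up to float summation order (checked at 1e-10);
* a kernel-shared 2×2 stride-2 deconv gives all four children of a parent
  identical votes, hence identical routing: the layer routes once at parent
  resolution and upsamples the routed field.

Models are float32; tests that compare algebraic identities run float64.

## Preprocessing and augmentation

CT voxels are clipped to the 0–90 HU window and scaled to [0, 1]
(hemorrhage and brain tissue live below 90 HU; acute blood is hyperdense).
Volumes are split into axial slices resized to 256×256 — bilinear for
images, nearest-neighbour for masks so labels stay binary.  Augmentation
applies random horizontal/vertical flips and right-angle rotations to image
and mask together (arbitrary angles behind a flag; right angles avoid
resampling artifacts), then adds zero-mean Gaussian noise to the image only
and re-clips.  The noise parameter N(0, 0.01) is interpreted as a
*variance* (std 0.1) and is exposed as a parameter, since the notation
leaves variance-vs-std ambiguous.  Slices with no hemorrhage are retained
(exclusion is available as an option).  The on-disk slice layout quantizes
images to 16-bit PNG; a save→load→save cycle is bit-stable, and masks are
lossless.

## Training and evaluation protocol

BCE on the segmentation capsule length; Adam at 1e-3 decayed by 0.9 every
60 epochs; at most 250 epochs — the protocol used for all published
comparisons.  (A differently-parameterised semi-supervised description
appears once in the source material's implementation notes and conflicts
with the comparison protocol; only the latter is implemented.)
Cross-validation splits by *volume* (k = 5), never by slice, because slices
of one patient are strongly correlated.  Confusion counts are pooled over
all test pixels of a fold (micro-averaging; stable when lesions are tiny),
with per-slice macro-averaging behind a flag.  Degenerate cases: an image
with empty truth and empty prediction scores 1 on the overlap metrics, and
0 if exactly one is empty.  Ensembling averages per-pixel capsule lengths
(not binary masks) across models before thresholding.

## Synthetic phantoms

The clinical dataset behind the published numbers is private, so every
end-to-end result in this package is computed on synthetic phantoms: an
elliptical skull ring near intensity 1.0, textured parenchyma in 0.28–0.45
(≈25–40 HU after windowing), and lesions drawn as ellipses with low-order
radial Fourier boundary perturbations filled from 0.65–1.0 (≈60–90 HU),
plus Gaussian pixel noise.  Masks are exactly the generative lesion
support — zero label noise.  Phantoms capture the hyperdensity contrast and
irregular lesion shapes the segmenter exploits, but not skull-base
artifacts, partial-volume effects, anatomical context (ventricles, sulci),
or inter-scanner variation; passing the phantom benchmark therefore shows
the architecture and training loop work end to end, not clinical-grade
performance.

## Desk-scale benchmark

The benchmark configuration (`groupcapsnet.benchmark`) is the reduced
GroupCapsNet-G2: 64×64 inputs, two encoder stages (grouped-layer totals
1 and 2) and two decoder stages (2 and 1) — the four-stage U truncated and
its depths halved so one training fits in minutes of a single CPU — trained
on 200 easy phantoms (single/double lesions of 2–8% area, noise σ 0.02) for
16 epochs with the standard protocol, evaluated on 50 held-out phantoms.
All seeds derive from one master seed; reruns are bit-identical on the same
platform.  Under these conditions held-out Dice reaches ≈0.95 for both
squashing variants, and the modified form tracks the original within the
ablation tolerance of two Dice points.

## Known limitations

* The weight-total calibration is closest-achievable, not exact (above).
* Timing claims are hardware-dependent and are replaced by analytic vote
  and operation counts.
* The phantom benchmark bounds what the tests demonstrate about real CT
  (above); the published clinical scores are not reproducible without the
  private data.
* Matrix capsules, EM/KDE routing variants, capsule pooling and
  reconstruction regularisation are out of scope.
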