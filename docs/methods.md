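# Methods

This note documents the models, numerical choices and deliberate design
decisions inside `cephalorl`, and what the synthetic-phantom experiments
do and do not demonstrate.

## Coordinate conventions

World coordinates are millimetres with x the transverse (left-right)
axis, y anterior-posterior and z vertical. Voxel indices are 0-based,
ordered (x, y, z), related to world space by `world = origin + index *
spacing`; both directions are exact affine maps (round trip ≤ 1e-9 mm).
DICOM series are rescaled (slope/intercept) so voxels are true Hounsfield
units, and all loaders clamp HU to [−1024, 4000] — air through dense
enamel. Non-uniform DICOM slice gaps are rejected rather than resampled.

## Volume rendering

Views are orthographic with axis-aligned rays, chosen over perspective
because every view used by the detection plans is an anatomical axis
view, and parallel rays make the pixel↔world map affine and exactly
invertible — the property the whole 2D→3D assembly rests on. The image
centre maps to the volume centre; the scale is fixed so the larger
in-plane extent of the volume fills 15/16 of the image width (480 px of a
512 px image).

Compositing is front-to-back with a piecewise-linear transfer function.
The bone preset is fully transparent below 200 HU, fully opaque from
700 HU, with brightness ramping over 200–1500 HU; opacity is interpreted
as extinction per millimetre of path (`α_step = 1 − (1−α)^Δs`). Samples
are taken every half voxel along the ray by linear inter-slice
interpolation, with early termination at accumulated opacity 0.99.
Because the rays are axis-aligned, compositing is performed on the
volume's in-plane voxel grid (vectorised across slices) and the result is
resampled bilinearly onto the output pixel grid; for parallel rays this
is equivalent to per-pixel marching up to interpolation order and is two
orders of magnitude faster on CPU.

Brightness is attenuated by exp(−depth/τ), τ = 40 mm, measured from the
volume face along the ray. Without a lighting model an opaque bone
silhouette would be flat; depth cueing is the standard minimal substitute
that makes surface relief and cut cavities visible, and it preserves
translation invariance of the render. Exact transfer-function windows and
shading for clinical CT viewers are vendor-specific; these values were
chosen once for good phantom contrast and are exposed as parameters.

Cutaway views force opacity to zero on one side of an axis-aligned plane
while leaving HU untouched. Each cut view code keeps the far side of the
plane relative to its viewer, so the cut always exposes interior
structure facing the camera.

## The landmark MDP

The environment is one rendered view with a ground-truth target pixel.
States are stacks of the k most recent patches, each cropped as a
(patch·zoom)² window centred on the agent, zero-padded at borders and
area-averaged to patch² — coarse scales see global context, the finest
sees native resolution. The reward is the decrease in Euclidean pixel
distance to the target; it telescopes exactly, so episode return equals
start-minus-end distance, which the tests assert to machine precision.
Transitions are deterministic; moves clamp at the image border (no abort,
no wraparound, keeps patches well defined).

Rollout details not fixed by the published description are set as
follows: training episodes start uniformly inside the central 80% of the
image, begin at the coarsest scale, and descend one scale whenever the
agent comes within `success_radius × zoom` pixels of the target
(success_radius = 1 px, i.e. 1 px at the finest scale); reaching the
radius at the finest scale, or exhausting the per-scale step budget, ends
the episode. Structuring episodes coarse-to-fine mirrors the inference
procedure and concentrates fine-scale experience near the target, which
is what makes the fine-scale Q-function accurate where it matters; with
independently sampled scales the fine-scale agent rarely sees the target
at all. The stored transition at a scale switch remains terminal for
that scale's value function.

## Double-DQN learner

The Q-network is built to the published architecture by default
(128×128×4 input; conv 32@5×5, 32@5×5, 64@3×3, 64@3×3, stride 1, each
followed by leaky ReLU and 2×2 max-pool stride 2; fully-connected
512/256/128 rectifiers and a linear 4-output head; Glorot-uniform
initialisation). Layers, backpropagation and Adadelta (ρ = 0.95,
ε = 1e-6) are implemented in numpy (im2col + GEMM convolutions, float32),
which is entirely adequate at the patch sizes the agents use and keeps
training bit-reproducible for a fixed seed on a given machine.

The loss is the squared Double-DQN temporal-difference error: the online
network selects the bootstrap action, the frozen target network evaluates
it, terminal transitions drop the bootstrap term. No Huber loss is used;
stability comes from the element-wise gradient clipping to [−1, 1].
Replay is a FIFO buffer with uniform sampling without replacement within
a batch; the target network is refreshed every C = 500 optimiser steps
(a convergence-checking choice, configurable). Exploration is ε-greedy,
linear 1.0 → 0.1 over the first half of training, then constant — the
standard DQN schedule. One model is trained per (landmark, view) pair.

Inference is greedy from the image centre at the coarsest scale. A
position revisited 4 times at a scale counts as oscillation: at coarse
scales it triggers descent, at the finest scale it terminates and the
most frequently visited position wins (ties broken by earliest visit).
The revisit threshold of 4 is the smallest count that cannot be produced
by a single crossing of a 2-cycle.

## Boundary depth estimation

Single-stage detection recovers the third coordinate from the 1D HU
profile along the predicted pixel's ray, sampled trilinearly every half
of the smallest voxel spacing. The profile is mapped through
`IE(x) = tanh((x − L)/W)` with L = 400 HU, W = 200 HU — a soft bone
threshold that compresses air/soft tissue toward −1 and bone toward +1 —
then denoised by explicit 1D Perona–Malik diffusion (conductance
`g(d) = 1/(1 + (d/κ)²)`, κ = 0.25 in post-enhancement units, 10
iterations, time step 0.2, under the 0.5 stability bound, zero-flux
ends). A structure-tensor formulation degenerates in 1D, so the scalar
edge-preserving scheme is the faithful reduction: it removes noise
without losing the gradient. The boundary is the *first* local maximum
of the derivative along the ray exceeding half the global maximum — the
outer cortical surface — rather than the global argmax, which can fall on
the inner table. Profiles that never cross L in both directions raise a
"no boundary" error and the pipeline records a failure instead of
fabricating a coordinate.

## Staged assembly

Plans are YAML data: landmark, Bookstein-type tag, mode (single /
two-stage / three-stage) and ordered view codes. Validation enforces that
the stages jointly cover all three world axes and that every cutaway at
stage ≥ 2 cuts along an axis some earlier stage predicts. First-stage
cut views (e.g. the median sagittal cut used for sella) cut at the volume
median. When two stages predict the same axis, the latest stage wins:
later views are cutaways localised by earlier predictions and hence
better conditioned. Training environments for stage ≥ 2 build their
cutaways from ground-truth coordinates (teacher forcing); at inference
the cut comes from the previous stage's prediction, a mild distribution
shift that the phantom study shows to be benign.

## The phantom generator

Each phantom (default 64³ voxels at 1 mm) is an ellipsoidal cortical
shell (1200 HU, 4 mm thick, radii ≈ 18/21/19 mm) with a 1.5 mm soft
tissue layer (40 HU) and air (−1000 HU) elsewhere, plus three
landmark-bearing features mirroring the geometric classes of
cephalometric landmarks: an anterior surface protrusion (apex =
`proto_ans`), an internal bone mass with a spherical air cavity (centre =
`proto_sella`), and a canal through the lower shell wall (outer-surface
axis point = `proto_foramen`). Truths are computed in continuous world
space from the jittered analytic geometry before rasterisation, so
sub-voxel error is measurable; feature/truth agreement after
rasterisation is within one voxel by construction. Per-subject variation
is uniform ±1.5 mm jitter of shell centre and radii (rejection-sampled
against geometric invariants, error after 100 draws), and additive
Gaussian HU noise with σ = 30 HU, a typical clinical CT noise level. HU
levels were chosen so the L = 400/W = 200 enhancement separates bone from
non-bone exactly as on real CT.

What the phantom does *not* emulate: real cranial anatomy and its
inter-subject shape variation, trabecular texture, beam-hardening and
metal artefacts, anisotropic voxels, and landmark ambiguity on smooth
anatomy. Passing phantom studies therefore demonstrates that the
*system* — rendering, geometry, learning, staging, boundary estimation —
is correct and trainable; it does not certify clinical accuracy on
patient CT, which requires training on annotated clinical data at full
problem size.

## Problem sizes

Two canonical configurations ship in `cephalorl.presets`:

* `paper_scale`: 512 px views, 128×128×4 states, the full network, batch
  96, replay 10⁶ — the published configuration, intended for GPU-class
  hardware and days of training per landmark.
* `desk_scale`: 128 px views of the 64 mm phantom (≈0.53 mm/px), 24 px
  single-frame states, conv 8@5×5 + 16@3×3 with one 64-unit hidden
  layer, batch 32, 5000 environment steps per agent. This is the size at
  which the package trains and validates the complete method on one CPU
  in minutes; the algorithm is identical, only the problem size changes.

The validation study trains one agent per (landmark, view) pair on 15
phantoms and evaluates on 5 held-out phantoms (mirroring a 20/8-style
subject split at reduced n), for the surface landmark (single- and
two-stage) and the cavity landmark (two-stage). Typical held-out mean 3D
errors are ≈0.6–1.1 mm, i.e. ≈1 voxel, with the oracle-policy baseline
isolating all plumbing error below one voxel.

## Known limitations

* Training determinism is bit-exact for a fixed seed on a fixed
  machine/BLAS; across different BLAS builds the floating-point reduction
  order may differ.
* The most-visited termination rule can return a position adjacent to
  the optimum when the greedy policy orbits it; errors are bounded by the
  finest step size.
* Detection-rate thresholds use strict inequality (an error exactly at
  the threshold does not count as detected).
* The statistical machinery stops at means, standard deviations (n−1)
  and detection rates; raw per-subject errors are exported so any
  significance testing can be done externally.
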