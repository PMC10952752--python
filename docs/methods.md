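# Methods

## The loop being simulated

The package models an intrinsic-navigator prospective motion-correction loop
for dynamic EPI of the fetal brain. Per repetition *n*: the volume is
acquired at the controller's current FOV center, a localizer produces a
binary brain/object mask, the mask is reduced to its world-frame center of
mass (CoM), the CoM displacement between repetitions *n* and *n−2* is
recorded as the motion signal, and a recentering shift is queued. The
feedback path has a configurable latency (default two repetitions): a step
translation first visible in the image at repetition *r* changes the FOV of
the image acquired at repetition *r+2*.

**Correction signal.** The raw *n* vs *n−2* CoM displacement stays nonzero
for two consecutive frames after a step, so feeding it back directly at
every repetition would correct the same motion twice. The controller
therefore drives the FOV with a *pending-aware absolute recentering* term,
`com(n) − fov_center(n) − Σ(queued, not-yet-applied shifts)`, while still
reporting the n/n−2 displacement in every record. Under noise-free
acquisition and step motion at voxel-multiple magnitudes this produces
exactly one shift per motion event and zero residual afterwards; this is the
package's own stabilisation choice, since feedback internals of deployed
systems are generally not published in this detail.

**Safety gates.** Corrections are suppressed (and flagged) when the mask
volume falls outside configurable plausibility bounds — motivated by the
known failure mode in which fluid-filled maternal structures (the stomach)
are segmented together with or instead of the brain, which would otherwise
yank the FOV. Shifts are clipped per axis to `max_shift_mm` (default: half
the FOV extent), an empty or failed localization holds the current FOV, and
a localizer exception never aborts the loop.

## Coordinate conventions

World units are millimetres; axes are x right→left, y bottom→top, z
front→back of the bore. Voxel indices are 0-based and the grid "center" is
the continuous midpoint index `(shape−1)/2`, which maps exactly onto the
geometry's `fov_center`; even-sized grids therefore have a half-voxel-offset
center, and the voxel↔world maps are exact inverses of each other. NIfTI
affines are written as `diag(spacing)` with the translation chosen so the
grid midpoint lands on the FOV center. Repetition indices are 0-based
internally; scan-style 1-based numbers appear only in printed reports.

## Acquisition simulator

Image formation is geometric: each voxel center is tested against the
analytic scene components (sphere/ellipsoid/box; later components overwrite
earlier ones; only the tracked target moves along the trajectory), and the
occupying component contributes the mono-exponential gradient-echo signal
`S0·exp(−TE/T2*)`. Optional additive Gaussian noise (clipped at zero, since
magnitude images are non-negative) is seeded per repetition — stream
`(base_seed + repetition, TE)` — so any frame is reproducible in isolation.
No k-space effects (distortion, ghosting, coil sensitivities) and no
intra-volume motion are modelled; single-shot readouts are assumed to freeze
motion within a volume.

The default phantom protocol mirrors a controlled scanner experiment:
isotropic 3.0 mm voxels, 50 repetitions, TE 90 ms, an agarose-like sphere
(radius 40 mm; S0 = 100, T2* = 60 ms against air), and five step
translations of ±9/±6 mm (multiples of the voxel edge, so recentering is
numerically unambiguous). The grid is 64³ (192 mm FOV) — a desk-scale
stand-in for clinical matrices that leaves the loop behaviour unchanged.
T2* values for phantom and tissue are fixture choices of this package, not
measured values.

## Localizers

**Intensity path (phantom).** Otsu threshold → largest 6-connected
component → internal hole filling. Invariant to global positive intensity
scaling; an all-zero volume yields a flagged empty mask.

**Network path (fetal).** A 3D U-Net with five encoder–decoder levels,
channels (32, 64, 128, 256, 512); each stage is two repeats of 3×3×3
stride-1 convolution + instance normalization + LeakyReLU; 2×2×2 average
pooling after the first two encoder stages and 2×2×2 max pooling after the
next two; the decoder mirrors the encoder with factor-2 trilinear
upsampling, concatenation skip connections, and a final 1×1×1 convolution to
N = 2 classes (background, brain). Binarization is per-voxel argmax with
exact ties going to background; no probability threshold is introduced.
Inputs are normalized per volume to [0, 1] between the 1st and 99th
intensity percentiles.

The network runs on a small pure-numpy substrate with hand-written
forward/backward passes (`fetaltrack.nn`); 3×3×3 convolutions are executed
as 27 BLAS matrix multiplies, one per kernel offset. Backpropagation is
verified against float64 finite differences (directional-derivative
agreement to ~1e-8) and the trilinear upsampler against its adjoint
identity. One caveat surfaced by those tests: a 1³ bottleneck makes
instance norm degenerate (output = β exactly, on the LeakyReLU kink), so
gradient checks and training use inputs ≥ 32³ for 5-level nets.

**Loss.** Training minimises the generalized Dice loss over M = 2 classes
with inverse-squared-volume weights `w_k = 1/(Σ_n t_kn)²`, optimised with
Adam (β₁ = 0.9, β₂ = 0.999). When a class is absent from the target the
weight diverges; it is clamped at `1/ε²` with ε = 1e-5 voxels, keeping the
loss finite without touching present-class behaviour. The loss
implementation is cross-checked against an exact-summation double-loop
evaluation to 1e-10.

**Free training parameters.** Learning rate (default 1e-3; the shipped
experiments use 3e-3 with cosine decay), epochs, batch size, flip/noise
augmentation and the patch size are free parameters — only the optimizer
family, its betas and the loss are fixed by the deployed design. Training
draws random 32³ patches (half centered on the target with jitter, half
uniform, the latter supplying negative supervision on the confounder);
inference runs on full volumes. A reduced "small" profile — the same
five-level family with channels (8, 16, 32, 64, 128) at a 64³ input — keeps
CPU training tractable; the faithful (32…512)/128³ configuration remains
the default for architecture-fidelity checks and is what `NetworkSpec()`
builds.

## Synthetic training scenes

Each scene is an ellipsoidal "head" (radii 20–32 mm per axis, mid-gestation
scale), randomly placed (±24 mm), with S0 ∈ [90, 110] and T2* ∈ [50, 70] ms;
a spherical fluid-like confounder (radius 10–18 mm, T2* ∈ [100, 140] ms)
placed 55–80 mm away whose signal at TE 90 ms overlaps the head's — so
intensity alone cannot separate them — and dim maternal background
(S0 ∈ [15, 25], T2* ∈ [25, 35] ms), acquired at 3 mm / TE 90 ms with noise
σ = 1 (SNR ≈ 20 relative to head signal ≈ 22).

What these scenes do *not* emulate: EPI distortion and ghosting, B0/B1
inhomogeneity, cortical texture and gyration, maternal anatomy beyond one
confounder, partial-volume boundaries (rasterization is binary at voxel
centers), through-plane anisotropy, and rotations. Passing the parameter-
recovery experiment therefore demonstrates that the architecture + loss +
optimizer pipeline can learn shape-and-size-based discrimination from
realistic geometry and contrast — not that the shipped weights would
segment clinical EPI. The headline clinical Dice figures of real-data
studies require real training corpora and are out of scope here.

## Evaluation

DSC and IoU use the convention that two empty masks agree perfectly (both
metrics 1) and exactly one empty mask scores 0, avoiding 0/0; for binary
masks `IoU = DSC/(2−DSC)` holds exactly and is used as a cross-check. CoM
trajectory error is reported per axis as both the mean of squared
differences (mm²) and its square root (mm), since "MSE in mm" tables are
dimensionally ambiguous; pairs with a missing CoM are excluded pairwise, and
the spread is the population s.d. (ddof = 0, so a single pair reports 0).
Grouped summaries report mean ± s.d. per echo-time index, gestational-age
class (≤23 / >23 weeks) or presentation (cephalic/breech); no hypothesis
tests are attached.

The phantom experiment report asserts two properties: every FOV correction
lands exactly `latency` repetitions after its motion event, and the
image-frame CoM of every corrected repetition matches the first
repetition's CoM within 1 voxel.

## Problem sizes and determinism

The shipped experiments run on one CPU core: tracking runs use a 64³ grid
(≈ 2 s for 50 repetitions noise-free), training runs use 32 scenes × 16
epochs of 32³ patches with the small profile (≈ 3–4 min per seed), and the
parameter-recovery experiment repeats that for seeds {0, 1, 2}. All
randomness flows from explicit integer seeds through numpy Generators:
acquisition noise from `(seed + repetition, TE)`, training shuffles,
augmentation and initialisation from the training seed — identical seeds
reproduce histories bitwise on a given platform.

## Known limitations

Translation-only correction (no rotation estimation); inter-volume motion
only; the acquisition model omits all k-space physics; the latency is
simulated as an exact integer delay rather than a measured computation/
communication time; instance norm makes predictions sensitive to
field-of-view content (tiled inference degrades markedly — documented here
because it constrains how the network may be deployed); and the evaluation
harness exercises the computation of the clinical metrics on synthetic
data, not clinical performance itself.
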