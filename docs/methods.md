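# Methods

## The registration model

`frrreg` estimates a dense displacement vector field (DVF) φ that aligns a
moving 3D volume I_m to a fixed volume I_f, with the backward-warping
convention

    I_w(v) = I_m(v + φ(v)),

sampled by trilinear interpolation with border clamping. Displacements are in
voxel units on a canonical isotropic grid (96×96×96 for production use);
components and axes are ordered (z, y, x) throughout.

The predictor is a recursive cascade of three convolutional subnetworks.
Subnetwork n receives the fixed image and the current warped image stacked as
two channels and predicts an incremental field φ_n; the moving image is warped
successively,

    I_w,n = I_w,n−1 ∘ φ_n ,  I_w,0 = I_m ,

and the total transform is the composition φ = φ_1 ∘ φ_2 ∘ φ_3 with

    compose(earlier, later)(v) = later(v) + earlier(v + later(v)),

so that one warp by the composed field agrees with sequential warping up to
interpolation error. The three subnetworks deepen progressively — (5 FRRU
blocks, channel cap 128), (7, 256), (9, 512), base 32 channels — so the first
cascade absorbs coarse global motion and the last refines it.

Each subnetwork is a full-resolution residual network: a residual stream that
stays at full resolution (boundary detail) and a pooling stream that descends
an encoder–decoder ladder (texture/context). A full-resolution residual unit
(FRRU) at pooling level L max-pools the residual stream to level L,
concatenates it with the pooling stream, applies two 3×3×3 conv + BN + ReLU
layers, and returns the result to the residual stream through a 1×1×1
projection and nearest-neighbour unpooling, added as a residual:

    x_n = x_{n−1} + Fr(x_{n−1}, y_{n−1}),   y_n = Fp(x_{n−1}, y_{n−1}).

The ladder layout is a symmetric V: for n blocks the levels are
1,…,(n+1)/2,…,1 (e.g. 5 → 1,2,3,2,1), channels doubling per level up to the
cap. The ladder is flanked by plain residual-unit pairs at full resolution,
and the network opens with a 3×3×3 convolution from the 2-channel stack to the
base width and closes with a 3×3×3 convolution to 3 channels. The closing
convolution is **zero-initialized**, so an untrained cascade is exactly the
identity transform — the recursion then starts from a sensible operating point
and the early loss surface is governed by the first cascade only. All other
convolutions use He initialization.

Training is unsupervised:

    L = MSE(I_f, I_w,3) + α · L_smooth(φ),

where the smoothness term is a diffusion regularizer — squared forward finite
differences of each field component along each axis, interior voxels only.
Defaults follow the production configuration: α = 0.01, the regularized field
is φ_3, and the penalty is **mean-reduced** so that α keeps its meaning across
grid sizes (the literal sum is available via `reduction="sum"`). Optimization
is Adam at batch size 1 for 9×10⁴ iterations, learning rate 10⁻⁴ halved after
3×10⁴ and 6×10⁴ iterations; pairs are sampled uniformly with replacement from
the enumerated pair list with a seeded generator, so runs are reproducible
bit-for-bit.

## Numerical core

No GPU framework is used: the networks run on a small reverse-mode autodiff
engine over NumPy arrays (`frrreg.autodiff`) providing exactly the operations
the model needs (3D convolution as shifted channel matmuls, 2× max-pooling,
nearest unpooling, batch normalization, ReLU, slicing, reductions) plus the
differentiable trilinear sampler. Every operation is verified against central
finite differences in the test suite, and an end-to-end gradient check runs
through the full cascade including the warps. Arithmetic is float64 in the
desk-scale configurations; float32 is available for the production-sized
networks.

Two numerical decisions deserve note:

* **Border policy.** Sample coordinates outside the volume are clamped to the
  border; the gradient with respect to the field is zero where the coordinate
  was clamped. This avoids injecting artificial zeros at organ boundaries near
  the volume edge.
* **Normalization statistics.** With batch size 1, spatial batch normalization
  is instance normalization. Running-average statistics are tracked but *not*
  used at inference by default: at the deepest ladder levels the spatial
  extent is a handful of voxels, running variance estimates collapse toward
  zero, and normalizing unseen volumes with them diverges (measured: held-out
  endpoint error ~315 voxels with running statistics vs 0.93 with per-volume
  statistics in an otherwise identical experiment). Per-volume statistics at
  inference are the default; `BatchNorm3d(use_running_stats=True)` restores
  the conventional behaviour.

## Volumes and intensity bookkeeping

Input volumes (NIfTI or MetaImage) are center-cropped to the largest cube
fitting the in-plane field of view, resampled trilinearly to the canonical
grid, clipped to an HU window (default −1000…1000) and mapped affinely to
[0, 1]. The window is kept on the `Volume` so RMSE can be reported in HU after
registration; NCC, SSIM and Dice are computed on normalized intensities. SSIM
is the single global value from whole-region statistics (no sliding window),
with C1 = (0.01·L)² and C2 = (0.03·L)², L = 1 on normalized data. ROI boxes
(canonically 30×30 in-plane × 5 slices over organs with large respiratory
motion) are reported alongside the global row; Dice is per-ROI only, from a
configurable intensity threshold (default 0.5) or, on phantoms, from the true
warped organ labels.

## The motion phantom

The synthetic generator emulates the structure of an abdominal 4D-CT series
cropped to the patient:

* a torso-like body slab (superellipsoid, exponent 4) spanning the axial
  extent and ~2/3 of the voxels, over an air background;
* ellipsoidal organs (liver, stomach, lung surrogate) with distinct pseudo-HU;
* spatially correlated fat/muscle/parenchyma mottle (150 pseudo-HU at a
  2-voxel correlation length) plus ~40 focal vessel/gas-like features
  (200–700 HU) — the image content that makes dense registration well-posed
  inside otherwise uniform organs;
* a partial-volume blur (σ = 1 voxel) reflecting that a resampled CT is
  band-limited, then white acquisition noise (15 pseudo-HU);
* one smooth random motion field (Gaussian-smoothed white noise), attenuated
  by a blurred body mask so the surrounding **air is static**, rescaled to a
  chosen peak displacement, and modulated sinusoidally across phases
  (amplitude 0 at the reference phase, 1 at mid-cycle).

Phase k is the base volume backward-warped by the phase-k field, so the stored
field is *exact* ground truth for registering the reference phase onto phase
k, and labels follow by nearest-neighbour warping. Same seed, same series,
bit-for-bit.

Design rationale worth recording: two earlier drafts of the generator were
rejected on identifiability grounds. A field that displaces featureless air
cannot be recovered by any registration method, so air is static; and white
noise carries almost no registration signal because trilinear interpolation
does not preserve it under subvoxel shifts, so tissue texture is spatially
correlated. A control experiment that optimizes a free-form field directly
under the package's own loss (no network) verifies that the ground-truth field
is recoverable under the final conditions.

What the phantom does **not** model: CT/CBCT projection physics, sliding
interfaces (pleura), intensity change with respiratory state, and XCAT-grade
anatomy. The CBCT-like mode is only a higher noise floor plus a crude streak
pattern. Conclusions from phantom studies therefore speak to the correctness
and trainability of the implementation, not to clinical accuracy.

## Desk-scale studies

The heavy validation runs on CPU at deliberately reduced size (the package's
own choice of problem scale): 16³ grids, reduced cascade specs
(3, 16)/(5, 32)/(7, 64) at base 8 channels, peak displacement 3 voxels, motion
correlation 4 voxels.

* **Single-pair overfit** — one phantom pair, 300 iterations: the similarity
  term must fall below 10% of its initial value, with a non-increasing
  smoothed (window 50) loss curve.
* **Patient-specific recovery** — the cascade trains on 8 phase pairs of one
  phantom series and is evaluated on the 2 held-out ground-truth pairs
  (phase combinations never seen in training), mirroring the within-series
  4D-CT protocol in which every phase is registered to a reference. Reported:
  mean endpoint error relative to the mean true displacement, before/after
  RMSE (HU), NCC, SSIM and liver Dice, and per-cascade RMSE (which decreases
  monotonically from cascade 1 to 3 — progressive registration).
* **Composition consistency** — one-step warping by the composed field versus
  three-step sequential warping on a smooth 32³ phantom (mottle only, no
  focal features) with three random smooth fields.

For these studies the training profile is Adam at 10⁻³ (halved at 1/3 and 2/3
of the run — the production schedule's shape) and the regularizer acts on the
**composed** transform at α = 0.02. The strength was calibrated on the
direct-optimization control above: with the spec's mean-reduced penalty,
α = 0.01 on φ_3 alone is too weak at this scale to prevent "interpolation
forgery" (fields that match intensities without matching the true motion).
Production defaults are unchanged.

Known limitation: **cross-phantom generalization is out of reach at this
scale.** With only 8 training pairs an amortized learned registration model
memorizes the training series rather than learning generic correspondence;
held-out-*subject* endpoint error stays at ~the magnitude of the true motion
even as image similarity improves severalfold. Learning population-level
registration requires training data and iteration counts orders of magnitude
beyond a desk-scale run (the production protocol enumerates 1320 pairs and
runs 9×10⁴ iterations). The recovery study is therefore within-series by
design, and passing it demonstrates correct end-to-end mechanics and
patient-specific trainability, not population generalization.

## Degenerate inputs and tie-breaks

NCC raises on constant images (zero variance); Dice of two empty masks is
defined as 1; max-pooling ties resolve to the first index (deterministic
backward routing); `random_smooth_dvf` with zero amplitude returns the exact
zero field; composition and warping validate shapes and raise
`ShapeMismatchError` on disagreement. The LR schedule is piecewise-constant
with drops applied strictly after the stated iteration.
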