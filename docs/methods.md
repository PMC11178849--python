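# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the desk-scale experiments
show. It is the design record of the package; the README covers usage.

## Problem

Brain age is the age predicted from structural neuroimaging; its deviation
from chronological age (the *brain-age gap*, predicted − chronological) is
an index of brain health and is elevated in neurodegeneration (mild
cognitive impairment, Alzheimer's disease). The package implements
volumetric CNN regressors that map skull-stripped T1-weighted volumes (or
anatomical-region channels extracted from aseg-style label maps) to a
scalar age in years.

## Architectures

All networks operate on channels-last cubes `(N, D, H, W, C)` and end in a
scalar regression head.

**Convolution block**: 3×3×3 convolution (padding 1) → group normalization
→ ReLU. Group normalization is used everywhere instead of batch
normalization because the protocol batch size is 4, which makes batch
statistics too noisy; per-sample statistics also make evaluation exactly
independent of batch composition. The group count defaults to 8 and is
clipped to a divisor of the channel count.

**Basic (residual) block**: two convolution blocks plus an identity skip
added to the output, with a 1×1×1 projection when channel counts or strides
differ. There is deliberately no activation after the addition: with all
convolution weights and biases zero, normalization emits its (zero) shift
and the block reduces exactly to the identity map — a testable null case.

**Trible Res Block** (three-path multi-scale fusion): given a feature map
with `c` channels,

* path 1 is the identity (no operations; the input values appear verbatim
  in the output),
* path 2 upsamples ×2 (trilinear), applies two convolution blocks with
  `p = path_channels` outputs, then max-pools ×2 back,
* path 3 max-pools ×2, applies two basic blocks (`p` outputs), then
  upsamples ×2 back.

The three aligned maps are concatenated on the channel axis, giving
`c + 2p` channels at unchanged spatial size. Inputs with odd spatial
dimensions are rejected rather than silently padded. Each feature level
thus carries its own scale plus information restored from a finer scale
and abstracted from a coarser one.

**Tri-UNet**: a depth-`d` 3D U-Net encoder–decoder (channels double per
encoder level, halve per decoder level, concatenating skip connections)
with one Trible Res Block on each skip path, whose full-resolution decoder
output feeds a 3D ResNet-34 regression tail. No voxel-wise age map is
produced; the decoder output goes to the head whole.

**3D U-Net baseline**: the same encoder–decoder without the Trible Res
Blocks (a strict sub-model by parameter count), same tail.

**3D ResNet-34**: the canonical stage plan 3, 4, 6, 3 with widths
`w, 2w, 4w, 8w`, a stride-2 stem (7×7×7 at input edge ≥ 64, else 3×3×3 —
small inputs would otherwise be dominated by the stem's receptive field),
2×2×2 max-pooling, global average pooling and a linear scalar output. Five
downsampling stages take a 32-cube to a single voxel; smaller inputs
saturate at 1³ (minimum supported edge 16). Standalone region networks use
the canonical width `w = 64`; used as the Tri-UNet tail the width follows
`head_width` (default 32), scaled to the 32-cube regime.

**Multi-channel region input**: one network whose first convolution accepts
`C ≥ 2` channels, each the volume masked to one anatomical region (e.g.
hippocampus + amygdala, or a region's left/right halves) — not an ensemble
of per-region networks with averaged outputs. Region inputs are masked
full-grid volumes by default; `trim_zero_margins` is available to crop the
all-zero margins but is off by default.

**Output calibration**: the final linear unit feeds a fixed affine map
`age = 35·z + 53.5` (years), centering the untrained network's output on
the adult lifespan midpoint. This removes the many optimizer steps that
would otherwise be spent dragging an output bias from 0 into the age range
at the fixed learning rate of 0.001; the calibration constants are
configurable and not fitted.

**Defaults** at input edge 32: `base_channels 8, depth 3, path_channels 4,
head_width 32`. The side paths run at half the trunk width and the
in-network tail at half the canonical ResNet width so that the upsampled
path-2 convolutions (which operate on 2×-enlarged grids) and the tail do
not dominate single-CPU training; all widths are configuration fields. At
edge 128 the defaults scale up (`base 16, depth 4, head_width 64`).

## The autodiff engine

No deep-learning framework is part of the runtime: the networks run on a
compact reverse-mode autodiff engine (`triunet.nn`) written on numpy.
Convolutions lower onto im2col + GEMM with the gather chunked to a fixed
byte budget; for unit stride the input gradient is computed as a
convolution with spatially flipped, channel-transposed weights, reusing the
same fast path. Trilinear ×2 upsampling is implemented as a separable
linear operator whose gradient is its transpose, applied axis by axis.
Max-pooling backpropagates through a one-hot argmax (first maximum wins on
ties). All arithmetic is float32. Every primitive's gradient is verified
against central finite differences in the test suite. On glibc systems the
engine raises the malloc mmap/trim thresholds at import so the large
per-step scratch buffers stay resident between steps (roughly halves step
time on one CPU); this is a no-op elsewhere.

## Synthetic aging-brain phantom

The phantom is a geometric cartoon of an aging brain on a 32-voxel cube
(1 mm nominal spacing), not an MRI simulation. For effective age `a_eff`
(chronological age + disease-group offset; offsets HC 0, MCI-like +5,
AD-like +10 years, configurable):

* **Brain**: an ellipsoid with semi-axes (14, 15, 13) voxels; cortex
  intensity `100 − 0.3·(a_eff − 18)` (arbitrary units).
* **Ventricle**: a central zero-intensity ellipsoid of fixed shape ratios
  (4.5, 4.5, 7.0), scaled so its volume fraction of the brain is
  `f(a_eff) = 0.045·(1 + 0.04·(a_eff − 18))` — the dominant age signal,
  affine in age and hence invertible in closed form.
* **Regions**: four spheres (left/right hippocampus 17/53, left/right
  amygdala 18/54, aseg label codes) at fixed fractional positions inside
  the brain, radius `2.5 − 0.0125·(a_eff − 18)` voxels, intensity 0.8× the
  cortex.
* **Noise**: additive Gaussian (default σ = 5), clipped at zero. The label
  map is geometric and noise-free by construction.

Ages are drawn uniformly on the configured range (default [18, 89]) rather
than from an empirical cohort histogram: the simplest distribution with
full-range coverage. The atrophy rates are invented, not calibrated to any
cohort; they were chosen once so that (i) every structure stays strictly
inside the brain at the maximum effective age (99 years) — verified
numerically at construction — and (ii) the per-year change in ventricle
voxel count (~18 voxels/year) is an order of magnitude larger than the
lattice-counting jitter of rasterizing an ellipsoid (~10–15 voxels), so the
age signal dominates voxelization error. Under these defaults the linear
oracle (least squares of age on label-map ventricle fraction) recovers age
with an in-sample MAE of ≈ 0.7 years on noise-free cohorts of 100.

What the phantom does *not* emulate: MRI physics (bias fields, partial
volume, k-space artifacts), anatomical variability between subjects at
equal age (the geometry is deterministic given age and group), registration
or skull-stripping errors, and nonlinear or region-heterogeneous atrophy
trajectories. Passing tests therefore show that the pipeline can extract a
volumetric atrophy signal end to end — not that it reaches any particular
accuracy on real cohorts.

## Training protocol

Adam with learning rate 0.001, 60 epochs and batch size 4 are the protocol
defaults; the split is a seeded random 80/20 partition (train size
`floor(0.8·n)`), with the validation split doubling as the test set and
disease cohorts entirely held out. The loss defaults to L1 (aligned with
the MAE headline metric; MSE selectable) — the choice is a documented
assumption. No learning-rate schedule, weight decay or early stopping is
applied; the best-epoch state (lowest validation MAE) is restored at the
end and the full per-epoch trace reported. Run summaries MinMAE / MaxMAE /
MeanMAE are the minimum / maximum / mean of the per-epoch validation MAE of
one run — the only reading under which a per-model (Min, Max, Mean) triplet
is well defined; summarizing repeated runs instead is a possible
alternative reading. All randomness (init, split, batch order) derives from
one seed, and a fixed seed reproduces the metric trace bit for bit.

Intensities are fed raw by default (`normalize=false`): the first group
normalization makes the network scale-invariant anyway, and per-volume
z-scoring is available as an option.

## Desk-scale experiment sizes

The packaged acceptance experiments (test suite and
`scripts/acceptance.py`) use: a training cohort of 200 noise-free phantoms
at edge 32 (160/40 split), the default Tri-UNet, 4 epochs — the validation
MAE falls below half the mean-age-predictor baseline (~17.5 years for
uniform ages) by epoch 3 of the study protocol — and matched-age test
cohorts of 50 subjects per group (HC / MCI-like / AD-like) for the gap
analysis. These sizes were chosen as the smallest run on which the learning
and gap-ordering properties are clearly resolved; they are configuration
values, not protocol constants, and the 60-epoch protocol default is
unchanged.

## Numerical choices and degenerate inputs

* Coordinates are 0-based voxel indices in stored (x, y, z) order; no
  reorientation or resampling anywhere.
* Center crop/pad puts the extra voxel on the high-index side on odd
  differences (fixed, documented tie-break); the center voxel is preserved.
* Group-norm epsilon 1e-5; Adam (β₁, β₂, ε) = (0.9, 0.999, 1e-8).
* Weight init: He-normal for convolutions, σ = 0.01 for the final linear
  layer (small but nonzero so gradients reach every layer at step one);
  zeros for biases and normalization shifts, ones for normalization gains.
* Degenerate inputs are rejected with messages rather than coerced:
  zero-variance normalization regions, all-zero volumes to trim, odd
  spatial sizes in the Trible Res Block, ages outside the configured
  range, atrophy rates that would invert a region, cohorts with all ages
  equal (oracle), empty split partitions, non-finite training losses.
* Region extraction with no matching voxels is allowed (all-zero output)
  but flagged with a warning and `empty_region=True`.

## Known limitations

* The engine is single-threaded CPU numpy; study-scale inputs (128³–256³)
  are architecturally supported but not practical to train here.
* The phantom's age–structure map is deterministic and affine, so desk
  results overestimate how linearly decodable age is from real anatomy.
* Checkpoints store raw float32 weights keyed by module path; they are not
  portable to other frameworks.
* The disease-group model is a uniform effective-age offset; real MCI/AD
  atrophy is regionally heterogeneous.
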