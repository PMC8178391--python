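# Methods

## Problem setting

Synchrotron parallel-beam tomography measures line integrals of an object's
attenuation: a sinogram `y` indexed by rotation angle and detector position,
related to the unknown slice `x` by a linear operator `A` (the Radon
transform).  Short exposures and fast dynamics leave substantial photon noise
in `y`, which filtered backprojection (FBP) carries into the reconstruction.
`n2itomo` implements self-supervised (Noise2Inverse-style) CNN denoising of
such reconstructions: the network is trained only on the noisy measurement
itself, split into complementary parts, with no clean reference data.

## The self-supervised training identity

Split the measured angles (or time steps) into `J` target sections with
complementary input sections.  Write `x_{j,noisy}` for the reconstruction of
target section `j`, `x_{·≠j,noisy}` for the reconstruction of its input
section, and `x_{j,clean}` for the (unknown) noise-free target
reconstruction.  Because the reconstruction is linear and the measurement
noise is zero-mean and independent across measurement units,

    E Σ_j ||f(x_{·≠j,noisy}) − x_{j,noisy}||²
      = Σ_j E ||f(x_{·≠j,noisy}) − x_{j,clean}||²  +  E ||x_{j,clean} − x_{j,noisy}||²

for any denoiser `f` that does not look at the target-section data: the
cross term pairs target-section noise with a quantity independent of it and
vanishes in expectation.  The second right-hand term does not depend on `f`,
so minimizing the left side minimizes the supervised loss one cannot
compute.  `baselines.verify_loss_decomposition` checks this identity by
Monte Carlo with fixed linear denoisers (identity, uniform blur); the
residual is reported in units of its own standard error and the package's
tests require agreement within 3 SE at 200 realizations.

Two conditions on the split make the argument valid, and
`splitting.verify_conditions` enforces them before any training pair is
built: (1) each input section is disjoint from its target section, and
(2) every measurement unit serves as target equally often.  For angular
splits "equally often" specializes to "exactly once" (the target sets
partition the angles); for the dynamic round-robin split each step appears
in exactly `K−1` of the complement targets, which is equal use — the checker
verifies exact partition for angle units and equal counts for time-step
units.

## Splitting strategies

* **Static 3D (`static_25d`)** — each slice's sinogram is split by angle with
  stride `J` (angle `k` goes to target set `k mod J`), so adjacent angles
  land in different target sections and every section samples the half-turn
  near-uniformly.  When the angle count is not divisible by `J` the
  remainder goes to the lowest-index target sets.  The network input is a
  stack of `2·context+1` adjacent slices reconstructed from the input
  section (2.5D), the target the single central slice from the target
  section.
* **Dynamic (`dynamic`)** — with interlaced acquisition each time step
  measures a sparse angle grid shifted from the previous step's, so a group
  of `K` steps tiles the full turn.  The split inverts the static size
  relation: input = one step alone (sparse, streaky), target = the combined
  sinogram of the other `K−1` steps (dense).  The trained network therefore
  suppresses sparse-angle artifacts as well as noise, and at inference is
  applied to every single-step reconstruction.  Groups are disjoint
  consecutive blocks of `K` steps.
* **Multi-channel (`multichannel`)** — per-channel sinograms of one slice
  share a single angular split; the full channel stack appears in both
  input and target, never divided across them.  The per-voxel channel vector
  (diffractogram) is constant within a material, and keeping channels
  together lets the network exploit that correspondence.

## Forward model and reconstruction

The projector is ray-driven Joseph-style: unit steps along the image axis
most parallel to the ray, linear interpolation between the two transverse
neighbours, path-length weight `1/max(|cos θ|, |sin θ|)`.  It is materialized
as a cached sparse matrix; the backprojector is its exact transpose, so the
adjoint identity holds to machine precision (tested at 1e−6 relative, and
exact up to float rounding).  FBP filters each projection in the frequency
domain with the discrete ramp response (optionally Shepp-Logan or cosine
windowed), zero-padded to the next power of two ≥ 2× the detector width to
suppress circular-convolution wrap, then backprojects with scale
`π/(2·num_angles)`.  With this scale, angle sets covering a half turn — or a
full turn, where opposite rays average implicitly — reconstruct attenuation
values quantitatively (disk phantom interior recovered within 5%; interior
agreement with scikit-image's `iradon` at the 1–3% level, differences
concentrated at edges where interpolation schemes differ).  Rays leaving the
image square are truncated; the rotation center is fixed at the detector
midpoint.

## Noise model

Clean line integrals `p` map to expected counts `I0·t·exp(−p) + dark`, a
Poisson draw per ray, then dark-field/flat-field/log correction.  The
virtual acquisition time fraction `t ∈ (0, 1]` rescales expected counts
only (the angle count is unchanged), so corrected-noise variance scales as
`1/t` — the mechanism used to emulate shortened multi-channel acquisitions;
the tests verify the 5× variance ratio between `t = 1` and `t = 0.2` within
10%.  Counts at or below dark are clamped one count above dark before the
log (photon starvation floor).  The log correction is exactly unbiased only
in the noiseless limit: a second-order expansion gives a deterministic bias
of `+1/(2·counts)` per ray, ≈ 0.025 at 20 counts, matching measurement.
Consequently the package asserts strict zero-mean for the raw counting noise
and for the additive-Gaussian mode, and for the corrected sinogram a bias
below 1% of the signal whenever minimum expected counts stay at or above 20
— the regime all shipped experiment configurations operate in.  An additive
Gaussian mode (`gaussian_sigma`) is provided as the other admissible
zero-mean noise family; Poisson is the default.

## Network

The denoiser is a simplified mixed-scale dense (MS-D) network: hidden layer
`i` applies one 3×3 convolution with dilation `((i−1) mod 10) + 1` over
*all* previous feature maps and input channels, adds a bias, and applies a
ReLU, producing a single new feature map; the output layer is a 1×1 linear
map over everything.  Parameter count is therefore
`Σ_i [9·(c_in + i − 1) + 1] + c_out·(c_in + depth) + c_out` — 13 at depth 1
with one channel, and 54,662 at depth 100 with 11 input channels, the
reported scale of the full-size architecture (≈ 5.5·10⁴).  Width-1 dense
connectivity is what keeps the count this small, and the small count is why
overfitting to noise is unlikely and no early stopping is used.

Convolutions use reflection padding that mirrors about the boundary pixel
excluding the edge (`−1 ↦ 1`); the same rule stacks out-of-range context
slices in the 2.5D assembly, so edge slices never see duplicated copies of
themselves.  A periodic padding mode exists as a test hook (translation
equivariance), and a `linear_activations` hook turns the network into a
linear operator for diagnostic checks.  Forward and backward passes are
hand-written numba kernels operating on float32 padded buffers; the backward
pass is the exact transpose of the forward computation including the padding
fold, and is verified against central finite differences.  Normalization is
a global affine map fitted on the training pairs sending the 1st/99th
percentile of inputs (and, separately, targets) to [0, 1] — robust to FBP
over/undershoot — stored inside the model and applied around every forward
pass.

## Training

Mean squared error between network output and target reconstruction,
minimized with Adam (learning rate 1e−3, batch size 2–4 depending on the
experiment), data order reshuffled each epoch from a dedicated seed.
Weight initialization, noise simulation and shuffling use separate seeded
generators, making every run bit-reproducible single-threaded.  Training
pairs (FBP reconstructions of the sections) are precomputed in memory
before the loop — at the problem sizes this package targets they are a few
hundred megabytes at most, and recomputing FBP per iteration would dominate
the cost; the CLI persists the underlying containers to HDF5 for
provenance.  Two inference modes are provided: applying the trained network
to the reconstruction from *all* measurements ("full", the default, which
empirically wins most seeds) and averaging the network outputs over the `J`
input-section reconstructions ("split_average", the original scheme).

## TV baseline

`min_x ½||Ax − y||² + λ·TV(x)` with isotropic TV (forward differences,
Neumann boundary), solved by 500 Chambolle-Pock iterations.  The
regularization weight is folded into the stacked operator `K = [A; λ∇]`
(unit-ball TV dual), so the power-iteration step sizes adapt to `λ`; without
this, iterates stall for `λ` far above `‖A‖` and the large-`λ` flat limit is
unreachable in practice.  The implementation was cross-checked against an
L-BFGS solve of the ε-smoothed objective on a dense 12² instance (objectives
agree to <0.5% across three decades of λ).  Where the original procedure
tuned λ visually, the automated tests replace this with a 5-point
logarithmic grid (`λ ∈ [1, 100]` for the shipped phantom scale, chosen by
the sinogram magnitude) scored by MSE against the known phantom.

## Synthetic data

Phantoms are piecewise-constant: a background disk (attenuation 0.01/pixel,
giving line integrals of order 1 and transmissions of 10–40% across a
~100-pixel object — a realistic regime) with non-overlapping ellipsoids of
2–3 materials (0.016–0.024/pixel) spanning several slices so that 2.5D
context is informative.  The dynamic phantom adds spherical inclusions of a
lighter material (0.004/pixel, water-like) growing linearly in radius from
`start_step`; earlier steps are bitwise identical.  The spectral phantom
assigns each material a sparse positive 11-channel signature (1–3 random
peaks, 0.008–0.03) with a weak broad background response.  The interlaced
schedule offsets step `s` by `s·Δ/num_steps` (`Δ = 2π/angles_per_step`) with
optional per-step rigid jitter modelling rotation-speed deviation.

What these phantoms deliberately do **not** model: detector blur, ring
artifacts, beam hardening, scatter, sample drift/vibration, realistic
microstructure or diffraction physics.  Passing tests therefore demonstrate
the correctness of the splitting/training machinery and the expected
statistical behaviour under the stated noise model — not performance on any
particular real instrument's data.

## Scaled experiment configurations

Problem sizes are chosen so each end-to-end experiment trains in minutes on
one CPU core:

* static: 8 slices of 128², 256 angles over π, `I0 = 200`, `J = 2`,
  depth-25 network with context 2 (5 input slices), 2000 iterations,
  batch 2.  Expected outcome (asserted): denoised MSE ≤ 0.5× noisy-FBP MSE.
  The full-vs-split-average comparison repeats a reduced configuration
  (4 slices of 64², depth 10, 300 iterations) over 10 seeds; the full mode
  is expected to win in at least 7.
* dynamic: 18 steps of 50 angles over 2π interlaced in groups of 6, 64²,
  process starts at step 12; training on steps 0–5, evaluation on the
  unseen static steps 6–11.  Asserted: combined-group FBP beats single-step
  FBP, and per-step denoising at least halves single-step FBP MSE.
* multi-channel: 11 channels, 64², 180 angles over π, `J = 3`, depth-15
  11→11 network.  Asserted: MSE improves in ≥ 9 of 11 channels; the spread
  of mean diffractograms across disjoint same-material regions stays within
  3× the residual noise RMS.

## Numerical choices and edge cases

* System matrices are cached with an LRU capped at ~1.2·10⁸ nonzeros;
  section geometries build their own (smaller) matrices.
* FBP of a single angle is defined (scale `π/2`); empty angle sets are
  rejected everywhere.
* `J = 1` angular splits are rejected (the input section would be empty);
  dynamic groups need `K ≥ 2`.
* SSIM on stacks thinner than the 7-pixel window is computed per slice and
  averaged; PSNR of identical volumes reports infinity.
* Training aborts with a diagnostic on a non-finite loss rather than
  continuing silently.
* Power iteration for step sizes runs 30 iterations from a seeded start;
  the estimate is monotone in iteration count and matched a dense SVD to
  <1% on 16² instances.

## Known limitations

The projector supports parallel-beam 2D geometry only (no fan/cone beam, no
center-of-rotation estimation, no ring-artifact handling).  The MS-D variant
here is width-1 with a fixed 1–10 dilation cycle; it reproduces the
parameter scale and qualitative behaviour of the full architecture, not its
exact implementation.  Training is single-threaded CPU: full-size
(2048-angle, 2k²) datasets are out of scope.  The dynamic strategy assumes
the training window is truly static; slow drift inside the window would
blur the combined targets.
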