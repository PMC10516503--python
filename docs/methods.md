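# Methods

This note documents the models, conventions and numerical choices behind the
package: what is simulated, how the reconstruction network is defined and
trained, how the analytical baseline works, and what the desk-scale
experiments do and do not demonstrate.

## Problem setting

Ultralow-field (ULF, < 0.1 T) brain MRI trades signal-to-noise ratio and
resolution for cost and portability. A fast 3D acquisition at such field
strengths uses a single excitation (no averaging) and 2D partial-Fourier
(PF) sampling: only a fraction f = 0.7 of k-space lines is acquired along
each of the two phase-encoding (PE) axes (left-right and superior-inferior);
the readout axis is always fully sampled. The resulting volumes are
low-resolution (3 mm isotropic), noisy, and carry PF blurring and Gibbs
ringing. The package implements the full computational counterpart of that
setting: a degradation simulator producing paired training data from clean
high-resolution volumes, a learned 3D super-resolution reconstruction
network (PF-SR), the traditional analytical pipeline it is compared against,
and the evaluation protocol.

## Phantom generator

Real training corpora (e.g. HCP-style T1W/T2W volumes) cannot be assumed
present, so the package generates brain-like phantoms with known ground
truth:

- **Geometry.** Nested ellipsoids: background outside the head surface, a
  peripheral CSF rim (normalised radius 0.90–1.0), a cortical gray-matter
  shell (0.68–0.90) and a white-matter core, plus optional sub-structures —
  ellipsoidal ventricle-like CSF cavities, sinusoidal folding of the
  gray/white interface, and thin vascular-like tubes. A smooth random
  displacement field (amplitude `deformation_strength`, default 0.12 in
  normalised-radius units) warps the coordinate frame. A hard 2-voxel
  background margin guarantees the head never touches the volume edge.
- **Intensities.** Per-class means on [0, 1] chosen to mimic the two
  clinical contrasts: T1W-like (background 0.02, CSF 0.25, gray 0.55, white
  0.85) and T2W-like (0.02, 0.90, 0.45, 0.25). The orderings
  white > gray > CSF (T1W) and CSF > gray > white (T2W) encode the
  complementary appearance of brain tissue in the two contrasts.
- **Texture.** Zero-mean Gaussian noise smoothed with a σ = 0.8 voxel kernel
  and rescaled to unit variance (using the exact l2 norm of the truncated
  kernel), scaled by a per-class SD (~0.02–0.03). This makes volumes
  piecewise-smooth rather than piecewise-constant; super-resolution of
  piecewise-constant targets would be uninformative.
- **Determinism.** A phantom is a pure function of its spec (including the
  seed); cohorts derive per-item seeds and ±7% geometric jitter from a
  single cohort seed via `numpy` seed sequences.

What the phantoms do *not* emulate: genuine cortical folding geometry,
partial-volume blur at tissue interfaces, B0/B1 inhomogeneity, scanner
artifacts other than those the degradation chain introduces, and pathology.
Passing tests on phantoms therefore demonstrates the *mechanics* of the
pipeline (sampling, reconstruction, ordering of methods under the modelled
degradations), not clinical image quality.

## Degradation chain

Given a clean high-resolution volume, the simulated ULF input is built as:

1. **Min-max normalisation** of the target to [0, 1].
2. **Symmetric k-space truncation** by an integer factor (default 2,
   1.5 mm → 3 mm): the central (N/2)³ block of the centered orthonormal
   spectrum is retained and inverse-transformed on the coarse grid, scaled
   so constants are preserved. Unlike local averaging this reproduces the
   band-limiting of actual MR acquisition, deliberately retaining Gibbs
   ringing. (Local-mean downsampling is also provided, for preparing
   high-resolution targets from finer source data.)
3. **2D partial-Fourier masking** at fraction 0.7 per PE axis. Band
   convention (the acquisition literature leaves the side free): keep the
   contiguous indices `0 .. ceil(f·N)-1` with DC at `N//2`, i.e. the full
   negative-frequency half plus a symmetric central band of half-width
   `ceil(f·N)-1-N//2`. The symmetric band is what makes low-frequency phase
   estimation for POCS well-posed. An elliptical PE option intersects the
   mask with the inscribed ellipse measured from DC (off by default for
   training-data emulation; the acquisition that motivates it uses it).
4. **Zero-fill reconstruction**: magnitude of the inverse transform of the
   masked spectrum.
5. **Rician noise**: each magnitude voxel v becomes sqrt((v+a)² + b²) with
   a, b ~ N(0, σ²). σ defaults to 0.05 on the [0, 1] scale; the matching
   experimental noise level is not a single published number, so σ is an
   explicit, swept parameter.
6. **Re-normalisation** of the noisy input to [0, 1].

All spectra use the centered orthonormal FFT convention (DC at `N//2`,
unitary transforms), so Parseval comparisons need no scale factors.

## PF-SR network

The reconstruction model maps the 3-mm input to a 1.5-mm output by learning
the residue against trilinear interpolation:

    shallow 3³ conv (1→64)
    → multiscale feature extraction: two stride-2 conv downsamplings; per
      scale one conv + channel attention; coarser features return via
      trilinear 2× upsampling and additive skips
    → multiscale spatial attention (mean+max channel pooling, one 3³ conv,
      sigmoid gate map)
    → 23 residual groups, each five mRCABs (conv–LReLU–conv–channel
      attention with block residual) plus a trailing conv and group residual
    → subpixel convolution: conv 64→512 and 3D pixel shuffle (2× per axis)
    → final 3³ conv to 1 channel (the residue)
    output = residue + trilinear 2× upsample of the input

Channel attention is a squeeze-excite bottleneck of two 1×1×1 convs
(64→8→64) with a sigmoid; every other kernel is 3×3×3; all activations are
leaky ReLU with slope 0.1; channels are 64 throughout.

**Residual-group count.** The printed architecture constants pin everything
except the depth of the residual-group cascade; the published total of
"approximately 29.7 million" learnable parameters is the only constraint on
it. With the parameter counts

    conv 64→64 (3³): 110,656   channel attention: 1,096
    mRCAB: 222,408             residual group: 1,222,696
    fixed blocks (shallow + multiscale + spatial attention + subpixel +
    final): 1,445,392

the budget is met by n_rg = 23: 23 × 1,222,696 + 1,445,392 = **29,567,400**
(29.57 M, 0.45% under the printed value). This choice is the package's own
reading of the budget, not a claim about the original implementation.

**Initialisation.** Kaiming fan-in normal matched to the LReLU gain for all
convs; zero biases; the final residue conv is zero-initialised, so an
untrained network reproduces trilinear interpolation exactly — training can
only improve on the interpolation baseline, and the global-residual law is
testable exactly.

**Implementation.** The network and its training loop run on a small
reverse-mode automatic-differentiation engine written on NumPy
(`pfsr.nn.autograd`): 3D convolutions are evaluated as im2col + GEMM with
slab chunking to bound memory; every operation's gradient is exact and
verified against central finite differences in the test suite. Inference
and training are deterministic given the seeds (pure NumPy, no threading
nondeterminism in the hot path).

## Training recipe

Full scale (as configured by default): L1 loss, AdamW (β1 = 0.9,
β2 = 0.999, decoupled weight decay 0.01, biases undecayed), initial learning
rate 1e-4 decayed by 0.8 every 100 epochs, 350 epochs, batch 8, random
32³ input patches paired with the aligned 64³ target patch (high-res corner
= 2 × low-res corner). One random patch per volume per epoch; patches whose
target mean is below 0.02 (essentially empty space) are redrawn, since tiny
phantom runs otherwise spend most of their capacity on background. A 10%
validation split (by seed) is monitored with a central-patch L1. All
randomness (split, volume order, patch corners, init) derives from the
config seeds.

## Analytical baseline (non-DL)

The comparator is the traditional chain **POCS → denoise → tricubic 2×**:

- **POCS.** Per readout slice (implemented volumetrically — the readout
  axis is fully sampled, so the per-slice 2D transforms factor out), the
  image phase is estimated once from the Hann-apodised symmetric central
  band, then up to `n_iter` (default 10) alternating projections impose
  that phase on the current magnitude image and restore the acquired
  k-space samples. `n_iter = 0` reproduces zero-fill exactly; stopping also
  triggers when the relative change drops below `tol` (1e-6).
  A structural limit worth knowing: with PF applied on *both* PE axes, the
  k-space corners where one axis is high-positive and the other negative
  have conjugate mirrors that are also unsampled, so no Hermitian-symmetry
  method can recover energy there. Recovery to small error is only possible
  for truths with little energy in those corners (smooth slices); the
  Hermitian-recovery test uses such a slice deliberately.
- **Denoising.** The published chain uses BM4D. BM4D itself is bespoke
  prior work and is not re-implemented; the `denoise3d` interface delegates
  to the optional `bm4d` package when installed and otherwise uses a
  deterministic 3D non-local-means fallback (scikit-image, patch size 3,
  search distance 5, h = 0.8·σ̂ with σ̂ wavelet-estimated).
- **Tricubic interpolation.** Separable Catmull-Rom cubic convolution with
  edge clamping. Upsampling uses the *aligned* convention out[2i] = in[i]:
  Fourier-domain decimation (step 2 of the degradation chain) keeps the
  coarse grid aligned with every second fine sample, so aligned
  interpolation is the geometrically consistent inverse. The kernel is
  interpolating (on-grid samples preserved) and reproduces linear fields
  exactly wherever its 4-sample stencil does not touch a clamped edge.
  The network's trilinear residual base and the zero-fill comparator use
  the same aligned convention.

## Evaluation protocol

3D SSIM (constants K1 = 0.01, K2 = 0.03, data range fixed at 1.0, Gaussian
weighting σ = 1.5 with 11³ support, population covariances, border crop of
the filter radius) and range-normalised RMSE, both over a central axial
slab: 60 slices at paper scale (axial extent ≥ 120), otherwise the central
50% of axial slices. Axial slices stack along the superior-inferior PE
axis. Every report records the absolute window and conventions. The SSIM
implementation is cross-checked against scikit-image's
`structural_similarity` (identical constants) to 1e-6 in the tests. These
constants are standard choices; the original evaluation's exact constants
are not published, so no claim of bit-equality is made.

## Desk-scale experiments

The full-scale study (≈1200 training pairs, 29.7M parameters, hundreds of
epochs on multiple GPUs) is far beyond a single CPU, so the package ships a
scaled-down version of the same comparison whose qualitative outcome is the
testable claim: **learned PF-SR > non-DL pipeline > zero-fill + trilinear**
on mean SSIM over held-out data, with the NRMSE ordering reversed.

Sizes, chosen once as the smallest problem on which the three methods
separate cleanly: 36 phantoms (30 train / 6 test) at 64³ targets and 32³
inputs, f = 0.7, σ = 0.05; a tiny PF-SR instance (2 residual groups, 16
channels, 4-channel attention bottleneck) trained 50 epochs with 16³→32³
patches, batch 4. The tiny run uses learning rate 1e-3 rather than the
full-scale 1e-4: with only ~400 optimiser steps, AdamW's cumulative update
magnitude at 1e-4 (steps × lr ≈ 0.04) cannot express the residue amplitudes
(~0.1 on the [0, 1] scale) the task requires, whereas at full scale
(~55,000 steps) 1e-4 is appropriate. The outcome is stochastic in the seed
but stable; the training-loss decrease and the final ordering are asserted
in the acceptance tests.

## Known limitations

- Phantoms are geometric idealisations; results do not transfer claims to
  clinical data.
- The degradation chain models sampling, truncation and Rician noise only —
  no coil sensitivities, B0 inhomogeneity, motion, or interference
  residues.
- The NumPy training path is practical at desk scale only; full-scale
  training would require a GPU framework (the architecture and recipe are
  framework-agnostic and reconstructible from `ModelConfig`/`TrainConfig`).
- `upscale` is implemented for factors 1 and 2 (the published factor); the
  subpixel layer generalises, but the trilinear base path is specialised
  to 2×.
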