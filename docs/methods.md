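# Methods

This note documents the models implemented in `cmrdiff`, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic phantoms do and do not establish about real
cardiac MR data.

## Diffusion model

The generator is a standard epsilon-parameterized DDPM. The forward process
adds Gaussian noise over `T` steps under a linear variance schedule; the
package default is `beta` from 1e-4 to 0.02 over `T = 1000`, which drives
the terminal signal attenuation `alpha_bar_T` to ~4e-5 so the chain start
is effectively standard normal. Schedule vectors (`betas`, `alphas`,
`alpha_bars`, posterior variances) are stored in float64: `alpha_bar_T` is
a product of a thousand near-unit factors, and float32 accumulation
visibly distorts it. Timesteps are 1-based at every public interface;
`alpha_bar_0 := 1` so the exact posterior at `t = 1` collapses onto the
clean image with zero variance.

Training minimizes the mean squared error between true and predicted noise.
The reduction is the mean over batch and pixels (not a summed norm), so the
loss scale is independent of image resolution — a loss of 1.0 always means
"no better than predicting zero".

For chains shorter than 1000 steps (used throughout the desk-scale runs),
`scaled_linear_schedule(T)` multiplies both beta endpoints by `1000 / T`,
preserving the total noising budget `sum(beta)` and hence the terminal
attenuation. Without this, a 200-step chain under the reference betas
leaves `alpha_bar_T ≈ 0.13`, and sampling that starts from pure noise is
initialized far from the true terminal marginal.

## Denoiser architecture

`UNetSpec` describes a five-level UNet: channels (64, 128, 256, 512, 1024)
at feature-map sides (128, 64, 32, 16, 8); two residual units per block;
encoder block kinds (plain, plain, plain, attn, attn) mirrored in the
decoder; multi-head self-attention with 8 heads restricted to sides <= 32;
group normalization with 16 groups; a 256-dimensional sinusoidal timestep
embedding passed through a two-layer SiLU MLP.

Each residual unit computes `h + W2 * SiLU(W1 * AdaGN(h, t))` with 3x3
convolutions and an identity final nonlinearity. Design choices the
architecture description leaves open, fixed here:

- **AdaGN parameterization.** Group statistics are computed without a
  learned affine; a linear map from the 256-d time embedding produces a
  per-channel `(scale, shift)` and the unit applies
  `xhat * (1 + scale) + shift`. The projection is zero-initialized, so
  every unit starts as an identity map with unconditioned statistics.
- **Second convolution zero-initialized** so the whole network starts near
  the zero function — standard practice that stabilizes early optimization.
- **Resampling.** Downsampling by stride-2 3x3 convolution; upsampling by
  nearest-neighbor followed by a 3x3 convolution.
- **Bottleneck** carries one attention block between two residual units, at
  the 8x8 resolution.
- **Skip connections** concatenate encoder features channel-wise into the
  decoder (one skip per encoder residual unit plus one per downsample, so
  decoder blocks carry three residual units).
- **Attention block**: group norm, 1x1 q/k/v/output projections over
  flattened spatial tokens, residual add. The time-embedding MLP hidden
  width equals the embedding width (256).

With these choices the reference 128x128 configuration holds
**255.5 million trainable parameters** (reported by
`scripts/acceptance.py`, recomputed from the instantiated tensors). The
parameter count is dominated by the deepest levels: a single 1024-channel
3x3 convolution alone holds 9.4 M weights, and the bottleneck plus the
1024-channel encoder level account for ~85 M. No realization of the stated
channel ladder with two 3x3-conv residual units per block can be
substantially smaller.

The network, its reverse-mode autodiff engine, and AdamW are implemented
in numpy. Gradients of every operation are validated against central
finite differences in the test suite. Model arithmetic defaults to float32
("reduced" precision); float64 ("full") is available and changes only the
arithmetic, never the logged-metric contract.

## Training loop

AdamW (beta1 0.9, beta2 0.999, eps 1e-8, decoupled weight decay 1e-5),
linear warmup from 0 to `lr_max = 2e-4` over 100 steps, then cosine
annealing to `lr_min = 1e-6` at the final step. Gradient clipping rescales
the joint global L2 norm to at most 1.0. Batch size defaults to 16 — the
16-group normalization is chosen precisely because it is stable at small
batch sizes. Run length may be given in steps or epochs (converted via
dataset size); the cosine schedule is step-indexed. Per training step: a
uniform timestep and fresh noise per sample, the noised batch formed in
closed form, loss, clip, step. Checkpoints carry weights, optimizer
moments and RNG state, so a resumed run is bit-identical to an
uninterrupted one (tested). No exponential moving average of weights is
kept: nothing in the training recipe calls for one, and silently adding it
would change what the checkpoints mean.

## Sampling

Full ancestral sampling from `t = T` down to 1 with reverse variance
`sigma_t^2 = beta_t`; the final step emits the posterior mean rather than
adding irreducible noise. The sampler refuses step counts different from
the schedule's `T` (no implicit striding). By default the implied clean
image `x0_hat = (x_t - sqrt(1 - alpha_bar_t) eps_hat) / sqrt(alpha_bar_t)`
is clipped to the training data support [-0.5, 0.5] before forming the
reverse mean; with imperfectly trained denoisers the unclipped recurrence
amplifies low-timestep prediction errors into trajectories far outside the
data range. Oracle tests that check the exact unclipped recurrence disable
it (`clip_x0=None`).

A classifier-free guidance hook (`guided_eps`) computes
`eps_u + s (eps_c - eps_u)` with default scale 3.0. The generator trained
here is unconditional, so there is no conditional branch to feed it: with
a single model the hook degenerates to the identity, and it exists so a
conditional denoiser can be plugged into the same sampling loop. This
contradiction — a guidance scale quoted for an unconditional model — is
surfaced here rather than resolved by inventing a hidden conditioning.

## K-space reading and preprocessing

OCMR-style HDF5 files hold one complex `kData` array across nine axes
`[kx, ky, kz, coil, phase, set, slice, rep, avg]` (native complex or
real/imag compound). Reconstruction is a centered, unitary inverse 2-D FFT
per coil followed by root-sum-of-squares combination; signal averages are
collapsed by mean. The unitary convention makes image-domain energy equal
k-space energy per coil, which the tests verify (Parseval).

Preprocessing chain (each stage toggleable): bias-field correction, then
histogram matching to a reference template (monotone quantile mapping at
256 levels; the packaged default template is the intensity distribution of
a canonical noiseless phantom), then z-score standardization, then an
affine rescale to exactly [-0.5, 0.5]. "Z-score to a bounded range" is
contradictory as a single operation; the resolution here is z-score
followed by min–max rescale, because the training pipeline requires the
bounded range. Bias correction fits a 2-D polynomial of total degree <= 3
to the log-image by least squares and divides it out — a self-contained
model of smooth multiplicative coil shading. It is pluggable: any callable
with the same signature (e.g. a full N4 implementation) can replace it.
Frames are center-cropped to square and bilinearly resized to the model
size (128 by default).

## Phantom generator

Each phantom draws a geometry (LV radius, myocardial thickness, RV outer
radius / bite ratio / bite offset, center jitter, septal angle) from
uniform ranges, rasterizes LV disk, myocardial annulus and RV crescent
(set difference of two offset disks, clipped against the heart), assigns
per-tissue intensities (LV 0.85 > RV 0.72 > myocardium 0.40 > background
0.12 on a [0, 1] scale — bright-blood contrast), adds Gaussian noise
(sd 0.04, modulated per tissue, RV most variable), and rescales to exactly
[-0.5, 0.5]. All randomness flows from one seeded generator; datasets
spawn per-phantom child seeds recorded in the manifest.

Geometry ranges were calibrated once, by simulation, so that mean class
proportions over many draws match the real-data statistics used as
targets: LV 1.52%, RV 1.25%, myocardium 2.04% of image pixels (measured
1.53 / 1.26 / 2.00 over 500 draws). LV roundness (~0.9–1.0) and solidity
(~0.96) fall in the plausibility range of real LV measurements. This is an
emulation for exercising the pipeline, not ground truth: phantoms have no
papillary muscles, no partial-volume mixing, no coil shading, no temporal
dimension, and far narrower morphological variation than real hearts.
Passing the calibration and comparison tests therefore demonstrates that
the pipeline measures what it claims on data of realistic dynamic range —
not that the generator reproduces clinical anatomy.

## Fidelity metrics

- **Fréchet distance** between Gaussian fits of feature embeddings,
  `||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})`, with a stabilized
  matrix square root. The feature extractor is pluggable; the packaged
  default is a fixed-seed two-stage random convolutional projection with
  mean/sd pooling. Distances under this extractor are self-consistent but
  not comparable to Inception-based values.
- **SSIM**: 7x7 Gaussian window (sigma 1.5), k1 = 0.01, k2 = 0.03, dynamic
  range 1.0 (images live in [-0.5, 0.5]); reflective boundary handling.
- **MS-SSIM**: contrast-structure terms at each scale, luminance at the
  coarsest, standard five-scale exponents (renormalized for fewer scales);
  downsampling by 2x average pooling. Negative contrast-structure means
  are clipped at zero before the fractional exponents; with a single scale
  the value equals plain SSIM exactly.
- **Nearest-neighbor SSIM**: for each generated image, the maximum SSIM
  over the training set (exhaustive search; the neighbor metric is SSIM
  itself). Values near 1 on large diverse training sets indicate
  memorization.
- **Pairwise MS-SSIM** over unordered sample pairs probes diversity; the
  report prints the value without imposing a direction of preference,
  since a higher value means more structural similarity between samples
  and what counts as "better" depends on the intended use.

## Anatomical evaluation

Masks use labels {0 background, 1 LV, 2 RV, 3 myocardium}. Per structure:
pixel percentage of the image; shape features (area, perimeter, roundness
`4*pi*A/P^2`, moment-ellipse eccentricity, convex-hull solidity) on the
largest connected component, ignoring fragments under 5 pixels; cardiac
ratios LV/Myo and RV/LV by area; myocardial thickness as the mean over 360
equal-angle rays from the LV centroid of the outer-minus-inner wall
crossing distance (radial rays rather than a medial axis: deterministic,
analytically checkable on annuli, and matching the short-axis intuition of
"wall thickness"). Perimeter uses the contour-length estimator with
diagonal correction; roundness is sensitive to this choice, so it is part
of the metric definition. Rasterization keeps disk solidity a few percent
below 1 (~0.96 at radius 20) because the convex hull bridges boundary
staircase notches.

Cohort comparison emits 18 rows (3 class percentages, 12 shape features, 3
cardiac metrics) with means, sds, relative differences, and a two-sample
Kolmogorov–Smirnov test per metric — asymptotic p-values at effective size
`nm/(n+m)`, appropriate for the n ≈ 100 regime — flagged at alpha = 0.05.
Under a shared generating configuration the per-metric flag rate stays at
or below twice the nominal level across 20 seeded repetitions (tested);
non-finite metric values (e.g. degenerate fragments) are dropped
metric-wise before testing.

## Problem sizes used in the checks

The behavioural test suite runs entirely on synthetic data: 1e5 chains for
the forward-marginal moment comparison; 1e4 ancestral samples at T = 200
for the analytic-denoiser distribution recovery; a 16x16 two-level
denoiser trained 1000 steps on 256 zoomed phantoms for the end-to-end
learning check; 500 phantoms for proportion calibration; 20 repetitions of
100-vs-100 cohorts for the null calibration. These sizes were chosen as
the smallest at which the statistical assertions have comfortable margins.

## Known limitations

- The full 255.5 M-parameter reference model is built and run forward in
  the tests, but training it is far outside numpy-on-CPU territory; all
  learning checks use reduced configurations of the same code paths.
- FID values are extractor-relative (see above).
- The guidance hook is a no-op without a conditional model.
- Phantoms emulate geometry and contrast statistics, not MR physics.
- KS p-values are asymptotic; at very small cohort sizes (< ~25) an exact
  method would be preferable.
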