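# Methods

`flairacc` is a desk-scale, fully synthetic replica of a clinical evaluation
chain for accelerated FLAIR brain MRI. Its purpose is to make every step of
that chain — undersampling, parallel-imaging reconstruction, CNN denoising,
and the quantitative/statistical comparison — available as tested,
reusable code. This note records the models, the defaults and their
rationale, and what the synthetic experiments can and cannot show.

## Synthetic cohort

Real raw multi-coil FLAIR data from patients are not publicly available, so
the package generates its own cohort of 2D axial FLAIR-like magnitude
phantoms:

* **Anatomy.** Concentric smoothed ellipses: an outer CSF rim, a cortical
  gray-matter ribbon, a white-matter core and two elliptical ventricles.
  Boundaries are perturbed per case by low-order radial harmonics
  (std 0.012) plus jitter of the ellipse axes and center, so cases are
  geometrically distinct. No anatomical atlas is used: the evaluation needs
  contrast classes and focal lesions, not anatomy.
* **Intensities** follow FLAIR contrast: CSF suppressed (0.15), white
  matter 0.55, gray matter 0.70, in arbitrary signal units, softened by a
  0.8-pixel Gaussian at tissue interfaces.
* **Lesions** are rasterized discs with a 1-pixel smoothed edge, restricted
  to white matter, non-overlapping, 3–10 mm in diameter (uniform), with a
  multiplicative contrast of 1.4 relative to white matter. Contrast and
  texture of real hyperintensities vary widely; 1.4 is a free parameter
  exposed in the configuration. The default cohort draws 3–5 lesions per
  case so that 30 cases provide at least 100 lesions for the regional
  analysis.
* **Coil maps.** Eight channels by default: Gaussian magnitude lobes
  arranged on a ring with a +0.05 floor (sum-of-squares strictly positive
  everywhere) and slowly varying phase. Eight well-separated lobes keep
  every SENSE system at R = 3 comfortably full rank. The clinical
  acquisition used a 32-channel head coil; channel count is configurable.
* **Grid.** 128 × 128 over a 240 × 240 mm field of view by default
  (configurable). This is far below the clinical 512 × 512 reconstruction
  but preserves every algorithmic property being tested while keeping the
  full experiment in minutes on one CPU core.

## k-space model

Per channel `c`, `data_c = F(S_c ⊙ m) + ε_c` with the unitary DC-centered
2D FFT and i.i.d. complex Gaussian noise (`noise_std` per real/imaginary
component). The orthonormal convention makes Parseval exact and the noise
variance identical in k-space and image space. Equidistant undersampling
keeps every `af`-th phase-encode line (column axis) starting at `offset`
(default 0; the acquisition's interleave choice is not modelled).
Retrospective undersampling operates on the *same* noisy k-space that forms
the reference arm — the accelerated arm shares the sampled third of the
noise realization with the reference, exactly as a retrospective study
design implies. This correlation matters for interpretation (below).

Accelerated scan time is full-sampling time divided by the acceleration
factor: 277 s / 3 = 92.33 s, rendered "1 min 32 s". The reconstruction
method does not change the acquisition, so one accelerated time applies to
both accelerated arms.

## Reconstruction

* **Reference ("std") arm:** per-channel inverse FFT, coil-combined by
  sensitivity-weighted least squares `m = Σ conj(S_c) x_c / Σ |S_c|²`,
  magnitude taken. Simulation supplies exact maps, so no calibration step
  exists; the same combination is used by every arm so that arm differences
  isolate undersampling and denoising.
* **SENSE:** zero-filled per-channel images alias R pixels spaced
  `n_pe/af`; each aliased group is unfolded by least squares over channels.
  The aliasing weights are derived numerically from the package's own FFT
  convention (impulse response of the masked transform), which keeps the
  implementation correct for any offset. Rank deficiency of any group
  (e.g. a single channel at R > 1) raises an "unresolvable aliasing" error
  with the group location. SENSE requires `af` to divide the number of
  phase-encode lines; the default 128-line grid with AF 3 therefore uses
  the POCS arm (the package's default), and SENSE examples use 126-line
  grids.
* **POCS with wavelet soft-thresholding:** iterate (1) data consistency —
  replace sampled k-space lines of the coil-weighted estimate with the
  measured data; (2) least-squares coil combination; (3) soft-thresholding
  of the wavelet detail coefficients (Daubechies-4, 3 levels; approximation
  band untouched, standard denoising practice that preserves bulk
  contrast). The threshold is `lam_factor` times the MAD-based noise
  estimate from the finest diagonal band of the initial zero-filled
  estimate, frozen across iterations; an absolute override is available.
  Soft-thresholding is magnitude shrinkage with phase preserved and is
  non-expansive, so the shrinkage step cannot destabilize the iteration.

  Defaults: `lam_factor = 0.75`, `max_iters = 150`, `tol = 1e-6` (relative
  image change). The iteration count deserves a note: plain POCS resolves
  3× aliasing on this geometry only after roughly 150–300 iterations
  (30 iterations leave visible aliasing, SSIM ≈ 0.79 even without noise);
  150 iterations with the default tolerance reproduce the converged image
  to the displayed precision at about 2 s per case. The experiment
  pipeline overrides `lam_factor` to 0.05 (see calibration below).

* **Noise maps.** `noise_uniformity_map` estimates the pixel-wise noise
  standard deviation by Monte Carlo over independent noise realizations
  with the phantom fixed. At R = 3 the SENSE map shows the expected
  g-factor behavior: higher mean noise and a larger coefficient of
  variation across the brain than at R = 1.

## Denoiser

A three-layer convolutional network with a global residual connection:
9×9 kernels / 64 channels, 5×5 / 32, 5×5 / 1, biases everywhere, ReLU
after layers 1 and 2, linear output added to the input. 57,281 parameters.
Design choices where the architecture description is underdetermined: the
output layer is linear (a residual correction must be signed, so a final
ReLU is applied only as a clamp to non-negative magnitudes after
denormalization), and the skip connection means the network predicts the
clean image as input + correction. Same-padding uses reflect boundaries to
avoid edge ringing. The final layer is initialized at 0.1× the He scale so
training starts near the identity map — the natural prior for a residual
denoiser and a large optimization speed-up at this scale.

The network, backpropagation and the Adam optimizer are implemented
directly on numpy arrays (float32, shift-and-matmul convolutions). At
57k parameters this trains in 2–7 minutes on one CPU core; no deep-learning
framework is involved.

**Training data.** Pairs are drawn from *reconstructions*, not phantoms:
the reference is the fully sampled reconstruction of noise-free data, the
noisy input is the POCS reconstruction of undersampled noisy data of the
same case. Both are normalized per case to [0, 1] by the *noisy* image's
1st–99th percentile window — the frame that is actually available at
inference, where the model re-derives the window from its input image (the
percentile levels are the model's stored normalization contract). Patch
centers
are drawn from the brain mask so network capacity is spent on tissue.
Defaults: 384 patches of 24×24 from a 12-case training cohort, Adam at
lr 3e-4 (stepped ×0.3 at 60% and 85% of epochs), batch 16, 90 epochs, MSE
loss, 80/20 train/validation split by position in the per-case patch
stream. Training is deterministic given its seed.

The optimizer settings are deliberate, not generic. The task is denoising
at roughly 40 dB input PSNR, where the optimal correction is small and,
because of the skip connection, the identity map is a strong attractor: at
lr 1e-3 the easiest descent direction kills the ReLU layers (the second
layer's channels go almost completely dead) and the network degenerates to
background zeroing with held-out MSE at the noisy baseline. At lr 3e-4
with ~2,000 small-batch steps the layers stay active and held-out patch
MSE drops to about 0.8× the noisy baseline. Small patches (24×24, still
well above the 17×17 receptive field) make optimizer steps cheap, which
matters more here than patch area.

**Train/evaluation separation.** The denoiser is trained on a synthetic
cohort generated from a seed branch disjoint from the evaluation cohort —
mirroring the clinical situation where the vendor's network was trained on
data unrelated to the study patients — so all 30 evaluation cases and
their ~100 lesions are held out and the paired statistics keep their full
sample size.

## Quantitative metrics

Whole-image SSIM (11×11 Gaussian window, σ = 1.5, k1 = 0.01, k2 = 0.03,
dynamic range = reference range, population covariance) and NRMSE (RMSE
divided by the reference intensity range; mean and Euclidean normalizers
selectable and always recorded). Regional variants evaluate 25×25-pixel
windows centered on each lesion, extracted at identical coordinates from
both images; near borders the window is clamp-shifted, never padded, so no
artificial intensities enter the score. SSIM values are reported as
computed (they can in principle be negative; no clamping). Summaries are
mean ± population SD per arm.

## Statistics

Paired acc-vs-dlr comparisons use the two-sided Wilcoxon signed-rank test:
exact by convolution of the signed-rank distribution for ≤ 12 nonzero
differences (valid under ties; zeros handled by the Pratt method by
default, the discard method selectable), otherwise the tie-corrected
normal approximation with continuity correction. The four quantitative
comparisons (SSIM, NRMSE, regional SSIM, regional NRMSE) are
Bonferroni-corrected with m = 4. ICC(2,1) — two-way random effects,
absolute agreement, single measure — is computed from the ANOVA mean
squares with the F-based 95% confidence interval, and labelled
poor (< 0.50) / moderate (0.50–0.75) / good (0.75–0.90) /
excellent (> 0.90); shared boundary points go to the lower band's closed
end. Tables with zero variance are flagged degenerate rather than scored.

The reader study itself is out of scope. To exercise the reliability
statistics end to end, the pipeline can attach *synthetic* reader ratings
(quantized regional-SSIM with reader-specific bias and ordinal noise);
these are labelled synthetic throughout and make no claim about human
perception.

## Calibration of the study conditions

The experiment's noise level is calibrated so that the accelerated arm's
whole-image SSIM against the reference lands in 0.85–0.95, mimicking the
regime in which the clinical comparison operated. Defaults frozen after
that calibration: k-space `noise_std = 0.008 ×` the white-matter signal,
with the experiment's POCS threshold at `lam_factor = 0.05`, which leaves
the accelerated arm's amplified noise largely intact for the denoiser to
remove — the clinical accelerated images were likewise visibly noisy
(reader noise scores of 1.4–2.2 on a 4-point scale).

A subtlety of retrospective undersampling is worth recording: because the
accelerated arm shares a third of its noise realization with the
reference, their errors are *positively correlated*, and a perfect
denoiser (output = noiseless truth) does not maximize SSIM against the
noisy reference. Direction-of-effect results (denoised arm closer to the
reference than the accelerated arm) therefore require the accelerated
arm's noise amplification to dominate the shared component — which the
calibrated defaults provide — and the magnitudes of the clinical study's
SSIM/NRMSE values are not reproducible from synthetic phantoms and are not
targeted.

## Problem sizes and determinism

Default experiment: 30 evaluation cases and 12 training cases at 128×128,
8 channels, AF 3, 512 training patches, 40 epochs — chosen as the natural
desk scale for a single CPU core (minutes, not hours). Every random choice
(cohort anatomy, lesion placement, noise, weight initialization, patch
sampling, shuffling) derives from one master seed through named seed
streams; re-running with the same configuration is bit-identical, and the
report writer emits no timestamps so regenerated reports are byte-equal.

## Known limitations

* 2D magnitude phantoms with piecewise-constant tissue classes; no Bloch
  simulation of the FLAIR sequence, no motion (motion cases were excluded
  in the clinical study), no partial-volume texture. Passing tests show
  the computational chain behaves correctly and reproduces the *direction*
  of the clinical quantitative findings under controlled conditions; they
  do not validate performance on real scanner data.
* Coil maps are smooth analytic constructions and the reconstruction uses
  them exactly; sensitivity calibration error is not modelled.
* The SENSE implementation requires the acceleration factor to divide the
  phase-encode dimension (integer ghost spacing); arbitrary masks are the
  POCS arm's territory.
* The exact Wilcoxon mode enumerates only up to the configured cutoff
  (12 nonzero differences by default); beyond that the normal
  approximation is used, as in the clinical analysis (n = 30 and n = 100).
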