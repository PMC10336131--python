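# Methods

`edofscope` models the computational chain of a wavefront-coded,
extended-depth-of-field (EDOF) miniature microscope: a cubic phase plate in
the pupil makes the point spread function (PSF) nearly defocus invariant
over a ±150 µm range, a low-rank shift-variant forward model describes how
the coded system images a 3-D sample, and deconvolution (or a learned
restorer trained on simulated pairs) recovers an all-in-focus image.  This
note records the models, the defaults and why they were chosen, and what
the synthetic tests do and do not demonstrate.

## Optical model

The system is a finite-conjugate microscope with NA 0.16, focal length
1 mm, conjugate distance 6 mm, RGB channels at 470/530/590 nm, and a
Φ3.6 mm field of view.  PSFs are computed with the scalar pupil-function
model

    PSF(z, u, v) = | FT{ A(ρ) · exp(i [φ_cubic + φ_defocus(z) + φ_field(u, v)]) } |²

* **Defocus**: φ_defocus = (2π/λ) · z · (NA²/2) · ρ² on the normalized
  pupil radius ρ, the standard quadratic defocus phase.  At z = 150 µm this
  is ≈ 22.8 rad (3.6 waves) — deep defocus for an uncoded system.
* **Cubic phase**: the plate surface is h(x, y) = α(x³ + y³) on physical
  pupil coordinates (mm), with phase 2π(n−1)h/λ, n = 1.5.  The entrance
  pupil semi-diameter is derived from the geometry,
  a = conjugate · tan(asin NA) ≈ 0.97 mm, so the design range
  α = 0.005…0.075 mm⁻² spans roughly 30–450 rad of edge phase — from barely
  stronger than the design defocus up to very strong coding.
* **Field dependence**: the real device's shift variance comes from its
  multi-lens design; here it is emulated by parametric tilt and coma
  Zernike-like terms scaled by the normalized field vector (defaults 1.0
  and 0.5 waves at the pupil edge for a unit field).  They exist so the
  factorization and forward-model code faces genuinely nonuniform PSFs;
  they are configuration values, not a lens design.
* **Sampling**: the pupil fills a quarter of the FFT grid, so the PSF pitch
  is λ/(4·NA) (Nyquist for the incoherent cutoff 2NA/λ).  A hard
  anti-aliasing guard rejects any grid on which the phase step between
  adjacent pupil samples reaches π; `required_grid` sizes the grid from an
  analytic bound on the cubic + defocus + field phase gradient with a 0.8
  safety factor.  Strong coding (α = 0.075) needs grids around 2048².

**Sensor pitch.**  The object-space pixel pitch defaults to 3 µm, i.e. a
sensor Nyquist frequency of 167 cycles/mm.  This matches the device's 3 µm
two-point resolution (a 6 µm line-pair period): the sensor samples at the
resolution limit of the restored image.  The choice matters: at half that
pitch the Nyquist frequency sits at 0.55 of the diffraction cutoff, where
no cubic strength can hold 10% modulation over ±150 µm in an ideal-lens
model, and the design constraint below would be infeasible by construction.

## Modulation-strength selection

For each candidate α the MTF stack |FT PSF| is computed over the depth
range and resampled onto a canonical ±Nyquist frequency grid (65×65 by
default) so that stacks simulated on different pupil grids are comparable.
Two scalars summarize each candidate:

* **Fisher-information merit** — the depth-invariance score
  FI = Σ_f Σ_z [MTF(f, z+Δz) − MTF(f, z)]² / Δz², a discrete squared
  defocus derivative summed over all frequency bins up to Nyquist.  FI = 0
  iff the MTF is exactly defocus invariant.  (The literature names the
  merit; the discretization is this package's.)
* **Minimum Nyquist MTF** — the smallest MTF value at the four on-axis
  Nyquist points over all depths.  The design constraint is ≥ 0.1, keeping
  the coded spectrum above the noise floor so deconvolution can restore it
  without contrast reversal.

The sweep enumerates α inclusively over the design range, marks candidates
feasible by the 0.1 constraint, and selects the feasible candidate with
minimum FI.  On the default model the feasible set is {0.005, 0.010} and
α = 0.01 is selected (FI 2.1×10⁻³ vs 11.6 uncoded; min Nyquist MTF 0.109
vs 0.0017 uncoded).  On-axis the cubic+defocus PSF satisfies
PSF(+z) = PSF(−z) exactly (conjugate-flip symmetry of the pupil), so the
stack only simulates |z|; a test asserts the identity.

## Low-rank shift-variant imaging

The PSF sampled at M ≤ 49 field points per depth is vectorized into a
matrix P (ab×M) and factorized as P ≈ H·W with non-negative bases
H (ab×N) and coefficients W (N×M), N ≤ M, by cyclic HALS (hierarchical
alternating least squares): exact per-block least-squares updates clipped
at zero, seeded uniform-random initialization, dead components re-seeded
from the largest-residual column.  The objective ‖HW−P‖_F is recorded per
sweep and is non-increasing.  In channel-uniform mode one W is fitted
against the channel-stacked matrix [P_r; P_g; P_b] (bases stay per
channel), so all color channels share the same field weights — this is
what suppresses color fringing in the forward model.  Coefficients are
interpolated bilinearly between calibration points, clamped (constant)
outside the calibrated hull, and clipped at zero.

The forward model is then

    i = Σ_{i=1..N} (s ⊙ w_i) ∗ h_i

computed per channel with zero-padded FFT convolution cropped back to the
scene frame ("same" semantics; kernel centre at the floor-midpoint pixel
n//2, matching `fftshift`).  A brute-force superposition sum — every
source pixel deposits its own PSF — serves as the quadratic-cost oracle;
with an exact factorization the two routes agree to machine precision.
Defaults: a 3×3 field grid spanning ±0.7 of the field radius, N = 9 (=M,
exact on the grid; the `factorize` CLI prints a residual-elbow report over
ranks for choosing smaller N).

Multi-depth scenes are snapped one-hot to the depth grid (nearest plane),
each slice imaged with its depth's basis, and the slices summed — an
additive model with no occlusion, matching the training-data protocol.
Sensor noise is Poisson shot noise at a configurable gain plus Gaussian
read noise, clipped at zero, seeded.

## Simulation-supervision training data

Synthetic samples (beads / resolution-target bars / band-limited texture /
mixed) carry a depth map: a plane tilted along the image columns spanning
the full ±150 µm (bars use a three-step piecewise-planar map).  A
conventional through-focus acquisition (−150…+150 µm, 10 µm steps) is
emulated by blurring each pixel with the *uncoded* PSF at defocus
(pixel depth − plane).  Labels are all-in-focus fusions: per-pixel local
Laplacian energy in an 11×11 window picks the sharpest plane, the winner
index map is median-smoothed (11×11), and pixels are assembled from their
winning slices.  Inputs are the coded captures of the depth-decomposed
scene, optionally with sensor noise.  Pairs are cropped into aligned
random patches (the full-scale protocol is 20 patches of 512×512×3).

What the synthetic generator does *not* emulate: occlusion and 3-D
radiometry, microscope flat-fielding and registration error, chromatic
focal shift beyond per-channel λ, and real texture statistics.  Passing
tests therefore demonstrate the correctness of the pipeline's operators
and its self-consistency, not restoration quality on real tissue.

## Deconvolution

* **ADMM-TV** (shift-invariant): argmin ‖A·S−I‖² + λ_TV‖DS‖₁ with the TV
  split variable soft-thresholded, penalty ρ = 1, circulant operators on
  an edge-padded frame.  λ_TV = 0 is solved directly in Fourier with a
  10⁻¹² Tikhonov floor.
* **Shift-variant RL-TV**: multiplicative Richardson–Lucy with a TV factor
  1/(1 − λ_TV·div(∇S/|∇S|)), forward blur through the low-rank operator,
  ratio image with a guarded denominator, and back-projection.  Two
  adjoint modes exist: `exact` (default) applies the true adjoint
  Σ a_i·(R ⋆ p_i) — correlation, weights outside — giving a convergent RL
  scheme; `unflipped` back-projects with the unflipped PSF and weights
  inside the convolution, retained for fidelity studies.  The modes
  coincide for centro-symmetric PSFs.  λ_TV defaults to 1.5×10⁻⁴; |∇S| and
  the ratio denominator are floored at 10⁻⁸·max(capture); iterates stay
  non-negative and a NaN raises.  Channels are deconvolved independently
  with the shared channel-uniform weights.

The iteration carries no flux-normalization term, so with the zero-padded forward operator, estimates of samples
that touch the frame boundary decay there over many iterations.  Test
scenes are therefore interior-supported (a field-stop vignette); users
restoring full-frame data should pad captures or stop early.

## Restoration network accounting

The generator is a U-Net: four 4×4 stride-2 conv + LeakyReLU encoder
blocks (widths 128/256/512/512 full, 32/64/128/256 pruned), nine residual
blocks (two 3×3 convs + shortcut; width = bottleneck width), four decoder
blocks (bilinear upsample + 3×3 conv + ReLU) with skip connections fused
by channel concatenation (the full-resolution decoder stage has no skip
partner; its width defaults to half the first encoder width), and a 3×3
output conv (tanh for training, sigmoid behind a deployment flag).  The
discriminator is the standard 70×70 PatchGAN.  Parameter counts are pure
functions of the spec — convolution weights + biases, generator only, no
normalization layers (the convention is printed in the report header) —
and the printed full/pruned channel specs give a 78.9% reduction.  The
composite loss is a weighted sum of least-squares GAN, L2, and perceptual
(pluggable feature extractor) terms; zero weights disable a term and its
dependency.  `train_toy` is a small L2 trainer behind the optional torch
dependency and raises an actionable error without it.

## Numerical and reproducibility choices

* Coordinates: 0-based row-major pixels, origin top-left, PSF centre at
  n//2; boundary handling is zero-pad to linear convolution + centre crop,
  everywhere.
* TV gradient: forward differences with replicated edges; divergence is
  its negative adjoint.
* Every stochastic stage derives its stream from a global seed plus a
  stage tag (FNV-style hash, < 2³¹).
* The pipeline manifest records SHA-256 checksums of artifact *content*
  (TIFF arrays, HDF5 datasets), so reruns with the same config are
  verifiably identical regardless of container metadata; HDF5 files are
  written without timestamps.
* Default problem sizes (the package's own choice of study scale): 128²
  scenes, 3×3 field grid, 5-plane depth grid for end-to-end runs; the
  design sweep runs the full 31-plane, 15-candidate protocol; depth-fusion
  checks use 160² tilted textures with the full 10 µm scan.

## Known limitations

* The pupil model is an idealized stand-in for the ray-traced multi-lens
  design: absolute Strehl/MTF numbers are not those of the fabricated
  device, and the selected α (0.01 under this package's physical-units
  convention) need not match the device value chosen by trained-network
  scores.
* Field aberrations are parametric, not derived from lens prescriptions.
* The additive depth model ignores occlusion; fusion labels inherit the
  residual diffraction blur of the in-focus plane.
* `unflipped` back-projection can diverge for strongly asymmetric
  PSFs; it exists for comparison, not production use.
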