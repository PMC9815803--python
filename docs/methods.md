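# Methods

## The model

`pseudotomo` performs subtomogram averaging by maximum a posteriori
estimation of a 3D map V from cryo-ET tilt series. The data model treats
every 2D Fourier pixel of every particle crop as an independent complex
Gaussian observation of a CTF-modulated central slice of V:

    -log P(X_p | phi) ∝ sum_{f,j} |X_fjp - CTF_fp(j) V_fj(p)|^2 / sigma_j^2

where f indexes tilt images, j 2D frequencies, `phi` the particle's
alignment, and `sigma_j^2` the per-shell noise power. The projected view
composes a per-particle attitude R_p (shared across the series) with the
per-tilt stage rotation A_f and translation t_f; beam-induced motion adds
a per-tilt 3D offset T_pf.

Rather than evaluating this sum over 2D stacks, each particle is turned
into a *pseudo-subtomogram*: three 3D Fourier volumes built by forward
trilinear insertion of the 2D pixels at their tilted-slice frequencies,

    D_k = sum l(A^T j - k) CTF(j) X_j     (CTF-premultiplied data)
    W_k = sum l(A^T j - k) CTF(j)^2       (squared-CTF weight)
    M_k = sum l(A^T j - k)                (multiplicity; each pixel deposits 1)

after which the likelihood is approximated by a single 3D sum

    nll(R, T) = sum_k |D_k - e^{-2 pi i k.T} W_k V(R k)|^2 / (M_k sigma_k^2).

This moves all per-tilt bookkeeping (CTFs, dose weighting, geometry) into
a one-off construction step, so orientation search, classification-style
marginalisation and reconstruction proceed exactly as in single-particle
analysis, and the missing wedge needs no special treatment: voxels never
observed simply have M = 0.

The map update is regularised by a Gaussian prior on the signal power,

    V_k = [sum_p D_p(R_p^T k)/sigma_k^2] / [sum_p W_p(R_p^T k)/sigma_k^2 + 1/tau_k^2]

with per-shell noise power `sigma_k^2` re-estimated from residuals
(`sum |D - W V|^2 / (2 sum M)`) and signal power `tau_k^2` from the shell
power of V corrected by the mean CTF^2 (the `sum W / sum M` ratio), all
on one-voxel-thick shells. Half-set (gold standard) splitting is by even/
odd particle index; resolution is read from the FSC at 0.143.

## Fidelity of the 3D approximation, and its limits

The 3D form is *exact* when interpolation is trivial: a single untilted
tilt on the grid reproduces the 2D sum to machine precision (this is a
unit test). In general it differs in two documented ways:

1. **CTF premultiplication.** The triplet stores CTF-premultiplied data,
   so its exact 2D counterpart is the residual `CTF.X - CTF^2.V`; the
   plain Eq-style residual `X - CTF.V` differs by a CTF^2 weighting.
   The library exposes both (`nll_2d(premultiplied=...)`); tilt-series
   refinement uses the plain form.
2. **Noise smearing.** Within one tilt, neighbouring 2D pixels share
   trilinear corner voxels, so independent noise partially averages in D
   while the denominator `M sigma^2` models it as independent. With a
   flat generative noise spectrum the 3D sum is therefore systematically
   ~0.6x the 2D sum. Because `sigma^2` is a *model parameter estimated
   from residuals* (in both forms), the bias is absorbed per shell in
   actual use; with model-consistent spectra the two likelihoods agree to
   a few percent at SNR ~1. The residual bias concentrates in sliver
   voxels with M << 1 at slice edges, which is why the default
   multiplicity cut is M >= 0.5 (half an observation) rather than a
   token epsilon; the threshold is exposed in every evaluator.
3. **Displaced optimum.** The anisotropic insertion smear (exact spacing
   in-plane, trilinear across planes) leaves the approximate likelihood's
   noiseless optimum ~1 degree per Euler axis (up to ~3 degrees along
   soft, nearly degenerate directions) and ~0.1 px away from the
   generative pose, while the 2D likelihood peaks exactly at truth.
   This is far below the noise-driven error at realistic SNR (the
   end-to-end pose test recovers poses to ~1-2 degrees median at SNR
   0.5) but is why local-refinement unit tests compare against the
   objective's own optimum.

## Interpolation and gridding

All Fourier arrays are full complex cubes/planes in FFT order, objects
centred via `ifftshift`; inserting both j and -j of each real image
keeps D exactly Hermitian and double-counts consistently in every sum,
so no half-plane bookkeeping is needed at these box sizes (<= 64).

Slice *extraction* from a reference never interpolates the raw transform:
`FourierReference` zero-pads the real-space map 2x and divides by the
trilinear kernel's transform (per-axis sinc^2) first. Without this the
slices of a box-filling map are attenuated and decorrelated by tens of
percent, which visibly biases every amplitude-sensitive fit (a plain
trilinear reference biased the defocus estimate by ~2000 A in an early
version; with the prepared reference the noiseless bias is a few A).

Forward *insertion* is plain trilinear with no apodisation correction,
as the data model prescribes. The resulting attenuation/leakage is
handled at reconstruction: final maps are built in each particle's
refined frame (a pre-oriented construction, so accumulation is on-grid
and needs no second interpolation) on a 2x oversampled grid, then
cropped back. This raises the noiseless 200-particle phantom FSC from
~0.90-0.94 (plain path) to >0.97 on every shell up to 0.8 Nyquist.
The rotate-and-gather accumulation path (`backproject_accumulate` with a
non-identity rotation) remains for the in-loop EM updates where speed
matters more than the last few percent of correlation.

## CTF model

Phase function `chi = pi lambda dz(alpha) k^2 - (pi/2) Cs lambda^3 k^4 +
phase_shift + even Zernike terms`, CTF = `-(sqrt(1-w^2) sin chi +
w cos chi) * kappa(k)`, negative at low frequency for underfocus
(`CTF(0) = -w`). Odd (antisymmetric) Zernike terms multiply the complex
prediction by `e^{i psi(j)}`; they cannot enter |CTF|. Per-particle
defoci follow from the particle's depth along the beam at each tilt
(`defocus = base - (A_f pos)_z`, handedness configurable). The damage
envelope is the empirical critical-exposure curve
`exp(-dose / (2 (0.245 k^-1.665 + 2.81)))`; fitted per-tilt scale
factors `kappa_f(k) = s_f exp(-B_f k^2/4)` override it when estimated
(the B-factor/scale pair keeps the fit well-posed on few particles; a
free per-shell mode exists for diagnostics).

## Condensed single-pass tilt refinement

Writing `CTF(chi) = Re(c e^{i chi})` with `c = -w + i sqrt(1-w^2)`, the
particles of one tilt image condense into per-frequency accumulators
(complex data cross Q, complex/static power P and S, odd-side cross O,
and the data constant). Any phase perturbation shared by those particles
— a defocus offset, an astigmatism change, even Zernike terms — then
scores *exactly* as `const - 2 Re(kappa e^{i delta} Q) + kappa^2
[Re(e^{2 i delta} P) + S]/2`, and an odd phase as
`const' - 2 Re(kappa e^{i psi} O)`, without revisiting the particles.
Defocus is scanned (+-3000 A in 100 A steps by default) and the minimum
parabola-fitted; astigmatism is a 3-parameter simplex fit; aberrations
are fitted globally over the pooled data set by direct minimisation over
the Zernike coefficients of the chosen parity.

Geometry refinement precomputes, per particle and tilt, the full nll as
a function of 2D displacement with one FFT, windowed and represented as
a bicubic spline (values and gradients at sub-pixel positions). Rigid
per-tilt alignment optimises an in-plane rotation plus shift over the
summed splines. Particle motion maximises the summed spline likelihoods
over per-tilt 3D displacements under a Gaussian-process prior on the
increments between consecutive tilts *in acquisition order* (damage
accumulates in time, not in stage angle), with covariance
`sigma_d^2 exp(-dist/L)` over particle positions, independent per axis;
defaults `sigma_d = 1 A` per increment, `L = 500 A`. The first acquired
tilt anchors the trajectories. The kernel's limits are tested: L -> inf
forces one common trajectory equal to the rigid-shift solution; L -> 0
decouples the particles into independent ridge fits. Hyperparameters are
fixed user inputs, not evidence-optimised. L-BFGS with an analytic
gradient; every refinement step is accepted only if it does not worsen
the objective it scores.

## The generator and what passing tests do not show

The simulator renders each particle crop as a CTF-premultiplied,
dose-damped central slice of the phantom (through the same prepared
reference the tests use as oracle), places particles in a slab with a
minimum pairwise distance enforced on *projected* positions across the
tilt range (so crops stay single-particle in every image), and adds
white Gaussian real-space noise, so the per-shell noise power is flat
and analytic. The default acquisition is the dose-symmetric +-60 degree,
3 degree-step scheme (0, +3, -3, +6, ...), 3 e/A^2 per tilt, 300 kV,
Cs 2.7 mm, 7% amplitude contrast, 3 um nominal defocus with a drawn
per-tilt jitter of sigma 1500 A (autofocus variation), pixel 4 A,
box 48. SNR is reported as crop-average signal power over noise power;
`noise_sigma_for_snr` calibrates the noise to a target.

Real data differ in ways the generator deliberately omits: coloured
(ice/solvent) noise, detector MTF, crowding and overlapping neighbours,
sample deformation, per-frame motion within a tilt, and errors in the
fiducial-based pre-alignment beyond the rigid/motion models injected
here. Passing recovery tests therefore demonstrates correctness of the
estimators under their own data model, not field performance.

Multi-tomogram studies (the noiseless reconstruction benchmark) use a
defocus ladder of 1.2-4.5 um across simulated tomograms; with a single
tomogram all tilts share nearly one defocus and the CTF zeros are
genuinely information-free, capping any fidelity figure.

## Numerical choices and degenerate inputs

- Shells: one voxel thick, indexed by rounded |k|; frequencies with any
  component beyond `n/2 - 1` are excluded from insertion and likelihoods.
- Empty shells carry the previous sigma^2 forward; shells with no
  observations have undefined tau^2 and are treated as an infinitely
  strong prior (V = 0) in the map update.
- Orientation grids are uniform in the three Euler angles within +-3
  prior sigmas (HEALPix-style sampling would be denser near the poles
  but is unnecessary at these search ranges); grid ties break to the
  lowest linear index; marginal weights use log-sum-exp.
- Simplex-based optimisers get explicit initial simplices because
  degrees, Angstrom and azimuth live on incommensurate scales.
- Noiseless inputs are legal everywhere; a vanishing noise power in a
  *populated* shell is an error.
- Box sizes are even; 2D MRC images read back with a singleton z axis.

## Problem sizes

The validation battery (`pseudotomo.benchmarks`, also driven by
`scripts/acceptance.py`) runs at boxes of 32-64 voxels with 12-200
particles per study and 7-41 tilts, sizes at which every figure of merit
is stable across seeds while the whole battery completes on a single CPU
core in minutes. The figures are properties of the estimators, not of
these sizes; the package applies unchanged to larger boxes.

## Known limitations

- Single-class refinement only: no classification or initial-model
  generation, no solvent masking, no sharpening.
- The diagonal 3D noise model is an approximation (see above); users who
  need exact 2D likelihoods for small data can evaluate `nll_2d`
  directly.
- Motion is translational only, between tilt images (no movie frames,
  no beam-induced rotation), and its prior hyperparameters are fixed
  inputs.
- The marginalised orientation weights are computed but the map update
  uses the MAP pose per particle; full weighted backprojection over the
  orientation grid would be a straightforward extension.
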