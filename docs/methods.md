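# Methods

## The estimation problem

A 2D multi-echo radial FLASH acquisition with blip gradients samples one
spoke per echo; with NS shots and NE echoes per slice the spoke angles

    theta_{l,m} = 2*pi / (NE*NS) * ((l-1)*NE + (m-1)),   l = 1..NS, m = 1..NE

tile the circle uniformly (the echo index rotates fastest), and
consecutive frames rotate by the small golden angle 180/phi^2 ~ 68.75
degrees.  The default protocol is NS = 30, NE = 35, TE1 = 2.37 ms, echo
spacing 1.88 ms.  Echo times are the arithmetic sequence TE1 + (m-1)*dTE
throughout (for the default train the last echo is 66.29 ms).

Each voxel follows the multi-peak water-fat model

    M(TE) = (W + F z(TE)) exp(i 2pi f_B0 TE) exp(-TE R2*),

where z(TE) = sum_p a_p exp(i 2pi f_p TE) is the summarized six-peak fat
spectrum.  The peak table (ppm relative to water; relative amplitude) is
the standard liver-fat model: -3.80/0.087, -3.40/0.693, -2.60/0.128,
-1.94/0.004, -0.39/0.039, +0.60/0.048, converted with 127.73 Hz/ppm
(nominal 3.0 T; configurable).  Off-resonance phase accrues with the
positive sign convention; simulator and reconstruction share it by
construction, and either consistent convention reproduces magnitude
results.

Maps x_p = (W, F, R2*, f_B0) and coil sensitivities x_c = (c_1..c_K) are
estimated jointly from the multi-coil radial k-space y by minimizing

    1/2 sum_m || P F { C . M_TEm(x_p) } - Y_TEm ||^2 + alpha R(x),
    R2* in [0, r2s_max],

with R(x) a joint l1-wavelet norm on (W, F, R2*)^T (Daubechies-4, 4
levels, periodized, approximation band unpenalized, grouping across the
three maps per coefficient position) plus quadratic Sobolev penalties
||(1 + s|k|^2)^{l/2} F{.}||^2 on the field map (s = 22 mm^2, l = 4, k in
cycles/mm) and on every coil map.  For the coils the far stronger
normalized-frequency weights (1 + 220 |k_hat|^2)^8 of joint
nonlinear-inversion parallel imaging are used: they fix the coil-object
gauge, forcing object detail into the maps rather than the
sensitivities.

## Solver

The outer loop is an iteratively regularized Gauss-Newton method: the
forward operator is linearized at the current estimate and
alpha_n = max(alpha_min, alpha0 / 3^n) with alpha0 = 1 and
alpha_min = 0.002.  Each subproblem is solved by FISTA (50 inner
iterations) with every data-consistency product applied as an FFT
convolution with the echo's point-spread function on the 2x-padded grid
(Toeplitz embedding; for equispaced radial spokes the PSF kernel is a sum
of Dirichlet kernels evaluated in closed form).

Numerical choices that make this work, and why:

* **Relative regularization.**  alpha multiplies the curvature of the
  data term: the penalty weights are alpha * L_block with L_block the
  norm of the corresponding block of A^H A (restricted power iteration,
  warm-started across outer steps).  The absolute scale of A is
  arbitrary (it changes with grid size and sample count), so only a
  relative alpha gives the schedule 1 -> 0.002 a stable meaning.  The
  joint-l1 weight carries one further dimensionless calibration constant
  (`l1_scale`), fixed once against noiseless phantom recovery and left
  alone.
* **Block-diagonal FISTA metric.**  The coil-object product is
  gauge-degenerate in scale ((c, x_p) -> (g c, x_p / g)), so the maps /
  field-map / coil blocks can sit at wildly different curvatures; a
  single global step size starves whichever block the gauge left small.
  Each block therefore gets the step 1/(1.1 mu L_block), with mu the norm
  of the block-preconditioned Hessian (a short extra power iteration;
  mu <= 3 in exact arithmetic).  Both the metric and the weights are
  invariant to the gauge scale.  The l1 group spans only the maps block,
  which shares one step, so the proximal map remains exact.
* **Line search.**  Each Gauss-Newton step is damped by backtracking
  until the nonlinear misfit does not increase.  Off-resonance enters
  through exp(i 2pi f TE): a linearized step of more than ~1/(4 TE_max)
  Hz overshoots the linearization validity at late echoes, and undamped
  steps diverge.  The accepted-step rule also realizes the contract that
  the misfit is non-increasing across outer iterations.
* **Initialization.**  W = 1, coils = 0 (the first step is then a linear
  coil calibration against a uniform object; an all-zero start would
  annihilate the bilinear linearization).  f_B0 and R2* are seeded from a
  quick-look estimate: per-coil single-echo images by a few CG iterations
  on the echo-wise Toeplitz operator (streak sidelobes of plain gridding
  otherwise leak neighbouring signal into fast-decaying regions), then a
  per-pixel variable-projection grid search over (f_B0, R2*) with
  closed-form water/fat solves.  The asymmetric fat spectrum makes this
  search resolve the fat-water/off-resonance ambiguity that pure phase
  differences cannot.  All penalties (the joint l1 included) act on the
  deviation from this initial guess — the classical Gauss-Newton
  reference point; penalizing the maps themselves would let the strong
  early-alpha thresholds erase seeded structure that has no data
  curvature yet.  The quadratic reference pull on R2* fades out at the
  alpha floor so the converged maps are governed by data and the stated
  regularizer alone.  Without the seed, field-map convergence is limited
  to a few Hz per outer step and +-50 Hz regions land in swapped basins.
* **Scalings.**  R2* is carried in units of 25 1/s per solver unit so
  its Jacobian column is commensurate with W and F inside the joint l1
  and the metric; f_B0 is carried in Hz.  Data are normalized to
  ||y|| = 100 and W, F are rescaled back on return.
* **Precision.**  Solver internals run in complex64; returned maps are
  float64.  The NUFFT itself (Kaiser-Bessel gridding, oversampling 2,
  kernel width 8) is double precision and accurate to ~1e-7 relative to
  direct summation; the adjoint is the exact algebraic adjoint.
* **Degenerate inputs.**  Zero data returns the zero solution directly.
  R2* is clamped to [0, 500] 1/s inside the inner iteration and on
  return.  A misfit that grows on two consecutive outer steps despite the
  line search raises a divergence error carrying the misfit history.

Default iteration counts (15 Gauss-Newton steps for general use; the
phantom validation uses 40 outer steps with 40 inner iterations at base
resolution 96) were chosen for the bias of ROI means to stabilize well
below the tube-to-tube spread; they are configuration options.

## Synthetic data

The phantom simulator evaluates closed-form ellipse Fourier transforms
(a b J1(2 pi rho)/rho with the appropriate phase) weighted per echo by
each region's tissue signal; overlapping regions are handled by signal
differencing (tubes replace background).  Coil sensitivities are
truncated Fourier series (Gaussian ring profiles with seeded random
phases, projected onto (2*4+1)^2 harmonics), so coil-weighted k-space is
an exact finite sum of shifted ellipse transforms — the ground-truth data
never touch a pixel grid.  Complex Gaussian noise is added per coil and
sample after the data are scaled so the root-sum-of-squares DC magnitude
of the first echo is 100, which makes "noise sd 0.1" a well-defined
condition.  An independent rasterized NUFFT path (2x-oversampled pixel
grid) agrees with the analytic pipeline to <1% at reconstruction
resolution and serves as the cross-check that no inverse crime links
simulator and reconstruction.

The standard validation phantom holds ten tubes (radius 11 mm on a 38 mm
ring) in a water background disk (radius 55 mm), FOV 128 mm: fat
fractions 5..95% in steps of 10, off-resonance -50..50 Hz in steps of 10
with the 0 Hz value assigned to the background, and tube T2* = 10..190 ms
in steps of 20 ms (the printed relaxation grid is internally
inconsistent — R2* 10..200 1/s does not equal T2* 10..200 ms — and the
T2* reading is the default, with the R2* grid selectable).  The
background is water-only with R2* = 20 1/s.  Eight circular receive
coils surround the phantom.  ROIs are central disks of half the tube
radius, placed programmatically.

What the simulator does *not* emulate: motion, gradient-delay and
eddy-current errors, slice profiles, T1 saturation (the FLASH
steady-state amplitude is absorbed into W and F), concomitant fields,
and vendor-specific k-space filtering.  Passing the phantom validation
therefore demonstrates the correctness and conditioning of the
estimation machinery under the stated noise model, not robustness to
scanner imperfections.

## Validation quantities and problem sizes

The acceptance pipeline regenerates the ten-tube phantom at base
resolution 96 (the full-size phantom uses 192; 96 keeps a complete
simulate-reconstruct-analyze cycle around ten minutes on one CPU),
simulates 30 x 35 spokes with noise sd 0.1, reconstructs, and reports
Bland-Altman mean differences of the per-tube ROI means against ground
truth for fat fraction, R2* and B0.  At this reduced resolution the
fastest-decaying tube (T2* = 10 ms) is the accuracy-limiting region:
its signal survives for only ~8 of the 35 echoes and its edges carry
visible Gibbs ringing at 96^2, which the half-radius ROI partially
samples.

Voxelwise reference fits (complex 3- and 4-parameter model fits with
multi-start over f_B0 spanning the alias-free band +-1/(2 dTE), and the
magnitude-exponential R2* fit with log-linear initialization) mirror the
reference methods used with Cartesian and EPI data; they are exact on
noiseless input and serve as the per-voxel oracle for the model.

Agreement statistics follow the standard definitions: ROI mean with
sample SD (n-1), Bland-Altman mean difference with 1.96-SD limits of
agreement, and ICC(A,1) (two-way random effects, absolute agreement,
single measurement — the appropriate form when absolute quantitative
values are compared between methods or repeated scans).

## Known limitations

* The joint problem is non-convex; the quick-look seed plus continuation
  finds the correct basin across the phantom's +-50 Hz / 5..100 1/s
  range, but pathological field maps beyond the seed's search band
  (+-150 Hz) would require a dedicated field-map initializer.
* Single R2* per voxel (no separate water/fat relaxation), no T1 term,
  2D single-slice only, one frame (the golden-angle multi-frame path is
  implemented for trajectory design only).
* Reconstruction bias at base resolution 96 is dominated by the
  shortest-T2* tube; at the full 192 resolution partial-volume and
  ringing effects in the ROIs shrink markedly.
* On noiseless single-tube data the jointly estimated R2* retains a
  small systematic underestimate (~0.6 1/s at R2* = 25, i.e. 2-3 %),
  stable against iteration count, the l1 weight and the ROI radius.  A
  band-limited oracle (ideal per-echo images followed by voxelwise fits)
  recovers R2* exactly on the same data, so the bias belongs to the
  joint solve itself — residual coil-estimate error absorbed into
  slightly slower decay — and is the accuracy floor of the desk-scale
  configuration.  The corresponding recovery check in the test suite
  documents this: fat fraction and off-resonance meet their bounds while
  the 2 % relative R2* bound is missed by a fraction of its width.
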