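# Methods

This note documents the models, numerical choices and limitations of the
`ctdr` study pipeline.  Everything quantitative stated here is computed by
the test suite or the `analysis/` scripts.

## Study design

A treatment plan is optimized **once** on the clean CT and held fixed.  Each
degradation level then filters (and optionally adds noise to) the CT, the
dose is recomputed with the fixed plan, and similarity to the clean-CT dose
is scored with a global 3D gamma test (1 mm / 1 %, 10 % dose threshold) over
the external contour and the PTV.  Separately, the scenario-based robustness
evaluation (worst case, voxel-wise minimum, `d50`) is repeated on degraded
CTs to verify that the robustness *budget* of the plan is not consumed by
the degradation.  Re-optimization on degraded CTs is deliberately out of
scope — the question is whether a dose computed on a degraded image is still
the clinical dose.

## Synthetic phantoms

Anatomy-like phantoms are ordered lists of geometric primitives (slabs,
cylinders, spheres) carrying HU values; later primitives overwrite earlier
ones.  Four canonical cases span the homogeneous-versus-interface contrast
that drives the results: brain-like (40 HU tissue inside an 1100 HU skull
shell; homogeneous surroundings), thorax-like (chest-wall CTV straddling a
40 → −750 HU lung interface), abdomen-like and pelvis-like.  Defaults are
96³ voxels at 2 mm (1 mm available via the spec), with zero-mean white
Gaussian baseline noise at levels typical of clinical planning CTs per
localization (brain 6.0, thorax 2.3, pelvis 9.6, abdomen 11.5 HU).  The CTV
must lie strictly inside the external contour and, for interface-class
targets, next to a ≥ 500 HU density step.

The wire phantom is a 0.18 mm wire (HU 3000, the saturated-metal class) in
water, rasterized with 32× sub-voxel area weighting on a 0.25 mm in-plane
grid, blurred by an isotropic Gaussian PSF of known FWHM, then noise.  The
water cylinder's quoted "20" diameter is read as 20 cm, which exceeds the
simulated field of view; water therefore fills the transversal grid.

What the phantoms do *not* emulate: anthropomorphic organ shapes, beam
hardening, correlated/streak noise, motion.  Passing tests show that the
*mechanism* (robust-plan insensitivity to low-pass filtering) holds and that
the pipeline measures it correctly; per-localization millimetre limits for
real patients are outside what synthetic geometry can establish.

## Degradation operators

Low-pass filtering is separable and isotropic in millimetres, with air
(−1000 HU) padding and the external contour dilated by the kernel
half-width.  Gaussian kernels are specified by FWHM and truncated at 4 σ
(then renormalized).  Boxcar kernels use a **zero-phase, noise-exact**
discretization: for odd width/spacing ratios the plain uniform kernel; for
even ratios a closed-form mixture of the two adjacent odd uniform kernels
chosen so that `Σk² = spacing/width` exactly (a 2-voxel boxcar becomes
`[1/6, 2/3, 1/6]`); for non-integer ratios, fractional overlap end-weights.
Rationale: a staggered even-length moving average shifts the volume by half
a voxel — on the 2 mm study grid a 1 mm spurious rigid setup error that
contaminates the gamma comparison — while the mixture keeps the square-root
noise-pooling law exact, which the exposure analysis relies on.  The cost is
a slightly heavier-tailed kernel than an ideal rect.  A related inherent
fact: the equal-second-moment Gaussian (σ = w/√12) pools about 2 % more
noise per axis than the boxcar (∫g² differs), so the two kernels agree in
delivered noise std to ~3.5 % in 3D, not exactly.

Noise is added **after** filtering (so the delivered noise level is
independent of the filter), i.i.d. Gaussian, only inside the expanded
external contour, with a dedicated seed per sweep cell derived from the
sweep seed.

## Dose engine

A deterministic analytic pencil-beam model stands in for a commercial
Monte-Carlo engine.  Beams are restricted to the six cardinal directions,
which makes the water-equivalent thickness (WET) of every voxel an exact
half-voxel-corrected cumulative sum of RSP along a grid axis; `trace_wet`
additionally supports arbitrary rays by fine-step sampling (min-spacing/4,
trapezoidal integration) and is validated against a 10× finer grid.

The depth-dose curve is `D(w) = 0.3·(1 − 0.9·min(w,R)/R)^−0.45 + Gaussian
peak at R`, normalized to 1 at the peak, with straggling width
`σ_R = √((0.01 R)² + (2 mm)²)` and a hard cut at `R + 3σ_R`.  The 2 mm
intrinsic width keeps Bragg peaks resolvable on the 2 mm grid and SOBP
plateaus flat at ~4 mm layer spacing; the peak-to-entrance ratio is ≈ 6.
SOBP layer weights come from non-negative least squares against a unit
plateau, with the deepest layer placed one straggling width beyond the
distal plateau edge (otherwise the plateau rolls off exactly at the edge).
Lateral spot profiles are area-normalized Gaussians whose σ grows linearly
with central-axis WET from σ_air (default 5 mm, the ≈12 mm FWHM clinical
beam-width class) to 2 σ_air at the deepest layer.  A range shifter of WET
`t` cm subtracts `10 t` mm of range.  Nuclear halo, secondaries and RBE are
omitted; doses are physical-dose surrogates, linear in the spot weights, and
carry no Monte-Carlo noise floor — gamma comparisons are exact to machine
precision on identical inputs.

## Scenarios and minimax optimization

Robustness scenarios pair six cardinal rigid shifts of magnitude `u` with
density scales `1 ± δ`, giving 12 perturbed scenarios plus the nominal (13).
The pairing of every shift with every density scale is one reading of the
clinical recipe; the alternative (6 + 2 = 8 perturbed) exists, and the
scenario set is a explicit, swappable object for that reason.  Patient
shifts are trilinear resamplings of the CT (integer-voxel shifts reduce to
exact rolls); the density scale multiplies the RSP map.  Scenario doses are
computed in the room frame and rigidly mapped **back to the patient frame**
before evaluation, so all statistics live on the nominal contours.

The optimizer minimizes the worst-scenario weighted quadratic deviation of
the CTV dose from prescription, with underdosed voxels weighted 6× (coverage
is the binding clinical constraint).  Dose is linear in the weights, so one
influence matrix per scenario is precomputed (float32, CTV subsampled to
1200 voxels).  Descent: a smooth warm-up on the scenario-average objective
(first third of 400 iterations), then projected subgradient steps on the
current worst scenario; the step size comes from a power-iteration Lipschitz
estimate; weights are clipped at zero; the final weights are rescaled so the
nominal median CTV dose sits 1 % above prescription, which keeps every
scenario's low tail above the V95 level.  On both default phantoms the
worst-scenario V95[CTV] exceeds 98 %.

## Gamma evaluation

For each reference voxel at or above the threshold, candidate offsets sorted
by distance are scanned with early termination (once the distance term alone
exceeds the current minimum, no farther candidate can win), interpolating
the evaluated dose trilinearly.  The candidate lattice uses a DTA/10 step
out to 3 DTA — the region that decides pass/fail — and a DTA/5 step beyond,
out to the γ = 10 cap; the coarser far field only affects voxels already far
above γ = 1.  The per-voxel loop is numba-compiled.  A pure-numpy exhaustive
oracle (dense lattice, no search tricks) validates the production path to
< 0.02 in γ on small grids — in practice they agree to machine precision.
Normalization defaults to the maximum reference dose inside the external
contour; prescription normalization is available.  The threshold is applied
to the reference dose.

## Robustness statistics

`V_D` is the percentage of ROI voxels at or above dose `D`.  The worst-case
scenario is the one minimizing V95[CTV]; the voxel-wise minimum distribution
is the element-wise minimum over scenario doses.  `d50` — the largest dose
`D` such that at least half of the scenarios still satisfy `V_D[CTV] > 98 %`
— is found by bisection to 0.1 % of prescription (the passing-scenario count
is non-increasing in `D`, so bisection is valid; tests compare against an
exhaustive 0.01 Gy scan).  OAR deltas report the maximum over scenarios of
the metric change (mean dose, near-max D2 %) as a percentage of
prescription.

## Image-quality metrology

The wire centre is found on the z-averaged slice (max ridge, centroid
refinement) and radial profiles are sampled along nine equally spaced
transversal directions with 4× oversampling, averaged over slices and
directions after subtracting the median of the profile tails (water
annulus).  FWHM comes from linear interpolation at half maximum; the MTF is
the magnitude of the Fourier transform of the averaged LSF normalized at
zero frequency, summarized by the 50 % and 10 % crossings in cm⁻¹.  Recovery
of generator PSFs between 1.0 and 2.5 mm is accurate to < 2 %; very wide
PSFs (≳ 3 mm) with strong noise can make the thin-wire ridge undetectable,
which the code reports as an error rather than guessing.

## Exposure model

`Var c ∝ 1/(E·Δ·ξ⁴)` is treated as an algebraic scanner model and **not**
verified by image-domain smoothing: filtering an already reconstructed image
rescales noise differently from acquiring with a wider system PSF, because
tomographic noise lives in the projection domain.  The broadening factor
`b = √(ξ² + FWHM_eq²)/ξ` uses the boxcar's equal-variance Gaussian
equivalent (σ = w/√12, so 4 mm ↔ 2.7 mm FWHM) and is cross-checked by
numerical convolution of 1D profiles; the exposure-sparing factor is
`b⁴ · f² · d` for a tolerated noise increase `f` and slice-width factor `d`.
For the 1.4–1.5 mm PSF class and a 4 mm boxcar this gives b ≈ 2.1 and a
sparing factor ≈ 20.

## Problem sizes and defaults

The study runs on 96³ × 2 mm grids with two-field plans (~2500–3500 spots),
13 scenarios, and sweep grids subsampled from the full width list
(2–8 mm in 2 mm steps, 10–50 mm in 4 mm steps) — sizes chosen so the entire
suite and the analysis scripts run on a laptop-class single core in minutes.
Sweeps use one seeded noise realization per cell (a repeats option exists);
all stochastic results re-run bit-exactly from the recorded config hash and
seed.

## Known limitations

* Cardinal-direction beams only in the grid engine; no couch/gantry angles.
* The analytic Bragg curve is a shape surrogate: no absolute dosimetry, no
  agreement with any commercial engine is claimed.
* The HU→RSP curve is a generic clinical-shaped stand-in.
* Synthetic phantoms cannot reproduce patient-specific acceptable-width
  tables; only the qualitative ordering (homogeneous ≥ interface) and the
  plateau behaviour are claimed, and both are tested.
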