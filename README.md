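# ctdr — CT degradation robustness of proton-therapy dose distributions

How much CT image quality does proton-therapy dose computation actually
need?  Treatment planning uses high-quality x-ray CTs, but adaptive
workflows (frequent verification scans), ultra-low-dose protocols, proton
CTs and PET-derived attenuation maps all deliver images with coarser spatial
resolution and more noise.  `ctdr` is an in-silico study of how far the
resolution of a planning CT can be lowered — and how much noise can be added
— before the computed proton dose distribution changes clinically.

The core argument is that a robustly optimized plan is, to first order,
insensitive to low-pass filtering of its patient model.  Writing the CT map
as voxels `c_k` and the dose operator as `D_i(c_1, …, c_N)`, a minimax-robust
plan satisfies `D_i(c(s)) ≈ D_prescr` for rigid shifts `s` within the setup
margin `u`, hence `dD_i/ds ≈ 0`.  A convolution `c * p` with a kernel `p`
narrower than `u` is a weighted superposition of such shifted maps, so the
Taylor expansion of `D_i` loses its linear term and the dose is unchanged to
`O(s²)`.  The package tests this prediction end to end on synthetic digital
phantoms:

* **phantoms** — anatomy-like HU volumes (brain-like homogeneous target,
  chest-wall target at a soft-tissue/lung interface, abdomen, pelvis) and a
  0.18 mm wire-in-water resolution phantom;
* **degrade** — zero-phase 3D boxcar / truncated-Gaussian low-pass filters
  (widths in mm, exact white-noise pooling) plus additive white Gaussian
  noise applied after filtering;
* **dose_engine** — a deterministic analytic pencil-beam proton engine (WET
  ray tracing, parameterized Bragg curves, depth-broadened lateral Gaussian,
  range shifter, SOBP weights);
* **robust_plan** — 6-shift × 2-density-scale scenario sets and minimax
  optimization of spot weights for CTV coverage (`V95 ≥ 98%` worst case);
* **gamma_eval** — global 3D gamma index (1 mm / 1%, 10% dose threshold)
  with sub-voxel interpolation, plus a brute-force oracle;
* **robust_eval** — scenario dose statistics: worst-case and voxel-wise
  minimum `V95[CTV]`, the `d50` coverage-dose statistic, OAR deltas;
* **image_quality** — LSF/FWHM/MTF metrology on the wire phantom and noise
  measurement in homogeneous regions;
* **exposure** — the tomographic noise–resolution–exposure scaling
  `Var c ∝ 1/(E·Δ·ξ⁴)` and the resulting exposure-sparing factors;
* **pipeline** — filter-width and noise sweeps with full provenance, and the
  maximum-acceptable-width summary.

## Worked example

```python
from ctdr.phantoms import brain_spec, generate_phantom
from ctdr.robust_plan import make_scenarios, optimize_minimax
from ctdr.dose_engine import compute_dose
from ctdr.degrade import FilterKernel, apply_lowpass
from ctdr.gamma_eval import GammaCriteria, gamma_index

ct, rois = generate_phantom(brain_spec(seed=42))     # 96³ @ 2 mm, 6 HU noise
scen = make_scenarios(u_mm=3.0, delta=0.035)          # 13 scenarios
opt = optimize_minimax(ct, rois, scen, prescription=54.0, seed=0)
print(f"worst-scenario V95[CTV] = {opt.worst_v95:.2f}%")

reference = compute_dose(opt.plan, ct, roi=rois)      # clean-CT dose
degraded, _ = apply_lowpass(ct, FilterKernel("boxcar", 4.0), rois["external"])
dose = compute_dose(opt.plan, degraded, roi=rois)     # same fixed plan
res = gamma_index(reference, dose, GammaCriteria(), rois)
print(f"gamma pass rate (external) = {res.pass_rates['external']:.2f}%")
```

prints

```
worst-scenario V95[CTV] = 98.83%
gamma pass rate (external) = 99.41%
```

i.e. the plan keeps clinical target coverage in every setup/density scenario,
and after degrading the CT with a 4 mm boxcar the recomputed dose still
agrees with the clean-CT dose at a 1 mm/1% gamma pass rate well above the
98% acceptance level.  The numbered scripts under `analysis/` run the full
study: phantom generation, wire-phantom metrology, planning, the width and
noise sweeps (the homogeneous brain case tolerates boxcar widths up to 6 mm
over the whole irradiated volume and far more inside the PTV, while the
chest-wall interface case fails beyond 4 mm; added noise below ~20 HU leaves
pass rates on a plateau), the scenario-robustness comparison, and the
exposure model.  Their tables land in `results/`.

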