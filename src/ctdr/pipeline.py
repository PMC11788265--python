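"""Orchestration of the in-silico study: degradation sweeps and their summaries.

The workflow mirrors the study design: a plan is optimized *once* on the
clean CT and held fixed; for every degradation level the CT is filtered (and
optionally made noisy), the dose is recomputed with the fixed plan, and the
gamma test against the clean-CT dose is scored over the external contour and
the PTV.  Sweep results carry full provenance (config hash, seed) and rerun
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .degrade import FilterKernel, NoiseModel, add_noise, apply_lowpass
from .dose_engine import Plan, compute_dose
from .gamma_eval import GammaCriteria, gamma_index
from .phantoms import PhantomSpec, generate_phantom
from .robust_plan import make_scenarios, optimize_minimax
from .volumes import CalibrationCurve, DEFAULT_CALIBRATION, ROISet, Volume

__all__ = [
    "SweepConfig",
    "SweepResult",
    "prepare_case",
    "run_width_sweep",
    "run_noise_sweep",
    "max_acceptable_width",
]

log = logging.getLogger("ctdr.pipeline")


@dataclass
class SweepConfig:
    """Degradation-sweep configuration.

    Width lists default to the study grid: boxcar widths 2..8 mm in 2 mm
    steps then 10..50 mm in 4 mm steps; the default "fast" profile used by
    the analysis scripts subsamples this.
    """

    phantom: PhantomSpec
    filter_kind: str = "boxcar"
    widths_mm: Sequence[float] = field(
        default_factory=lambda: tuple(range(2, 10, 2)) + tuple(range(10, 51, 4))
    )
    noise_sigmas_hu: Sequence[float] = (0.0,)
    criteria: GammaCriteria = field(default_factory=GammaCriteria)
    score_rois: Sequence[str] = ("external", "PTV")
    pass_threshold: float = 98.0
    prescription: float = 54.0
    setup_uncertainty_mm: float = 3.0
    density_uncertainty: float = 0.035
    beam_directions: Sequence[str] = ("+x", "+y")
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.widths_mm) != sorted(self.widths_mm):
            raise ValueError("widths must be sorted ascending")
        if not (0.0 < self.pass_threshold < 100.0):
            raise ValueError("pass threshold must be in (0, 100)")

    def digest(self) -> str:
        payload = {k: repr(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class SweepResult:
    table: pd.DataFrame  # columns: width_mm, noise_sigma_hu, roi, pass_rate, n_voxels
    provenance: Dict[str, object]

    def rates(self, roi: str, noise_sigma: float = 0.0) -> pd.DataFrame:
        t = self.table
        sel = (t["roi"] == roi) & np.isclose(t["noise_sigma_hu"], noise_sigma)
        return t[sel].sort_values("width_mm")


@dataclass
class PreparedCase:
    ct: Volume
    rois: ROISet
    plan: Plan
    reference_dose: Volume
    worst_v95: float


def prepare_case(config: SweepConfig, curve: CalibrationCurve = DEFAULT_CALIBRATION) -> PreparedCase:
    """Generate the phantom, optimize the minimax plan on the clean CT, and
    compute the clean-CT reference dose (the plan is then held fixed)."""
    t0 = time.perf_counter()
    ct, rois = generate_phantom(config.phantom)
    scen = make_scenarios(config.setup_uncertainty_mm, config.density_uncertainty)
    opt = optimize_minimax(
        ct, rois, scen,
        prescription=config.prescription,
        curve=curve,
        beam_directions=tuple(config.beam_directions),
        setup_margin_mm=config.setup_uncertainty_mm,
        density_margin=config.density_uncertainty,
        seed=config.seed,
    )
    ref = compute_dose(opt.plan, ct, curve, rois)
    log.info(
        "prepared case %s: worst-scenario V95=%.2f%% (%.1f s)",
        config.phantom.name, opt.worst_v95, time.perf_counter() - t0,
    )
    return PreparedCase(ct, rois, opt.plan, ref, opt.worst_v95)


def _one_cell(
    case: PreparedCase,
    config: SweepConfig,
    width: float,
    noise_sigma: float,
    noise_seed: int,
    curve: CalibrationCurve,
) -> List[dict]:
    t0 = time.perf_counter()
    kernel = FilterKernel(config.filter_kind, width)
    external = case.rois.by_role("external")
    degraded, ext_exp = apply_lowpass(case.ct, kernel, external)
    if noise_sigma > 0:
        degraded = add_noise(degraded, NoiseModel(noise_sigma, noise_seed), ext_exp)
    dose = compute_dose(case.plan, degraded, curve, case.rois)
    masks = {"external": external}
    for name in config.score_rois:
        if name in case.rois:
            masks[name] = case.rois[name]
    res = gamma_index(case.reference_dose, dose, config.criteria, masks,
                      prescription=config.prescription)
    rows = []
    for name in config.score_rois:
        if name in res.pass_rates:
            rows.append(
                dict(width_mm=width, noise_sigma_hu=noise_sigma, roi=name,
                     pass_rate=res.pass_rates[name], n_voxels=res.n_evaluated[name])
            )
    log.info("width=%g mm sigma=%g HU: %s (%.1f s)",
             width, noise_sigma,
             {r["roi"]: round(r["pass_rate"], 2) for r in rows},
             time.perf_counter() - t0)
    return rows


def _provenance(config: SweepConfig, case: PreparedCase) -> Dict[str, object]:
    from . import __version__

    return {
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "worst_v95_at_planning": case.worst_v95,
    }


def run_width_sweep(
    config: SweepConfig,
    case: Optional[PreparedCase] = None,
    curve: CalibrationCurve = DEFAULT_CALIBRATION,
) -> SweepResult:
    """Gamma pass rate versus low-pass filter width at zero added noise.

    Width 0 (the identity degradation) is always included and scores 100%.
    """
    case = case or prepare_case(config, curve)
    rows: List[dict] = []
    widths = [0.0] + [w for w in config.widths_mm if w > 0]
    for w in widths:
        if w == 0:
            for name in config.score_rois:
                if name in case.rois:
                    n = int((case.rois[name] & (case.reference_dose.data > 0)).sum())
                    rows.append(dict(width_mm=0.0, noise_sigma_hu=0.0, roi=name,
                                     pass_rate=100.0, n_voxels=n))
            continue
        rows.extend(_one_cell(case, config, w, 0.0, config.seed, curve))
    return SweepResult(pd.DataFrame(rows), _provenance(config, case))


def run_noise_sweep(
    config: SweepConfig,
    case: Optional[PreparedCase] = None,
    curve: CalibrationCurve = DEFAULT_CALIBRATION,
) -> SweepResult:
    """Gamma pass rate over the (filter width, added noise) grid.

    One seeded noise realization per cell; the seed is derived from the
    sweep seed and the cell coordinates, so results rerun bit-exactly.
    """
    case = case or prepare_case(config, curve)
    rows: List[dict] = []
    for iw, w in enumerate(config.widths_mm):
        for isig, sig in enumerate(config.noise_sigmas_hu):
            cell_seed = int(
                np.random.SeedSequence([config.seed, iw, isig]).generate_state(1)[0] % (2**31)
            )
            rows.extend(_one_cell(case, config, w, sig, cell_seed, curve))
    return SweepResult(pd.DataFrame(rows), _provenance(config, case))


def max_acceptable_width(
    result: SweepResult, roi: str, threshold: float = 98.0, noise_sigma: float = 0.0
) -> Tuple[float, str]:
    """Largest tested width that passes with all smaller widths also passing.

    First-crossing rule: a non-monotone recovery of the pass rate beyond the
    first failure is ignored.  Returns ``(width_mm, flag)`` with flag one of
    ``"ok"``, ``"never_passes"``, ``"never_fails"``.
    """
    t = result.rates(roi, noise_sigma)
    if t.empty:
        raise ValueError(f"no sweep rows for ROI {roi!r}")
    widths = t["width_mm"].to_numpy()
    rates = t["pass_rate"].to_numpy()
    passing = rates >= threshold
    if not passing[0]:
        return 0.0, "never_passes"
    fails = np.nonzero(~passing)[0]
    if not fails.size:
        return float(widths[-1]), "never_fails"
    return float(widths[fails[0] - 1]), "ok"
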