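"""Robustness evaluation of a fixed plan over setup/density scenarios.

Implements the clinical ("Dutch protocol") robust evaluation: the plan is
*not* re-optimized; its dose is recomputed in every scenario, and coverage is
judged on the worst-case scenario and on the voxel-wise minimum dose
distribution via V95%[CTV] (required >= 98%).  A higher-sensitivity statistic
is included: the dose D at which exactly half of the perturbed scenarios
still satisfy V_D[CTV] > 98% — degradation of the CT biases this D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .dose_engine import Plan, compute_dose
from .gamma_eval import GammaCriteria
from .robust_plan import Scenario, ScenarioSet, apply_scenario
from .volumes import CalibrationCurve, DEFAULT_CALIBRATION, ROISet, Volume

__all__ = [
    "RobustnessReport",
    "scenario_doses",
    "voxelwise_min",
    "v_d",
    "d50_statistic",
    "oar_delta",
    "evaluate_robustness",
]


def scenario_doses(
    plan: Plan,
    ct: Volume,
    scenarios: ScenarioSet,
    curve: CalibrationCurve = DEFAULT_CALIBRATION,
    rois: Optional[ROISet] = None,
) -> List[Volume]:
    """One deterministic dose grid per scenario (nominal included).

    The patient shift is applied to the CT, the density perturbation scales
    the RSP map inside the engine, and the room-frame dose is rigidly mapped
    back into the patient frame so every scenario dose is evaluated on the
    nominal contours.
    """
    from scipy import ndimage as ndi

    external = rois.by_role("external") if rois is not None and "external" in rois else None
    doses = []
    for sc in scenarios:
        shifted = apply_scenario(ct, sc)
        d = compute_dose(plan, shifted, curve, None, density_scale=sc.density_scale)
        data = d.data
        if any(s != 0 for s in sc.shift):
            shift_vox = [-s / sp for s, sp in zip(sc.shift, ct.spacing)]
            data = ndi.shift(data, shift_vox, order=1, mode="constant", cval=0.0)
        if external is not None:
            data = np.where(external, data, 0.0)
        doses.append(ct.with_data(np.clip(data, 0.0, None), quantity="dose"))
    return doses


def voxelwise_min(doses: Sequence[Volume]) -> Volume:
    """Element-wise minimum over scenario dose grids."""
    if not doses:
        raise ValueError("need at least one dose grid")
    ref = doses[0]
    for d in doses[1:]:
        if not ref.same_geometry(d):
            raise ValueError("scenario dose grids are not congruent")
    data = np.min(np.stack([d.data for d in doses]), axis=0)
    return ref.with_data(data, quantity="dose")


def v_d(dose: Volume | np.ndarray, mask: np.ndarray, D: float) -> float:
    """V_D: percentage of mask voxels receiving at least dose D."""
    data = dose.data if isinstance(dose, Volume) else dose
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return 100.0 * float(np.mean(data[mask] >= D))


def d50_statistic(
    doses: Sequence[Volume],
    ctv: np.ndarray,
    prescription: float,
    coverage: float = 98.0,
    tol_fraction: float = 0.001,
) -> float:
    """Dose D at which 50% of the perturbed scenarios fulfil V_D[CTV] > coverage.

    The count of passing scenarios is non-increasing in D, so D is found by
    bisection (to ``tol_fraction`` of the prescription) on the largest D for
    which at least half of the scenarios still pass.
    """
    if len(doses) < 2:
        raise ValueError("d50 needs at least two scenarios")
    ctv_doses = np.stack([d.data[ctv] for d in doses])
    if not np.any(ctv_doses > 0):
        raise ValueError("all scenario doses are zero inside the CTV")
    need = int(np.ceil(len(doses) / 2.0))

    def n_pass(D: float) -> int:
        v = 100.0 * np.mean(ctv_doses >= D, axis=1)
        return int(np.sum(v > coverage))

    lo, hi = 0.0, float(ctv_doses.max()) + 1.0
    if n_pass(lo) < need:
        return 0.0
    tol = tol_fraction * prescription
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if n_pass(mid) >= need:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class RobustnessReport:
    """Scenario dose statistics of one plan on one CT."""

    scenario_v95: np.ndarray  # % per scenario, order of the scenario set
    worst_case_v95: float
    worst_scenario_index: int
    voxelwise_min_v95: float
    d50: float
    oar_metrics: Dict[str, Dict[str, np.ndarray]]  # oar -> metric -> per-scenario
    prescription: float


def _oar_metrics(doses: Sequence[Volume], mask: np.ndarray) -> Dict[str, np.ndarray]:
    vals_mean, vals_d2 = [], []
    for d in doses:
        x = d.data[mask]
        vals_mean.append(float(np.mean(x)))
        vals_d2.append(float(np.percentile(x, 98)))  # near-maximum dose D2%
    return {"Davg": np.array(vals_mean), "D2%": np.array(vals_d2)}


def evaluate_robustness(
    plan: Plan,
    ct: Volume,
    scenarios: ScenarioSet,
    rois: ROISet,
    curve: CalibrationCurve = DEFAULT_CALIBRATION,
) -> RobustnessReport:
    """Full robustness evaluation: scenario doses, V95 statistics, d50, OARs.

    The worst-case scenario is the one minimizing V95%[CTV]; the voxel-wise
    minimum distribution is evaluated separately.
    """
    ctv = rois.by_role("CTV")
    doses = scenario_doses(plan, ct, scenarios, curve, rois)
    thresh = 0.95 * plan.prescription
    v95s = np.array([v_d(d, ctv, thresh) for d in doses])
    worst = int(np.argmin(v95s))
    vmin = voxelwise_min(doses)
    oars = {
        name: _oar_metrics(doses, rois[name])
        for name, role in rois.roles.items()
        if role == "OAR"
    }
    return RobustnessReport(
        scenario_v95=v95s,
        worst_case_v95=float(v95s[worst]),
        worst_scenario_index=worst,
        voxelwise_min_v95=v_d(vmin, ctv, thresh),
        d50=d50_statistic(doses, ctv, plan.prescription),
        oar_metrics=oars,
        prescription=plan.prescription,
    )


def oar_delta(
    report_clinical: RobustnessReport,
    report_degraded: RobustnessReport,
    oar: str,
    metric: str = "Davg",
) -> float:
    """Max over scenarios of the degraded-vs-clinical metric deviation,
    as a percentage of the prescription (symmetric in its two inputs)."""
    for rep in (report_clinical, report_degraded):
        if oar not in rep.oar_metrics:
            raise KeyError(f"OAR {oar!r} missing from report")
    a = report_clinical.oar_metrics[oar][metric]
    b = report_degraded.oar_metrics[oar][metric]
    if a.shape != b.shape:
        raise ValueError("scenario sets of the two reports do not match")
    return 100.0 * float(np.max(np.abs(b - a))) / report_clinical.prescription
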