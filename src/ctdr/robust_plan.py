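"""Scenario generation and minimax robust optimization of spot weights.

Robustness scenarios follow the clinical recipe: six rigid patient shifts of
magnitude u along the cardinal axes, each combined with two mass-density
perturbations of +/- delta, giving 12 perturbed scenarios plus the nominal
(13 in total).  The optimizer minimizes the worst-scenario mean squared
deviation of the CTV dose from the prescription, by scenario-wise steepest
descent on the (linear) dose-influence matrices with a non-negativity
projection on the spot weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .dose_engine import Beam, Plan, beam_influence, compute_dose, design_beam
from .volumes import CalibrationCurve, DEFAULT_CALIBRATION, ROISet, Volume, hu_to_rsp

__all__ = [
    "Scenario",
    "ScenarioSet",
    "make_scenarios",
    "apply_scenario",
    "optimize_minimax",
    "OptimizationResult",
]


@dataclass(frozen=True)
class Scenario:
    """One robustness scenario: a cardinal rigid shift plus a density scale."""

    shift: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    density_scale: float = 1.0

    @property
    def is_nominal(self) -> bool:
        return self.shift == (0.0, 0.0, 0.0) and self.density_scale == 1.0

    def __post_init__(self) -> None:
        if sum(1 for s in self.shift if s != 0.0) > 1:
            raise ValueError("scenario shifts must be axis-aligned (one cardinal axis)")


@dataclass
class ScenarioSet:
    scenarios: List[Scenario]

    def __post_init__(self) -> None:
        if not any(s.is_nominal for s in self.scenarios):
            raise ValueError("scenario set must contain the nominal scenario")

    def __iter__(self):
        return iter(self.scenarios)

    def __len__(self) -> int:
        return len(self.scenarios)

    @property
    def nominal_index(self) -> int:
        return next(i for i, s in enumerate(self.scenarios) if s.is_nominal)

    @property
    def perturbed(self) -> List[Scenario]:
        return [s for s in self.scenarios if not s.is_nominal]


def make_scenarios(u_mm: float, delta: float) -> ScenarioSet:
    """Nominal + 6 cardinal shifts x 2 density scales (13 scenarios).

    ``u_mm = 0`` and ``delta = 0`` collapse to the nominal scenario only; with
    only one of them zero the degenerate duplicates are removed.
    """
    if u_mm < 0 or delta < 0:
        raise ValueError("uncertainties must be >= 0")
    scen = [Scenario()]
    shifts: List[Tuple[float, float, float]] = []
    if u_mm > 0:
        for ax in range(3):
            for sgn in (+1.0, -1.0):
                v = [0.0, 0.0, 0.0]
                v[ax] = sgn * u_mm
                shifts.append(tuple(v))  # type: ignore[arg-type]
    else:
        shifts.append((0.0, 0.0, 0.0))
    scales = [1.0 - delta, 1.0 + delta] if delta > 0 else [1.0]
    for sh in shifts:
        for sc in scales:
            s = Scenario(sh, sc)
            if not s.is_nominal:
                scen.append(s)
    return ScenarioSet(scen)


def apply_scenario(ct: Volume, scenario: Scenario) -> Volume:
    """Rigidly shift the patient model (trilinear resampling, air fill).

    A shift of the *patient* by +s along an axis moves tissue to larger
    coordinates.  Integer-voxel shifts reduce to an exact roll.  The density
    scale is not applied here — it multiplies the RSP map downstream (see
    :func:`scenario_rsp`).
    """
    shift_vox = [s / sp for s, sp in zip(scenario.shift, ct.spacing)]
    if all(s == 0 for s in shift_vox):
        return ct.with_data(ct.data.copy())
    data = ndimage.shift(ct.data, shift_vox, order=1, mode="constant", cval=-1000.0)
    return ct.with_data(data)


def scenario_rsp(
    ct: Volume, scenario: Scenario, curve: CalibrationCurve = DEFAULT_CALIBRATION
) -> np.ndarray:
    """RSP array of a scenario: shifted CT -> calibration -> density scale."""
    shifted = apply_scenario(ct, scenario)
    rsp = np.clip(hu_to_rsp(shifted, curve).data, 0.0, None)
    return rsp * scenario.density_scale


@dataclass
class OptimizationResult:
    plan: Plan
    converged: bool
    objective_history: np.ndarray
    scenario_v95: np.ndarray  # % per scenario, on the optimization point sample
    worst_v95: float


def _v95(dose: np.ndarray, prescription: float) -> float:
    return 100.0 * float(np.mean(dose >= 0.95 * prescription))


def optimize_minimax(
    ct: Volume,
    roi: ROISet,
    scenarios: ScenarioSet,
    prescription: float = 54.0,
    curve: CalibrationCurve = DEFAULT_CALIBRATION,
    beam_directions: Sequence[str] = ("+x", "+y"),
    sigma_air: float = 5.0,
    range_shifter_wet: float = 7.4,
    setup_margin_mm: float = 3.0,
    density_margin: float = 0.035,
    max_iter: int = 400,
    n_sample_points: int = 1200,
    tol: float = 1e-5,
    underdose_weight: float = 6.0,
    seed: int = 0,
) -> OptimizationResult:
    """Minimax robust optimization of spot weights for CTV coverage.

    Each iteration evaluates the quadratic CTV objective in every scenario,
    takes a projected-gradient step on the worst one (step size from a power
    -iteration Lipschitz estimate), and clips weights at zero.  Underdosed
    voxels are weighted ``underdose_weight`` times more than overdosed ones —
    coverage (V95) is the binding clinical constraint, uniformity the soft
    one.  The CTV is subsampled to ``n_sample_points`` voxels for the
    influence matrices; the final weights are rescaled so the nominal-scenario
    median CTV dose sits 1% above the prescription.
    """
    ctv = roi.by_role("CTV")
    if not ctv.any():
        raise ValueError("CTV is empty")

    beams = [
        design_beam(ct, ctv, d, curve, sigma_air, range_shifter_wet,
                    setup_margin_mm, density_margin)
        for d in beam_directions
    ]
    plan = Plan(beams, prescription, setup_margin_mm, density_margin)

    rng = np.random.default_rng(seed)
    idx = np.argwhere(ctv)
    if len(idx) > n_sample_points:
        idx = idx[rng.choice(len(idx), n_sample_points, replace=False)]

    # influence matrices per scenario (dose is linear in the weights); the
    # patient-frame CTV voxels are mapped into each shifted scenario's room
    # frame (tissue at x sits at x + shift after the patient shift)
    A_list = []
    for sc in scenarios:
        rsp = scenario_rsp(ct, sc, curve)
        shift_vox = np.array([s / sp for s, sp in zip(sc.shift, ct.spacing)])
        pts = idx.astype(np.float64) + shift_vox[None, :]
        A = np.hstack([beam_influence(b, rsp, ct, pts) for b in beams])
        A_list.append(A)

    w = plan.get_weights()
    # scale the initial guess to the prescription level
    d_nom = A_list[scenarios.nominal_index] @ w
    scale = prescription / max(float(np.median(d_nom)), 1e-12)
    w = w * scale

    # Lipschitz estimate of the worst-case gradient via power iteration
    A0 = A_list[scenarios.nominal_index]
    v = rng.standard_normal(A0.shape[1]).astype(np.float32)
    for _ in range(15):
        v = A0.T @ (A0 @ v)
        v /= np.linalg.norm(v)
    lam = float(v @ (A0.T @ (A0 @ v)))
    lr = A0.shape[0] / (2.0 * lam)

    # hot loop stays in float32 end to end (mixed dtypes defeat BLAS)
    w = w.astype(np.float32)
    target = np.full(A0.shape[0], prescription, dtype=np.float32)
    uw = np.float32(underdose_weight)

    def residual_weights(r: np.ndarray) -> np.ndarray:
        return np.where(r < 0, uw, np.float32(1.0))

    def objectives(wv: np.ndarray):
        resids = [A @ wv - target for A in A_list]
        objs = np.array([float(np.mean(residual_weights(r) * r * r)) for r in resids])
        return objs, resids

    lr = lr / underdose_weight
    history = []
    n_mean_phase = max_iter // 3
    for it in range(max_iter):
        objs, resids = objectives(w)
        if it < n_mean_phase:
            # smooth warm-up: descend on the scenario-average objective
            grad = np.zeros_like(w)
            for A, r in zip(A_list, resids):
                grad += (2.0 / len(target)) * (A.T @ (residual_weights(r) * r))
            grad /= len(A_list)
        else:
            worst = int(np.argmax(objs))
            r = resids[worst]
            grad = (2.0 / len(target)) * (A_list[worst].T @ (residual_weights(r) * r))
        w = np.clip(w - lr * grad, 0.0, None)
        history.append(float(objs.max()))
    converged = bool(
        len(history) > 20
        and abs(history[-1] - min(history[-20:])) < tol * prescription**2 * 100
    )

    # final rescale: nominal median 1% above prescription keeps the low tail
    # of every scenario above the V95 level
    d_nom = A_list[scenarios.nominal_index] @ w
    w = w * 1.01 * prescription / max(float(np.median(d_nom)), 1e-12)
    plan.set_weights(w)

    v95s = np.array([_v95(A @ w, prescription) for A in A_list])
    return OptimizationResult(
        plan=plan,
        converged=converged,
        objective_history=np.asarray(history),
        scenario_v95=v95s,
        worst_v95=float(v95s.min()),
    )
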