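"""Deterministic analytic proton pencil-beam dose engine.

The engine is a physical-dose surrogate: an analytic Bragg curve (power-law
plateau plus a Gaussian peak with range straggling) is placed along water
equivalent depth (WET), and a depth-broadened lateral Gaussian models the spot
profile.  It is deliberately simple — no nuclear halo, no secondaries, no RBE
— because the study's questions concern the *shape stability* of dose
distributions under CT degradation, which is engine-agnostic, not absolute
dosimetry.  Being deterministic, it has no Monte-Carlo noise floor, so gamma
comparisons are not contaminated by statistical uncertainty.

Beams are restricted to the six cardinal directions, which makes the WET of
every voxel an exact cumulative sum of RSP along a grid axis and keeps the
whole-grid dose computation a few tensor contractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .volumes import CalibrationCurve, DEFAULT_CALIBRATION, ROISet, Volume, hu_to_rsp

__all__ = [
    "Beam",
    "Plan",
    "plan_to_json",
    "plan_from_json",
    "trace_wet",
    "depth_dose",
    "compute_dose",
    "build_sobp",
    "design_beam",
    "beam_wet_array",
]

_CARDINALS = {
    "+x": (0, +1), "-x": (0, -1),
    "+y": (1, +1), "-y": (1, -1),
    "+z": (2, +1), "-z": (2, -1),
}


def range_sigma(R_mm: float | np.ndarray) -> np.ndarray:
    """Bragg-peak width: 1% range straggling quadratically added to a 2 mm
    intrinsic peak width (keeps peaks resolvable on clinical dose grids)."""
    return np.sqrt((0.01 * np.asarray(R_mm, dtype=float)) ** 2 + 2.0**2)


@dataclass
class Beam:
    """One cardinal-direction scanned proton field.

    ``spot_u`` / ``spot_v`` are lateral spot-centre world coordinates (mm)
    along the two non-beam axes in package axis order; ``weights`` has shape
    ``(n_layers, n_u, n_v)``.  ``layer_ranges`` are nominal ranges R (mm
    water) *before* the range shifter; the shifter subtracts
    ``10 * range_shifter_wet`` mm of range.
    """

    direction: str
    layer_ranges: np.ndarray
    spot_u: np.ndarray
    spot_v: np.ndarray
    weights: np.ndarray
    sigma_air: float = 5.0
    range_shifter_wet: float = 7.4  # cm water

    def __post_init__(self) -> None:
        if self.direction not in _CARDINALS:
            raise ValueError(f"beam direction must be one of {sorted(_CARDINALS)}")
        self.layer_ranges = np.atleast_1d(np.asarray(self.layer_ranges, dtype=float))
        self.spot_u = np.atleast_1d(np.asarray(self.spot_u, dtype=float))
        self.spot_v = np.atleast_1d(np.asarray(self.spot_v, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        expected = (self.layer_ranges.size, self.spot_u.size, self.spot_v.size)
        if self.weights.shape != expected:
            raise ValueError(f"weights shape {self.weights.shape} != {expected}")
        if np.any(self.weights < 0):
            raise ValueError("spot weights must be non-negative")
        if np.any(self.effective_ranges <= 0):
            raise ValueError("nominal range must exceed the range-shifter WET")

    @property
    def axis(self) -> int:
        return _CARDINALS[self.direction][0]

    @property
    def sign(self) -> int:
        return _CARDINALS[self.direction][1]

    @property
    def effective_ranges(self) -> np.ndarray:
        """Residual range in the patient after the range shifter (mm water)."""
        return self.layer_ranges - 10.0 * self.range_shifter_wet

    @property
    def n_weights(self) -> int:
        return int(self.weights.size)


@dataclass
class Plan:
    """Proton plan: beams plus prescription and robustness parameters."""

    beams: List[Beam]
    prescription: float = 54.0  # Gy
    setup_uncertainty: float = 3.0  # mm, isotropic
    density_uncertainty: float = 0.035  # fraction

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("plan needs at least one beam")
        if self.setup_uncertainty < 0:
            raise ValueError("setup uncertainty must be >= 0")
        if not (0.0 <= self.density_uncertainty < 0.2):
            raise ValueError("density uncertainty must be in [0, 0.2)")

    def get_weights(self) -> np.ndarray:
        return np.concatenate([b.weights.ravel() for b in self.beams])

    def set_weights(self, w: np.ndarray) -> None:
        w = np.asarray(w, dtype=float)
        if np.any(w < 0):
            raise ValueError("spot weights must be non-negative")
        i = 0
        for b in self.beams:
            b.weights = w[i : i + b.n_weights].reshape(b.weights.shape)
            i += b.n_weights
        if i != w.size:
            raise ValueError(f"weight vector length {w.size} != plan total {i}")


def plan_to_json(plan: Plan, path) -> None:
    """Serialize a plan (beams, weights, prescription, uncertainties) to JSON."""
    import json
    from pathlib import Path

    payload = {
        "prescription": plan.prescription,
        "setup_uncertainty": plan.setup_uncertainty,
        "density_uncertainty": plan.density_uncertainty,
        "beams": [
            {
                "direction": b.direction,
                "layer_ranges": b.layer_ranges.tolist(),
                "spot_u": b.spot_u.tolist(),
                "spot_v": b.spot_v.tolist(),
                "weights": b.weights.tolist(),
                "sigma_air": b.sigma_air,
                "range_shifter_wet": b.range_shifter_wet,
            }
            for b in plan.beams
        ],
    }
    Path(path).write_text(json.dumps(payload))


def plan_from_json(path) -> Plan:
    import json
    from pathlib import Path

    p = json.loads(Path(path).read_text())
    beams = [
        Beam(
            b["direction"],
            np.asarray(b["layer_ranges"]),
            np.asarray(b["spot_u"]),
            np.asarray(b["spot_v"]),
            np.asarray(b["weights"]),
            sigma_air=b["sigma_air"],
            range_shifter_wet=b["range_shifter_wet"],
        )
        for b in p["beams"]
    ]
    return Plan(beams, p["prescription"], p["setup_uncertainty"], p["density_uncertainty"])


def trace_wet(
    rsp: Volume,
    entry_mm: Sequence[float],
    direction: Sequence[float],
    depth_samples: np.ndarray,
) -> np.ndarray:
    """Cumulative water-equivalent thickness along an arbitrary ray.

    ``WET(t) = integral of RSP over [0, t]`` evaluated by fine sampling
    (step = min spacing / 4) with trilinear interpolation; monotone
    non-decreasing, and exactly ``t`` in uniform water.
    """
    from scipy.ndimage import map_coordinates

    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if not np.isclose(n, 1.0, atol=1e-6):
        raise ValueError("direction must be a unit vector")
    entry = np.asarray(entry_mm, dtype=float)
    idx_entry = (entry - np.asarray(rsp.origin)) / np.asarray(rsp.spacing)
    if np.any(idx_entry < -0.5) or np.any(idx_entry > np.asarray(rsp.shape) - 0.5):
        raise ValueError(f"entry point {entry} lies outside the grid")

    depth_samples = np.atleast_1d(np.asarray(depth_samples, dtype=float))
    t_max = float(depth_samples.max())
    step = min(rsp.spacing) / 4.0
    t = np.arange(0.0, t_max + step, step)
    pts = entry[None, :] + t[:, None] * d[None, :]
    coords = (pts - np.asarray(rsp.origin)) / np.asarray(rsp.spacing)
    vals = map_coordinates(rsp.data, coords.T, order=1, mode="constant", cval=0.0)
    from scipy.integrate import cumulative_trapezoid

    cum = cumulative_trapezoid(vals, t, initial=0.0)
    return np.interp(depth_samples, t, cum)


_DD_PLATEAU = 0.3
_DD_NORM = _DD_PLATEAU * 0.1 ** (-0.45) + 1.0


def depth_dose(R: float, wet: np.ndarray) -> np.ndarray:
    """Analytic Bragg curve, peak normalized to 1 at ``wet = R``.

    A slowly rising power-law plateau models the inverse-velocity stopping
    power rise; a Gaussian of width :func:`range_sigma` models the straggled
    peak.  The curve is exactly zero beyond ``R + 3 * range_sigma(R)``; the
    peak-to-entrance ratio is about 6.
    """
    if R <= 0:
        raise ValueError("nominal range must be > 0")
    wet = np.asarray(wet, dtype=float)
    s = float(range_sigma(R))
    wclip = np.minimum(wet, R)
    plateau = _DD_PLATEAU * (1.0 - 0.9 * wclip / R) ** (-0.45)
    over = np.maximum(wet - R, 0.0)
    tail = np.exp(-(over**2) / (2.0 * s**2))
    peak = np.exp(-((wet - R) ** 2) / (2.0 * s**2))
    d = (plateau * tail + peak) / _DD_NORM
    d[wet > R + 3.0 * s] = 0.0
    return d


def beam_wet_array(rsp_data: np.ndarray, spacing: Tuple[float, float, float], beam: Beam) -> np.ndarray:
    """WET (mm water) at every voxel centre for a cardinal beam direction.

    Computed as the cumulative sum of RSP * spacing along the beam axis, with
    a half-voxel correction so the value refers to the voxel centre.
    """
    a, sign = beam.axis, beam.sign
    arr = np.moveaxis(rsp_data, a, 0)
    if sign < 0:
        arr = arr[::-1]
    ds = spacing[a]
    wet = np.cumsum(arr, axis=0) * ds - arr * (ds / 2.0)
    if sign < 0:
        wet = wet[::-1]
    return np.moveaxis(wet, 0, a)


def _lateral_axes(axis: int) -> Tuple[int, int]:
    return tuple(i for i in range(3) if i != axis)  # type: ignore[return-value]


def _sigma_profile(beam: Beam, wet_axis: np.ndarray) -> np.ndarray:
    """Lateral spot sigma per depth slice: grows linearly with central-axis WET
    from sigma_air at the surface to 2*sigma_air at the deepest layer."""
    r_max = float(beam.effective_ranges.max())
    frac = np.clip(wet_axis / max(r_max, 1e-9), 0.0, 1.0)
    return beam.sigma_air * (1.0 + frac)


def _gauss_design(grid_mm: np.ndarray, spots_mm: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """(n_slices, n_grid, n_spots) lateral 1D Gaussian factors, area-normalized."""
    d = grid_mm[None, :, None] - spots_mm[None, None, :]
    s = sigmas[:, None, None]
    return np.exp(-(d**2) / (2.0 * s**2)) / (np.sqrt(2.0 * np.pi) * s)


def compute_dose(
    plan: Plan,
    ct: Volume,
    curve: CalibrationCurve = DEFAULT_CALIBRATION,
    roi: ROISet | None = None,
    density_scale: float = 1.0,
) -> Volume:
    """Deterministic pencil-beam dose of a plan on a HU volume.

    ``dose(v) = sum over beams, layers, spots of
    w * depth_dose(R_eff, WET(v)) * lateral Gaussian``; the lateral sum over a
    beam's regular spot grid is evaluated as separable tensor contractions.
    The dose is linear in the spot weights and zeroed outside the external
    contour when an ROI set is supplied.
    """
    rsp = hu_to_rsp(ct, curve)
    rsp_data = np.clip(rsp.data, 0.0, None) * density_scale
    dose = np.zeros(ct.shape, dtype=np.float64)
    external = roi.by_role("external") if roi is not None and "external" in roi else None

    for beam in plan.beams:
        dose += _beam_dose(beam, rsp_data, ct)

    if external is not None:
        if not np.any(dose[external] > 0):
            import warnings

            warnings.warn(f"plan deposits no dose inside the external contour")
        dose = np.where(external, dose, 0.0)
    return ct.with_data(dose, quantity="dose")


def _beam_dose(beam: Beam, rsp_data: np.ndarray, ct: Volume) -> np.ndarray:
    a = beam.axis
    u_ax, v_ax = _lateral_axes(a)
    wet = beam_wet_array(rsp_data, ct.spacing, beam)
    wet_b = np.moveaxis(wet, a, 0)  # (n_depth, n_u, n_v)

    # central-axis WET per slice, at the lateral position of the spot pattern centre
    iu = int(np.clip(round((float(np.mean(beam.spot_u)) - ct.origin[u_ax]) / ct.spacing[u_ax]),
                     0, ct.shape[u_ax] - 1))
    iv = int(np.clip(round((float(np.mean(beam.spot_v)) - ct.origin[v_ax]) / ct.spacing[v_ax]),
                     0, ct.shape[v_ax] - 1))
    wet_axis = wet_b[:, iu, iv]
    sigmas = _sigma_profile(beam, wet_axis)

    grid_u = ct.origin[u_ax] + np.arange(ct.shape[u_ax]) * ct.spacing[u_ax]
    grid_v = ct.origin[v_ax] + np.arange(ct.shape[v_ax]) * ct.spacing[v_ax]
    Gu = _gauss_design(grid_u, beam.spot_u, sigmas)  # (nz, nu_grid, n_us)
    Gv = _gauss_design(grid_v, beam.spot_v, sigmas)

    dose_b = np.zeros_like(wet_b)
    for l, R in enumerate(beam.effective_ranges):
        W = beam.weights[l]
        if not W.any():
            continue
        dd = depth_dose(R, wet_b)
        tmp = np.einsum("zpa,ab->zpb", Gu, W)
        fluence = np.einsum("zpb,zqb->zpq", tmp, Gv)
        dose_b += dd * fluence
    return np.moveaxis(dose_b, 0, a)


def beam_influence(
    beam: Beam,
    rsp_data: np.ndarray,
    ct: Volume,
    points_idx: np.ndarray,
) -> np.ndarray:
    """Dose-influence submatrix of one beam at selected points.

    ``points_idx`` may be fractional voxel-index coordinates (e.g. nominal
    CTV voxels mapped into a shifted scenario's room frame); WET is then
    trilinearly interpolated.  Returns ``(n_points, n_layers * n_u * n_v)``
    (float32): the dose at each point per unit weight of each spot.
    """
    from scipy.ndimage import map_coordinates

    a = beam.axis
    u_ax, v_ax = _lateral_axes(a)
    points_idx = np.asarray(points_idx, dtype=np.float64)
    wet = beam_wet_array(rsp_data, ct.spacing, beam)
    wet_pts = map_coordinates(wet, points_idx.T, order=1, mode="nearest")

    iu = int(np.clip(round((float(np.mean(beam.spot_u)) - ct.origin[u_ax]) / ct.spacing[u_ax]),
                     0, ct.shape[u_ax] - 1))
    iv = int(np.clip(round((float(np.mean(beam.spot_v)) - ct.origin[v_ax]) / ct.spacing[v_ax]),
                     0, ct.shape[v_ax] - 1))
    sel = [points_idx[:, 0], points_idx[:, 1], points_idx[:, 2]]
    sel[u_ax] = np.full(len(points_idx), float(iu))
    sel[v_ax] = np.full(len(points_idx), float(iv))
    wet_axis_pts = map_coordinates(wet, np.stack(sel), order=1, mode="nearest")
    sig_pts = _sigma_profile(beam, wet_axis_pts)

    pos_u = ct.origin[u_ax] + points_idx[:, u_ax] * ct.spacing[u_ax]
    pos_v = ct.origin[v_ax] + points_idx[:, v_ax] * ct.spacing[v_ax]
    gu = np.exp(-((pos_u[:, None] - beam.spot_u[None, :]) ** 2) / (2 * sig_pts[:, None] ** 2))
    gv = np.exp(-((pos_v[:, None] - beam.spot_v[None, :]) ** 2) / (2 * sig_pts[:, None] ** 2))
    norm = 1.0 / (2.0 * np.pi * sig_pts**2)
    lateral = (gu[:, :, None] * gv[:, None, :] * norm[:, None, None]).astype(np.float32)

    n_l = beam.layer_ranges.size
    A = np.empty((len(points_idx), n_l, beam.spot_u.size, beam.spot_v.size), dtype=np.float32)
    for l, R in enumerate(beam.effective_ranges):
        A[:, l] = depth_dose(R, wet_pts)[:, None, None].astype(np.float32) * lateral
    return A.reshape(len(points_idx), -1)


def build_sobp(
    range_span: Tuple[float, float],
    n_layers: int,
    plateau_samples: int = 80,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Layer ranges and non-negative weights giving a flat plateau in water.

    Solves a non-negative least-squares fit of the layer depth-dose matrix to
    a unit plateau over ``range_span``.  The deepest layer is placed one
    straggling width beyond the distal plateau edge so the plateau does not
    roll off at the edge itself.  Returns ``(ranges_mm, weights,
    achieved_flatness)`` where flatness is plateau max/min; a value above 1.04
    means the requested flatness was not achievable with these layers.
    """
    lo, hi = float(range_span[0]), float(range_span[1])
    if hi < lo or lo <= 0:
        raise ValueError("range span must be positive with hi >= lo")
    if n_layers < 1:
        raise ValueError("need at least one layer")
    if n_layers == 1 or hi == lo:
        return np.array([hi]), np.ones(1), 1.0

    ranges = np.linspace(lo, hi + float(range_sigma(hi)), n_layers)
    depths = np.linspace(lo, hi, plateau_samples)
    M = np.stack([depth_dose(R, depths) for R in ranges], axis=1)
    from scipy.optimize import nnls

    w, _ = nnls(M, np.ones(plateau_samples))
    plateau = M @ w
    flat = float(plateau.max() / max(plateau.min(), 1e-12))
    return ranges, w, flat


def design_beam(
    ct: Volume,
    ctv_mask: np.ndarray,
    direction: str,
    curve: CalibrationCurve = DEFAULT_CALIBRATION,
    sigma_air: float = 5.0,
    range_shifter_wet: float = 7.4,
    setup_margin_mm: float = 3.0,
    density_margin: float = 0.035,
    layer_spacing_mm: float = 4.0,
    spot_spacing_mm: float | None = None,
) -> Beam:
    """Beam geometry covering a CTV from one cardinal direction.

    Layers span the CTV's WET extent plus setup/range margins; spots cover the
    CTV's lateral bounding box plus setup margin and one spot sigma, at a
    spot spacing equal to sigma_air by default.  Weights are initialized from
    a water SOBP and uniform laterally (the minimax optimizer refines them).
    """
    if not ctv_mask.any():
        raise ValueError("CTV mask is empty")
    rsp_data = np.clip(hu_to_rsp(ct, curve).data, 0.0, None)
    probe = Beam(direction, [1000.0], [0.0], [0.0], np.zeros((1, 1, 1)),
                 sigma_air=sigma_air, range_shifter_wet=0.0)
    wet = beam_wet_array(rsp_data, ct.spacing, probe)
    wet_ctv = wet[ctv_mask]
    depth_margin = setup_margin_mm + density_margin * float(wet_ctv.max()) + 3.0
    lo = max(float(wet_ctv.min()) - depth_margin, 2.0)
    hi = float(wet_ctv.max()) + depth_margin
    n_layers = max(int(np.ceil((hi - lo) / layer_spacing_mm)) + 1, 2)
    ranges_eff, w_sobp, _ = build_sobp((lo, hi), n_layers)
    ranges = ranges_eff + 10.0 * range_shifter_wet

    a = probe.axis
    u_ax, v_ax = _lateral_axes(a)
    ds = spot_spacing_mm or sigma_air
    idx = np.argwhere(ctv_mask)
    margins = setup_margin_mm + sigma_air

    def spot_coords(ax: int) -> np.ndarray:
        lo_mm = ct.origin[ax] + idx[:, ax].min() * ct.spacing[ax] - margins
        hi_mm = ct.origin[ax] + idx[:, ax].max() * ct.spacing[ax] + margins
        n = max(int(np.ceil((hi_mm - lo_mm) / ds)) + 1, 2)
        return np.linspace(lo_mm, hi_mm, n)

    spot_u, spot_v = spot_coords(u_ax), spot_coords(v_ax)
    weights = np.broadcast_to(
        w_sobp[:, None, None], (n_layers, spot_u.size, spot_v.size)
    ).copy()
    return Beam(direction, ranges, spot_u, spot_v, weights,
                sigma_air=sigma_air, range_shifter_wet=range_shifter_wet)
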