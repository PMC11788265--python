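"""Synthetic digital phantoms: anatomy-like test volumes and the wire phantom.

Every downstream stage of the study (degradation, dose computation, robust
planning, gamma evaluation, resolution metrology) runs on volumes produced
here, so no external image data is required anywhere in the package.

Anatomical phantoms are built from ordered geometric primitives (slabs,
cylinders, spheres) carrying HU values; later primitives overwrite earlier
ones.  Four canonical specs mirror typical treatment localizations: a
brain-like homogeneous target inside a skull, a thorax-like chest-wall target
at a soft-tissue/lung interface, and abdomen-/pelvis-like variants.  The wire
phantom emulates a scanner QA object: a 0.18 mm metal wire in a water
cylinder, blurred by a known Gaussian PSF, used to measure the line-spread
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volumes import ROISet, Volume, external_from_hu

__all__ = [
    "Primitive",
    "PhantomSpec",
    "WirePhantomSpec",
    "generate_phantom",
    "generate_wire_phantom",
    "spec_to_yaml",
    "spec_from_yaml",
    "brain_spec",
    "thorax_spec",
    "abdomen_spec",
    "pelvis_spec",
    "canonical_specs",
]

HU_MIN, HU_MAX = -1024.0, 3000.0


@dataclass
class Primitive:
    """One geometric tissue region: kind in {"slab", "sphere", "cylinder"}.

    * slab: ``axis`` plus world-coordinate bounds ``(lo, hi)`` in mm;
    * sphere: ``center`` (mm) and ``radius`` (mm);
    * cylinder: ``center`` (mm), ``radius`` (mm) and ``axis`` along which it
      is infinite (optionally bounded by ``(lo, hi)``).
    """

    kind: str
    hu: float
    center: Tuple[float, float, float] | None = None
    radius: float | None = None
    axis: int = 2
    bounds: Tuple[float, float] | None = None
    name: str | None = None

    def rasterize(self, coords: Sequence[np.ndarray]) -> np.ndarray:
        mask = self._rasterize(coords)
        shape = np.broadcast_shapes(*[c.shape for c in coords])
        return np.broadcast_to(mask, shape).copy() if mask.shape != shape else mask

    def _rasterize(self, coords: Sequence[np.ndarray]) -> np.ndarray:
        x, y, z = coords
        if self.kind == "slab":
            c = (x, y, z)[self.axis]
            lo, hi = self.bounds  # type: ignore[misc]
            return (c >= lo) & (c <= hi)
        if self.kind == "sphere":
            cx, cy, cz = self.center  # type: ignore[misc]
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius**2
        if self.kind == "cylinder":
            cx, cy, cz = self.center  # type: ignore[misc]
            lat = [(x, cx), (y, cy), (z, cz)]
            lat.pop(self.axis)
            d2 = sum((c - c0) ** 2 for c, c0 in lat)
            inside = d2 <= self.radius**2
            if self.bounds is not None:
                c = (x, y, z)[self.axis]
                inside = inside & (c >= self.bounds[0]) & (c <= self.bounds[1])
            return inside
        raise ValueError(f"unknown primitive kind {self.kind!r}")


@dataclass
class PhantomSpec:
    """Recipe for an anatomy-like phantom with a target and ROIs."""

    name: str
    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    tissue_layout: List[Primitive] = field(default_factory=list)
    ctv: Optional[Primitive] = None
    target_class: str = "homogeneous"  # or "interface"
    ptv_margin_mm: float = 4.0
    oars: List[Primitive] = field(default_factory=list)
    baseline_noise_sigma: float = 0.0
    background_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0 on all axes")
        for p in self.tissue_layout:
            if not (HU_MIN <= p.hu <= HU_MAX):
                raise ValueError(f"primitive HU {p.hu} outside [{HU_MIN}, {HU_MAX}]")
        if self.target_class not in ("homogeneous", "interface"):
            raise ValueError(f"unknown target class {self.target_class!r}")


@dataclass
class WirePhantomSpec:
    """Wire-in-water resolution phantom blurred by a known scanner PSF."""

    wire_diameter: float = 0.18  # mm
    cylinder_diameter: float = 200.0  # mm; "20 diameter" read as 20 cm
    wire_hu: float = 3000.0  # copper saturates the CT scale
    water_hu: float = 0.0
    psf_fwhm: float = 1.45  # mm, Gaussian blur emulating the scanner PSF
    grid_shape: Tuple[int, int, int] = (161, 161, 16)
    spacing: Tuple[float, float, float] = (0.25, 0.25, 1.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.wire_diameter <= 0:
            raise ValueError("wire_diameter must be > 0")


def _world_coords(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def generate_phantom(spec: PhantomSpec) -> Tuple[Volume, ROISet]:
    """Rasterize a phantom spec into a noisy HU volume plus its ROI set.

    Deterministic given ``spec.seed``.  The returned ROI set always contains
    ``external`` and ``CTV``; a ``PTV`` (CTV dilated by ``ptv_margin_mm``) and
    any OAR primitives are added when defined.
    """
    coords = _world_coords(spec.grid_shape, spec.spacing)
    hu = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    for prim in spec.tissue_layout:
        hu[prim.rasterize(coords)] = prim.hu

    noiseless = Volume(hu, spec.spacing, quantity="HU")
    external = external_from_hu(noiseless)

    masks: Dict[str, np.ndarray] = {"external": external}
    roles: Dict[str, str] = {"external": "external"}
    if spec.ctv is not None:
        ctv = spec.ctv.rasterize(coords)
        if not ctv.any():
            raise ValueError(f"CTV primitive {spec.ctv.kind!r} lies outside the grid")
        if np.any(ctv & ~external):
            raise ValueError(
                f"CTV primitive {spec.ctv.kind!r} extends outside the external contour"
            )
        if _touches_border(ctv):
            raise ValueError(f"CTV primitive {spec.ctv.kind!r} touches the grid border")
        masks["CTV"], roles["CTV"] = ctv, "CTV"
        from .volumes import _ball_mm  # structuring element shared with contours

        ptv = ndimage.binary_dilation(ctv, structure=_ball_mm(spec.ptv_margin_mm, spec.spacing))
        ptv &= external
        masks["PTV"], roles["PTV"] = ptv, "PTV"
        if spec.target_class == "interface":
            _check_interface(hu, ctv)
    for oar in spec.oars:
        oname = oar.name or f"oar_{len(masks)}"
        m = oar.rasterize(coords)
        if not m.any():
            raise ValueError(f"OAR primitive {oname!r} lies outside the grid")
        masks[oname], roles[oname] = m, "OAR"

    rng = np.random.default_rng(spec.seed)
    noisy = hu + rng.normal(0.0, spec.baseline_noise_sigma, size=hu.shape) \
        if spec.baseline_noise_sigma > 0 else hu.copy()
    return Volume(noisy, spec.spacing, quantity="HU"), ROISet(masks, roles)


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def _check_interface(hu: np.ndarray, ctv: np.ndarray) -> None:
    """Interface-class targets must sit next to a >= 500 HU density step."""
    shell = ndimage.binary_dilation(ctv, iterations=2) & ~ctv
    span = hu[shell | ctv].max() - hu[shell | ctv].min()
    if span < 500:
        raise ValueError(
            f"interface-class CTV has only a {span:.0f} HU step in its surroundings"
        )


def generate_wire_phantom(spec: WirePhantomSpec) -> Volume:
    """Wire phantom: sub-voxel area-weighted wire, PSF blur, then noise.

    The wire runs along z through the transversal grid centre.  Its HU
    contribution per voxel is weighted by the geometric overlap of the wire
    disc with the voxel footprint (supersampled 8x in-plane), so wires thinner
    than a voxel are represented correctly in integral terms.
    """
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    if nz < 1:
        raise ValueError("wire phantom grid must have at least one slice")
    cx, cy = (nx - 1) / 2.0 * sx, (ny - 1) / 2.0 * sy
    r_wire = spec.wire_diameter / 2.0
    r_cyl = spec.cylinder_diameter / 2.0

    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    slice_hu = np.where(d2 <= r_cyl**2, spec.water_hu, -1000.0)

    # sub-voxel wire: fractional area of the wire disc inside each voxel
    sub = 32
    ox = (np.arange(sub) + 0.5) / sub - 0.5
    frac = np.zeros((nx, ny))
    near = d2 <= (r_wire + max(sx, sy)) ** 2
    for i, j in zip(*np.nonzero(near)):
        px = x[i] + ox * sx
        py = y[j] + ox * sy
        pxx, pyy = np.meshgrid(px, py, indexing="ij")
        frac[i, j] = np.mean((pxx - cx) ** 2 + (pyy - cy) ** 2 <= r_wire**2)
    slice_hu = slice_hu + frac * (spec.wire_hu - spec.water_hu)

    if spec.psf_fwhm > 0:
        sigma = spec.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        slice_hu = ndimage.gaussian_filter(
            slice_hu, sigma=(sigma / sx, sigma / sy), mode="constant", cval=-1000.0
        )

    vol = np.repeat(slice_hu[:, :, None], nz, axis=2)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    return Volume(vol, spec.spacing, quantity="HU")


# ---------------------------------------------------------------------------
# Canonical phantom specs
# ---------------------------------------------------------------------------
# Baseline noise defaults follow typical planning-CT noise levels per
# localization (brain 6.0 HU, thorax 2.3 HU, pelvis 9.6 HU, abdomen 11.5 HU).


def brain_spec(seed: int = 42, grid_shape=(96, 96, 96), spacing=(2.0, 2.0, 2.0),
               baseline_noise_sigma: float = 6.0) -> PhantomSpec:
    """Brain-like: homogeneous soft-tissue sphere inside a bony skull shell."""
    ext = [g * (n - 1) / 2.0 for g, n in zip(spacing, grid_shape)]
    c = tuple(ext)
    r_head = 0.72 * min(ext)
    layout = [
        Primitive("sphere", 1100.0, center=c, radius=r_head),           # skull
        Primitive("sphere", 40.0, center=c, radius=r_head - 6.0),       # brain
    ]
    ctv = Primitive("sphere", 40.0, center=(c[0], c[1] + 10.0, c[2]), radius=16.0)
    oar = Primitive("sphere", 40.0, center=(c[0], c[1] - 28.0, c[2]), radius=10.0,
                    name="brainstem")
    return PhantomSpec("brain", grid_shape, spacing, layout, ctv,
                       target_class="homogeneous", oars=[oar],
                       baseline_noise_sigma=baseline_noise_sigma, seed=seed)


def thorax_spec(seed: int = 42, grid_shape=(96, 96, 96), spacing=(2.0, 2.0, 2.0),
                baseline_noise_sigma: float = 2.3) -> PhantomSpec:
    """Thorax-like: chest-wall target straddling the soft-tissue/lung interface."""
    ext = [g * (n - 1) / 2.0 for g, n in zip(spacing, grid_shape)]
    c = tuple(ext)
    r_body = 0.78 * min(ext)
    # lung: large low-density cylinder inside the body, offset towards +y
    lung_c = (c[0], c[1] + 0.30 * r_body, c[2])
    layout = [
        Primitive("cylinder", 40.0, center=c, radius=r_body, axis=2),
        Primitive("cylinder", -750.0, center=lung_c, radius=0.52 * r_body, axis=2,
                  bounds=(c[2] - 0.8 * ext[2], c[2] + 0.8 * ext[2]), name="lung"),
    ]
    # CTV at the chest wall: sphere straddling the anterior lung boundary,
    # kept clear of the body surface
    iface_y = lung_c[1] + 0.52 * r_body
    ctv = Primitive("sphere", 40.0, center=(c[0], iface_y + 2.0, c[2]), radius=9.0)
    oar = Primitive("cylinder", -750.0, center=lung_c, radius=0.52 * r_body, axis=2,
                    bounds=(c[2] - 0.8 * ext[2], c[2] + 0.8 * ext[2]), name="lung")
    return PhantomSpec("thorax", grid_shape, spacing, layout, ctv,
                       target_class="interface", oars=[oar],
                       baseline_noise_sigma=baseline_noise_sigma, seed=seed)


def abdomen_spec(seed: int = 42, grid_shape=(96, 96, 96), spacing=(2.0, 2.0, 2.0),
                 baseline_noise_sigma: float = 11.5) -> PhantomSpec:
    """Abdomen-like: soft-tissue body with a deep homogeneous target."""
    ext = [g * (n - 1) / 2.0 for g, n in zip(spacing, grid_shape)]
    c = tuple(ext)
    r_body = 0.80 * min(ext)
    layout = [
        Primitive("cylinder", 45.0, center=c, radius=r_body, axis=2),
        Primitive("cylinder", 1000.0, center=(c[0], c[1] - 0.85 * r_body, c[2]),
                  radius=10.0, axis=0, name="spine"),
    ]
    ctv = Primitive("sphere", 45.0, center=(c[0] + 15.0, c[1], c[2]), radius=16.0)
    return PhantomSpec("abdomen", grid_shape, spacing, layout, ctv,
                       target_class="homogeneous",
                       baseline_noise_sigma=baseline_noise_sigma, seed=seed)


def pelvis_spec(seed: int = 42, grid_shape=(96, 96, 96), spacing=(2.0, 2.0, 2.0),
                baseline_noise_sigma: float = 9.6) -> PhantomSpec:
    """Pelvis-like: soft tissue with lateral bone blocks flanking the target."""
    ext = [g * (n - 1) / 2.0 for g, n in zip(spacing, grid_shape)]
    c = tuple(ext)
    r_body = 0.80 * min(ext)
    layout = [
        Primitive("cylinder", 40.0, center=c, radius=r_body, axis=2),
        Primitive("sphere", 900.0, center=(c[0] - 0.65 * r_body, c[1], c[2]), radius=18.0),
        Primitive("sphere", 900.0, center=(c[0] + 0.65 * r_body, c[1], c[2]), radius=18.0),
    ]
    ctv = Primitive("sphere", 40.0, center=c, radius=16.0)
    return PhantomSpec("pelvis", grid_shape, spacing, layout, ctv,
                       target_class="homogeneous",
                       baseline_noise_sigma=baseline_noise_sigma, seed=seed)


def spec_to_yaml(spec: PhantomSpec, path) -> None:
    """Serialize a phantom spec (including primitives) to YAML."""
    import yaml
    from dataclasses import asdict
    from pathlib import Path

    Path(path).write_text(yaml.safe_dump(asdict(spec), sort_keys=False))


def spec_from_yaml(path) -> PhantomSpec:
    import yaml
    from pathlib import Path

    d = yaml.safe_load(Path(path).read_text())
    for key in ("tissue_layout", "oars"):
        d[key] = [Primitive(**p) for p in d.get(key) or []]
    if d.get("ctv") is not None:
        d["ctv"] = Primitive(**d["ctv"])
    for key in ("grid_shape", "spacing"):
        d[key] = tuple(d[key])
    for prim in d["tissue_layout"] + d["oars"] + ([d["ctv"]] if d["ctv"] else []):
        if prim.center is not None:
            prim.center = tuple(prim.center)
        if prim.bounds is not None:
            prim.bounds = tuple(prim.bounds)
    return PhantomSpec(**d)


def canonical_specs(seed: int = 42) -> Dict[str, PhantomSpec]:
    return {
        "brain": brain_spec(seed),
        "thorax": thorax_spec(seed),
        "abdomen": abdomen_spec(seed),
        "pelvis": pelvis_spec(seed),
    }
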