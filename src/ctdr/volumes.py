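"""Geometry-aware scalar volumes, ROI masks, HU->RSP calibration and contours.

Conventions used across the package:

* arrays are indexed ``[x, y, z]``; world positions are in mm, voxel-centred,
  0-based (voxel ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``);
* every physical width (filter width, margin, DTA) is specified in mm and
  converted to voxels internally through the volume spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "ROISet",
    "CalibrationCurve",
    "DEFAULT_CALIBRATION",
    "read_volume",
    "write_volume",
    "read_roiset",
    "write_roiset",
    "hu_to_rsp",
    "external_from_hu",
    "expand_external",
]

Quantity = str  # {"HU", "RSP", "dose"}


@dataclass
class Volume:
    """A 3D scalar grid (HU, relative stopping power, or dose) with geometry.

    Parameters
    ----------
    data:
        3D array indexed ``[x, y, z]``.
    spacing:
        Voxel size in mm per axis, all strictly positive.
    origin:
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    quantity:
        One of ``"HU"``, ``"RSP"``, ``"dose"``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    quantity: Quantity = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume requires 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0 on all axes, got {self.spacing}")
        if self.quantity not in ("HU", "RSP", "dose"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )

    def with_data(self, data: np.ndarray, quantity: Quantity | None = None) -> "Volume":
        """New volume sharing this geometry (the universal metadata-preserving op)."""
        return replace(self, data=data, quantity=quantity or self.quantity)

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROISet:
    """Named binary masks sharing one volume geometry.

    ``roles`` maps each ROI name to one of ``external``, ``CTV``, ``PTV``,
    ``OAR``.  When external/CTV/PTV are all present the nesting
    CTV <= PTV <= external is enforced.
    """

    masks: Dict[str, np.ndarray]
    roles: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"ROI masks have inconsistent shapes: {shapes}")
        for name, mask in self.masks.items():
            self.masks[name] = np.asarray(mask, dtype=bool)
        self._check_nesting()

    def _check_nesting(self) -> None:
        by_role = {role: name for name, role in self.roles.items()}
        chain = [by_role.get("CTV"), by_role.get("PTV"), by_role.get("external")]
        present = [self.masks[n] for n in chain if n is not None]
        for inner, outer in zip(present, present[1:]):
            if np.any(inner & ~outer):
                raise ValueError("ROI nesting violated: expected CTV <= PTV <= external")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> Iterable[str]:
        return self.masks.keys()

    def by_role(self, role: str) -> np.ndarray:
        for name, r in self.roles.items():
            if r == role:
                return self.masks[name]
        raise KeyError(f"no ROI with role {role!r}")


class CalibrationCurve:
    """Piecewise-linear HU -> relative stopping power (RSP) calibration.

    Anchors must be sorted by HU with non-decreasing RSP and cover the
    clinical HU range [-1024, 3000]; values outside the anchor range clamp
    to the end anchors.
    """

    def __init__(self, anchors: Iterable[Tuple[float, float]]):
        pts = sorted((float(h), float(r)) for h, r in anchors)
        if len(pts) < 2:
            raise ValueError("calibration curve needs at least two anchors")
        self.hu = np.array([p[0] for p in pts])
        self.rsp = np.array([p[1] for p in pts])
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("duplicate HU anchors in calibration curve")
        if np.any(np.diff(self.rsp) < 0):
            raise ValueError("calibration curve must be monotonically non-decreasing")
        if np.any(self.rsp < 0):
            raise ValueError("RSP must be non-negative")
        if self.hu[0] > -1024 or self.hu[-1] < 3000:
            raise ValueError("calibration curve must cover [-1024, 3000] HU")

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        return np.interp(hu, self.hu, self.rsp)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls([(row[0], row[1]) for row in arr])

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.hu, self.rsp]), delimiter=",")


#: Generic clinical-shaped curve (the institutional curve of any given scanner
#: is proprietary; this stand-in has the conventional water and air anchors).
DEFAULT_CALIBRATION = CalibrationCurve(
    [
        (-1024, 0.001),
        (-1000, 0.001),
        (-750, 0.25),
        (0, 1.000),
        (60, 1.04),
        (700, 1.30),
        (1400, 1.60),
        (3000, 2.4),
    ]
)


def _quantity_from_name(path: Path) -> Quantity:
    name = path.name.lower()
    if "dose" in name:
        return "dose"
    if "rsp" in name:
        return "RSP"
    return "HU"


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume to NRRD (via SimpleITK) or NIfTI (via nibabel).

    The on-disk array order is (z, y, x) for NRRD (ITK convention) and
    (x, y, z) for NIfTI; both round-trip bit-exactly through
    :func:`read_volume`.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.T))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
    else:
        raise ValueError(f"unknown volume format: {path.name} (use .nrrd/.nhdr/.nii/.nii.gz)")


def read_volume(path: str | Path, quantity: Quantity | None = None) -> Volume:
    """Read an NRRD or NIfTI volume; spacing/origin preserved to <= 1e-6 mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"expected 3D volume, got {img.GetDimension()}D in {path.name}")
        data = sitk.GetArrayFromImage(img).T
        spacing = img.GetSpacing()
        origin = img.GetOrigin()
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {data.ndim}D in {path.name}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(o) for o in img.affine[:3, 3])
    else:
        raise ValueError(f"unknown volume format: {path.name}")
    return Volume(np.asarray(data), spacing, origin, quantity or _quantity_from_name(path))


def write_roiset(rois: ROISet, directory: str | Path, geometry: Volume) -> None:
    """Write each mask as a uint8 NRRD plus a JSON index of names and roles."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {}
    for name, mask in rois.masks.items():
        fname = f"{name}.nrrd"
        write_volume(geometry.with_data(mask.astype(np.uint8)), directory / fname)
        index[name] = {"file": fname, "role": rois.roles.get(name, "OAR")}
    (directory / "roiset.json").write_text(json.dumps(index, indent=2))


def read_roiset(directory: str | Path) -> ROISet:
    import json

    directory = Path(directory)
    index = json.loads((directory / "roiset.json").read_text())
    masks = {
        name: read_volume(directory / entry["file"]).data.astype(bool)
        for name, entry in index.items()
    }
    roles = {name: entry["role"] for name, entry in index.items()}
    return ROISet(masks, roles)


def hu_to_rsp(ct: Volume, curve: CalibrationCurve = DEFAULT_CALIBRATION) -> Volume:
    """Convert a HU volume to relative stopping power via the calibration curve."""
    if ct.quantity != "HU":
        raise ValueError(f"hu_to_rsp expects a HU volume, got {ct.quantity}")
    return ct.with_data(curve(ct.data), quantity="RSP")


def external_from_hu(ct: Volume, threshold: float = -300.0) -> np.ndarray:
    """Patient outline: largest connected component of {HU > threshold}, closed.

    The -300 HU default keeps lung inside the body outline while excluding
    surrounding air.
    """
    fg = ct.data > threshold
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError(f"no voxels above {threshold} HU; cannot build external contour")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    closed = ndimage.binary_closing(largest, structure=_ball(2), border_value=0)
    # the body outline encloses internal low-density cavities (e.g. lung)
    return ndimage.binary_fill_holes(closed)


def _ball(radius_vox: int) -> np.ndarray:
    r = int(radius_vox)
    x, y, z = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return x * x + y * y + z * z <= r * r


def _ball_mm(radius_mm: float, spacing: Tuple[float, float, float]) -> np.ndarray:
    rv = [max(int(np.ceil(radius_mm / s)), 0) for s in spacing]
    if all(r == 0 for r in rv):
        return np.ones((1, 1, 1), dtype=bool)
    grids = np.meshgrid(*[np.arange(-r, r + 1) * s for r, s in zip(rv, spacing)], indexing="ij")
    return sum(g * g for g in grids) <= radius_mm**2 + 1e-9


def expand_external(mask: np.ndarray, kernel_width_mm: float, spacing: Tuple[float, float, float]) -> np.ndarray:
    """Dilate the external contour by half the degradation-kernel width.

    Low-pass filtering smears the body surface into the surrounding air, so the
    external must grow by the kernel half-width to keep the smeared tissue
    inside the evaluated region.  Width 0 is the identity; expansion is
    monotone in the width.
    """
    if kernel_width_mm < 0:
        raise ValueError("kernel width must be >= 0")
    if kernel_width_mm == 0:
        return mask.astype(bool)
    radius_mm = np.ceil(kernel_width_mm / 2.0)
    return ndimage.binary_dilation(mask, structure=_ball_mm(radius_mm, spacing))
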