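"""Voxel grids, structure masks, IO, and physical-unit morphology.

A :class:`VoxelGrid` is a 3-D scalar lattice with a physical voxel spacing
and origin, tagged with the unit its values carry (``HU``, ``Bq``,
``Bq/mL``, ``Gy``, ``mg/mL`` or ``Gy/history``).  Voxel ``(i, j, k)`` has
its *center* at ``origin + (i + 0.5) * spacing`` along each axis; every
morphological margin in this package is interpreted in physical
millimetres, never in voxel counts, because the grids involved are
strongly anisotropic (e.g. 0.313 x 0.313 x 2.0 mm CT).

Masks are stored on the grid they were drawn on; use across grids always
goes through :func:`resample_mask` (nearest-center assignment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "UNITS",
    "VoxelGrid",
    "StructureMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_structure_set",
    "read_structure_set",
    "expand_mask",
    "erode_mask_radial_longitudinal",
    "resample_mask",
]

#: Recognised unit tags and what they label.
UNITS = ("HU", "Bq", "Bq/mL", "Gy", "mg/mL", "Gy/history", "decays")


@dataclass
class VoxelGrid:
    """3-D scalar lattice with physical spacing (mm), origin (mm) and a unit tag."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "HU"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VoxelGrid requires 3-D data, got {self.values.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive, got {self.spacing}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelGrid values must be finite")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (1 mL = 1000 mm^3)."""
        return self.voxel_volume_mm3 / 1000.0

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical center coordinates of all voxels along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray, unit: str) -> "VoxelGrid":
        """New grid with the same geometry, different values and unit."""
        return replace(self, values=np.asarray(values), unit=unit)


@dataclass
class StructureMask:
    """Boolean lattice indexing a reference :class:`VoxelGrid`."""

    voxels: np.ndarray
    reference: VoxelGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.reference.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} != grid shape {self.reference.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.reference.voxel_volume_ml

    def values_in(self, grid: VoxelGrid) -> np.ndarray:
        """Scalar values of ``grid`` inside the mask (same geometry required)."""
        if grid.shape != self.voxels.shape:
            raise ValueError("mask and grid shapes differ; resample the mask first")
        return grid.values[self.voxels]


# -- IO -------------------------------------------------------------------
# SimpleITK handles both NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd).
# ITK's image origin is the center of voxel (0,0,0); our internal origin is
# the corner, so the two conventions differ by half a voxel.

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    if not any(str(path).endswith(ext) for ext in _EXTENSIONS):
        raise ValueError(f"unsupported volume format: {path.name}; use {_EXTENSIONS}")
    return path


def read_volume(path: str | Path, expected_unit: str) -> VoxelGrid:
    """Read a NIfTI or MetaImage volume and tag it with ``expected_unit``."""
    path = _check_path(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path.name} is {img.GetDimension()}-D; only 3-D supported")
    values = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
    spacing = img.GetSpacing()
    itk_origin = np.asarray(img.GetOrigin())
    origin = tuple(itk_origin - 0.5 * np.asarray(spacing))
    return VoxelGrid(values=values, spacing=spacing, origin=origin, unit=expected_unit)


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    path = _check_path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(tuple(np.asarray(grid.origin) + 0.5 * np.asarray(grid.spacing)))
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path, reference: VoxelGrid) -> StructureMask:
    grid = read_volume(path, expected_unit=reference.unit)
    if not grid.same_geometry(reference):
        raise ValueError("mask file geometry does not match the reference grid")
    return StructureMask(voxels=grid.values > 0, reference=reference)


def write_mask(mask: StructureMask, path: str | Path) -> None:
    grid = mask.reference.with_values(mask.voxels.astype(np.uint8), mask.reference.unit)
    write_volume(grid, path)


def write_structure_set(
    masks: dict[str, StructureMask], directory: str | Path, stem: str = "structures"
) -> Path:
    """Write masks as 0/1 NIfTI files plus a JSON sidecar naming their roles.

    Roles follow the study convention: ``L`` (liver), ``L_shell`` (liver +
    1 cm margin), ``L_bkg`` (non-embolized background region), ``B`` (body).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for role, mask in masks.items():
        fname = f"{stem}_{role}.nii.gz"
        write_mask(mask, directory / fname)
        manifest[role] = fname
    sidecar = directory / f"{stem}.json"
    sidecar.write_text(json.dumps({"roles": manifest}, indent=2))
    return sidecar


def read_structure_set(sidecar: str | Path, reference: VoxelGrid) -> dict[str, StructureMask]:
    sidecar = Path(sidecar)
    manifest = json.loads(sidecar.read_text())["roles"]
    return {
        role: read_mask(sidecar.parent / fname, reference)
        for role, fname in manifest.items()
    }


# -- morphology in physical units ----------------------------------------

def expand_mask(mask: StructureMask, margin: float) -> StructureMask:
    """Isotropic expansion by ``margin`` mm (Euclidean, voxel-center distance).

    The result contains every voxel whose center lies within ``margin`` of
    the center of some voxel already in the mask.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0 or not mask.voxels.any():
        return StructureMask(mask.voxels.copy(), mask.reference)
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.reference.spacing)
    return StructureMask(dist <= margin + 1e-9, mask.reference)


def erode_mask_radial_longitudinal(
    mask: StructureMask, radial: float, longitudinal: float, axis: int = 2
) -> StructureMask:
    """Erode a roughly cylindrical mask by separate radial/longitudinal margins.

    Removes voxels within ``radial`` mm of the lateral surface (in-plane
    distance) and within ``longitudinal`` mm of either end (distance along
    ``axis``).  Raises if the erosion empties the mask, so callers can apply
    special rules for structures too small to erode.
    """
    if radial < 0 or longitudinal < 0:
        raise ValueError("margins must be >= 0")
    if radial == 0 and longitudinal == 0:
        return StructureMask(mask.voxels.copy(), mask.reference)
    spacing = np.asarray(mask.reference.spacing, dtype=float)
    # distances to the outside are local: work on the mask bounding box
    idx = np.argwhere(mask.voxels)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, mask.voxels.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub = mask.voxels[box]
    keep_sub = sub.copy()
    big = 1e9
    if radial > 0:
        samp = spacing.copy()
        samp[axis] = big  # distances confined to the transverse plane
        d_inplane = ndimage.distance_transform_edt(sub, sampling=samp)
        keep_sub &= d_inplane > radial
    if longitudinal > 0:
        samp = np.full(3, big)
        samp[axis] = spacing[axis]  # distances along the cylinder axis only
        d_axial = ndimage.distance_transform_edt(sub, sampling=samp)
        keep_sub &= d_axial > longitudinal
    keep = np.zeros_like(mask.voxels)
    keep[box] = keep_sub
    if not keep.any():
        raise ValueError(
            "erosion emptied the mask (structure smaller than the margins)"
        )
    return StructureMask(keep, mask.reference)


def resample_mask(mask: StructureMask, target: VoxelGrid) -> StructureMask:
    """Evaluate a mask on another grid by nearest-center assignment.

    A target voxel belongs to the resampled mask iff its center falls inside
    the rectangular extent of a source voxel that is in the mask.
    """
    src = mask.reference
    if src.same_geometry(target):
        return StructureMask(mask.voxels.copy(), target)
    idx = []
    inside = np.ones(1, dtype=bool)
    for ax in range(3):
        centers = target.voxel_centers(ax)
        i = np.floor((centers - src.origin[ax]) / src.spacing[ax]).astype(int)
        ok = (i >= 0) & (i < src.shape[ax])
        idx.append((np.clip(i, 0, src.shape[ax] - 1), ok))
    ix, okx = idx[0]
    iy, oky = idx[1]
    iz, okz = idx[2]
    inside = (
        okx[:, None, None] & oky[None, :, None] & okz[None, None, :]
    )
    if not inside.any():
        raise ValueError("grids have disjoint physical extents")
    vox = mask.voxels[np.ix_(ix, iy, iz)] & inside
    return StructureMask(vox, target)
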