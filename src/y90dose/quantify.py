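"""HU -> microsphere concentration -> Y-90 activity, and PET-side utilities.

The calibration line ``HU = m_cal * MS_con + b_cal`` is inverted per voxel
to give a microsphere concentration map; multiplying by the number of
microspheres per milligram, the per-sphere activity and the voxel volume
converts it to an activity map in Bq.  Recovery coefficients compare the
image-derived activity inside a structure with the administered activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import StructureMask, VoxelGrid

__all__ = [
    "SubjectRecord",
    "microspheres_per_mg",
    "ct_to_concentration",
    "concentration_to_activity",
    "recovery_coefficient",
    "gaussian_postfilter",
    "pet_to_activity",
    "activity_ratio_outside",
    "recovered_mass_mg",
]


@dataclass
class SubjectRecord:
    """Administered activity and microsphere factors for one subject.

    ``administered_activity_bq`` is A0 net of residuals (so
    ``residual_fraction`` defaults to 0); ``activity_per_sphere_bq`` and
    ``microspheres_per_mg`` are the two scalar factors that link
    microsphere mass concentration to Y-90 activity.
    """

    administered_activity_bq: float
    residual_fraction: float = 0.0
    activity_per_sphere_bq: float = 156.0
    microspheres_per_mg: float = 24_460.0
    masks: dict[str, StructureMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.administered_activity_bq <= 0:
            raise ValueError("administered activity must be positive")
        if not (0 <= self.residual_fraction < 1):
            raise ValueError("residual fraction must be in [0, 1)")
        if self.activity_per_sphere_bq <= 0 or self.microspheres_per_mg <= 0:
            raise ValueError("microsphere factors must be positive")


def microspheres_per_mg(mean_sphere_mass_mg: float) -> float:
    """Number of microspheres per milligram from the mean sphere mass."""
    if mean_sphere_mass_mg <= 0:
        raise ValueError("mean sphere mass must be positive")
    return 1.0 / mean_sphere_mass_mg


def ct_to_concentration(
    ct: VoxelGrid,
    slope_hu_per_mg_ml: float,
    intercept_hu: float,
    clamp: bool = True,
    mask: StructureMask | None = None,
) -> VoxelGrid:
    """Invert the calibration line to a concentration map (mg/mL).

    With ``clamp`` (default), voxels at or below the intercept map to
    0 mg/mL: the intercept is a one-sided 95% detection threshold, so such
    voxels are not credibly embolized.  Outside ``mask`` (if given) the
    concentration is set to 0.
    """
    if ct.unit != "HU":
        raise ValueError(f"expected an HU grid, got {ct.unit!r}")
    if slope_hu_per_mg_ml <= 0:
        raise ValueError("calibration slope must be positive")
    conc = (ct.values - intercept_hu) / slope_hu_per_mg_ml
    if clamp:
        conc = np.maximum(conc, 0.0)
    if mask is not None:
        if mask.voxels.shape != ct.shape:
            raise ValueError("mask geometry does not match the CT grid")
        conc = np.where(mask.voxels, conc, 0.0)
    return ct.with_values(conc, "mg/mL")


def concentration_to_activity(conc: VoxelGrid, record: SubjectRecord) -> VoxelGrid:
    """Per-voxel Bq = concentration x spheres/mg x Bq/sphere x voxel mL."""
    if conc.unit != "mg/mL":
        raise ValueError(f"expected a mg/mL grid, got {conc.unit!r}")
    factor = (record.microspheres_per_mg * record.activity_per_sphere_bq
              * conc.voxel_volume_ml)
    return conc.with_values(conc.values * factor, "Bq")


def recovery_coefficient(activity: VoxelGrid, mask: StructureMask,
                         administered_activity_bq: float) -> float:
    """Percentage of the administered activity recovered inside ``mask``."""
    if administered_activity_bq <= 0:
        raise ValueError("administered activity must be positive")
    if activity.unit != "Bq":
        raise ValueError(f"expected a Bq grid, got {activity.unit!r}")
    return 100.0 * float(mask.values_in(activity).sum()) / administered_activity_bq


def gaussian_postfilter(pet: VoxelGrid, fwhm_mm: float) -> VoxelGrid:
    """Separable Gaussian post-filter with FWHM in physical mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return pet.with_values(pet.values.copy(), pet.unit)
    sigma_vox = fwhm_mm / 2.3548 / np.asarray(pet.spacing)
    return pet.with_values(ndimage.gaussian_filter(pet.values, sigma=sigma_vox),
                           pet.unit)


def pet_to_activity(pet: VoxelGrid) -> VoxelGrid:
    """Convert an activity-concentration grid (Bq/mL) to per-voxel Bq."""
    if pet.unit != "Bq/mL":
        raise ValueError(f"expected a Bq/mL grid, got {pet.unit!r}")
    return pet.with_values(pet.values * pet.voxel_volume_ml, "Bq")


def activity_ratio_outside(activity: VoxelGrid, inner: StructureMask,
                           outer: StructureMask) -> float:
    """Percent of the activity in ``outer`` that lies outside ``inner``."""
    if np.any(inner.voxels & ~outer.voxels):
        raise ValueError("inner mask must be a subset of outer mask")
    total = float(outer.values_in(activity).sum())
    if total == 0:
        raise ValueError("no activity inside the outer structure")
    outside = float(activity.values[outer.voxels & ~inner.voxels].sum())
    return 100.0 * outside / total


def recovered_mass_mg(
    ct: VoxelGrid,
    mask: StructureMask,
    slope_hu_per_mg_ml: float,
    intercept_hu: float,
) -> float:
    """Microsphere mass inside a contour from the calibration line.

    Signed enhancement integral: sum of (HU - intercept) / slope x voxel
    volume, *without* clamping.  For mass integration the intercept should
    be the fitted calibration intercept (~ the background mean), not the
    one-sided detection threshold: background noise then averages to zero
    and the integral is unbiased, which is what makes the mass of even a
    2-mm structure recoverable once the contour is expanded beyond the
    blurred boundary.
    """
    if ct.unit != "HU":
        raise ValueError(f"expected an HU grid, got {ct.unit!r}")
    if slope_hu_per_mg_ml <= 0:
        raise ValueError("calibration slope must be positive")
    hu = mask.values_in(ct)
    conc = (hu - intercept_hu) / slope_hu_per_mg_ml  # mg/mL, signed
    return float(conc.sum() * ct.voxel_volume_ml)
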