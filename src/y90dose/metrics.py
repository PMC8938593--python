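"""Per-structure dose statistics, cumulative DVHs, detectability limits,
and boundary-activity fractions.

Conventions (the source material leaves them open, so they are fixed here
and documented): voxel-population standard deviations divide by n; D_x is
the exact order statistic (no interpolation) - the largest dose d such
that at least x% of the masked volume receives >= d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import BackgroundStats, CalibrationCurve, ONE_SIDED_95_Z
from .grids import StructureMask, VoxelGrid
from .quantify import SubjectRecord

__all__ = [
    "DoseReport",
    "CumulativeDVH",
    "DetectabilityResult",
    "dose_stats",
    "cdvh",
    "d_x",
    "detectability",
    "boundary_activity_fraction",
]


@dataclass
class DoseReport:
    """Summary dose metrics over one structure."""

    d_med_gy: float
    d_max_gy: float
    d_mean_gy: float
    sigma_gy: float
    cov: float
    d70_gy: float
    n_voxels: int


@dataclass
class CumulativeDVH:
    """Volume fraction receiving at least each dose edge (non-increasing)."""

    dose_edges_gy: np.ndarray
    volume_fraction: np.ndarray

    def at(self, dose_gy: float) -> float:
        """Fraction of the volume receiving >= ``dose_gy``."""
        return float(np.interp(dose_gy, self.dose_edges_gy, self.volume_fraction))


@dataclass
class DetectabilityResult:
    """Limit of blank / detection and minimum detectable activity (CT)."""

    lob_hu: float
    lod_hu: float
    lod_mg_ml: float
    mda_bq_ml: float


def _masked(dose: VoxelGrid, mask: StructureMask) -> np.ndarray:
    vals = mask.values_in(dose)
    if vals.size == 0:
        raise ValueError("empty mask")
    return vals


def dose_stats(dose: VoxelGrid, mask: StructureMask) -> DoseReport:
    vals = _masked(dose, mask)
    mean = float(vals.mean())
    sigma = float(vals.std())  # population SD over the voxel population
    return DoseReport(
        d_med_gy=float(np.median(vals)),
        d_max_gy=float(vals.max()),
        d_mean_gy=mean,
        sigma_gy=sigma,
        cov=sigma / mean if mean != 0 else np.nan,
        d70_gy=d_x(dose, mask, 70.0),
        n_voxels=int(vals.size),
    )


def cdvh(dose: VoxelGrid, mask: StructureMask, bins: int = 200) -> CumulativeDVH:
    """Cumulative DVH computed exactly from sorted voxel doses, then binned."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    vals = np.sort(_masked(dose, mask))
    edges = np.linspace(0.0, float(vals.max()) if vals.max() > 0 else 1.0, bins)
    # fraction with dose >= edge
    frac = 1.0 - np.searchsorted(vals, edges, side="left") / vals.size
    return CumulativeDVH(dose_edges_gy=edges, volume_fraction=frac)


def d_x(dose: VoxelGrid, mask: StructureMask, x: float) -> float:
    """Minimum dose received by at least x% of the structure volume."""
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    vals = np.sort(_masked(dose, mask))[::-1]  # descending
    k = int(np.ceil(x / 100.0 * vals.size))
    return float(vals[k - 1])


def detectability(
    bkg: BackgroundStats,
    sigma_low_conc_hu: float,
    curve: CalibrationCurve,
    record: SubjectRecord,
    delta_hu_mode: bool = False,
    intercept_hu: float | None = None,
) -> DetectabilityResult:
    """Limits of blank/detection and the minimum detectable activity.

    LOB = mu_bkg + 1.645 sigma_bkg (mu_bkg = 0 in delta-HU mode);
    LOD_HU = LOB + 1.645 sigma of a known low-concentration sample;
    LOD in mg/mL inverts the calibration line; MDA multiplies by the two
    microsphere scalar factors, giving Bq/mL.
    """
    if curve.slope_hu_per_mg_ml <= 0:
        raise ValueError("calibration slope must be positive")
    mu = 0.0 if delta_hu_mode else bkg.mu_hu
    lob = mu + ONE_SIDED_95_Z * bkg.sigma_hu
    lod_hu = lob + ONE_SIDED_95_Z * sigma_low_conc_hu
    if intercept_hu is None:
        intercept_hu = 0.0 if delta_hu_mode else curve.intercept_hu
    lod_conc = (lod_hu - intercept_hu) / curve.slope_hu_per_mg_ml
    mda = lod_conc * record.microspheres_per_mg * record.activity_per_sphere_bq
    return DetectabilityResult(lob_hu=lob, lod_hu=lod_hu,
                               lod_mg_ml=lod_conc, mda_bq_ml=mda)


def boundary_activity_fraction(activity: VoxelGrid, mask: StructureMask,
                               depth_mm: float) -> float:
    """Percent of in-mask activity within ``depth_mm`` of the mask's
    exterior boundary (physical-unit distance to the nearest outside voxel)."""
    if depth_mm < 0:
        raise ValueError("depth must be >= 0")
    vals_total = float(mask.values_in(activity).sum())
    if mask.n_voxels == 0 or vals_total == 0:
        raise ValueError("empty mask or no activity inside the mask")
    # pad so the grid edge counts as exterior boundary too
    padded = np.pad(mask.voxels, 1, constant_values=False)
    dist = ndimage.distance_transform_edt(padded,
                                          sampling=mask.reference.spacing
                                          )[1:-1, 1:-1, 1:-1]
    near = mask.voxels & (dist <= depth_mm + 1e-9)
    return 100.0 * float(activity.values[near].sum()) / vals_total
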