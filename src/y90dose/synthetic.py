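"""Synthetic calibration phantom and virtual subjects.

No image data accompany the study this package operationalizes, so every
downstream stage is exercised against synthetic ground truth:

* a 27-post cylindrical calibration phantom (nine post diameters per
  microsphere concentration, posts 40 mm long on a 100 mm circle inside a
  150 mm resin background), imaged with a Gaussian PSF and additive
  Gaussian HU noise;
* virtual subjects: an ellipsoidal liver holding a branching
  vascular-tree-like microsphere deposition, with a paired high-resolution
  CT (forward model of the calibration line plus contrast nonuniformity
  and noise) and a coarse PET (activity resampled, blurred, and smeared
  along the cranial-caudal axis to mimic respiration).

All randomness flows through one seeded generator per call; the seed is
recorded in the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import StructureMask, VoxelGrid, expand_mask
from .quantify import SubjectRecord

__all__ = [
    "PostGeometry",
    "PhantomSpec",
    "VirtualSubject",
    "generate_phantom_ct",
    "generate_virtual_subject",
]

#: CT and PET grid defaults: the acquisition voxel sizes of the study.
CT_SPACING_MM = (0.313, 0.313, 2.0)
PET_SPACING_MM = (2.039, 2.039, 2.039)


@dataclass
class PostGeometry:
    """One calibration post: a z-axis cylinder at (x, y), diameter, conc."""

    x_mm: float
    y_mm: float
    diameter_mm: float
    concentration_mg_ml: float
    length_mm: float


@dataclass
class PhantomSpec:
    """Geometry and imaging model of the calibration phantom."""

    post_diameters_mm: tuple[float, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 15)
    concentrations_mg_ml: tuple[float, ...] = (0.5, 5.0, 25.0)
    post_length_mm: float = 40.0
    post_axis_radius_mm: float = 100.0
    background_radius_mm: float = 150.0
    background_mu_hu: float = 50.0
    background_sigma_hu: float = 4.0
    true_slope_hu_per_mg_ml: float = 14.13
    psf_fwhm_mm: float = 1.0
    spacing_mm: tuple[float, float, float] = CT_SPACING_MM
    fov_margin_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.post_diameters_mm):
            raise ValueError("post diameters must be positive")
        if any(c < 0 for c in self.concentrations_mg_ml):
            raise ValueError("concentrations must be non-negative")

    def posts(self) -> list[PostGeometry]:
        """Post geometry records, equally spaced on the placement circle."""
        n = len(self.post_diameters_mm) * len(self.concentrations_mg_ml)
        angles = 2 * np.pi * np.arange(n) / n
        out = []
        k = 0
        for conc in self.concentrations_mg_ml:
            for dia in self.post_diameters_mm:
                out.append(
                    PostGeometry(
                        x_mm=self.post_axis_radius_mm * np.cos(angles[k]),
                        y_mm=self.post_axis_radius_mm * np.sin(angles[k]),
                        diameter_mm=dia,
                        concentration_mg_ml=conc,
                        length_mm=self.post_length_mm,
                    )
                )
                k += 1
        # neighbouring posts must not overlap
        if n > 1:
            pitch = 2 * self.post_axis_radius_mm * np.sin(np.pi / n)
            if pitch < max(self.post_diameters_mm):
                raise ValueError("post geometry infeasible: posts overlap")
        return out


def generate_phantom_ct(spec: PhantomSpec) -> tuple[VoxelGrid, list[PostGeometry]]:
    """Simulate the phantom CT in HU and return it with the post records.

    Inside a post the noiseless value is ``slope * concentration +
    background_mu``; the resin background carries ``background_mu``; air
    (outside the resin cylinder or beyond the post length in z) is
    -1000 HU.  The Gaussian PSF is applied before additive noise.
    """
    posts = spec.posts()
    dx, dy, dz = spec.spacing_mm
    r_fov = spec.post_axis_radius_mm + max(spec.post_diameters_mm) / 2 + spec.fov_margin_mm
    r_fov = min(r_fov, spec.background_radius_mm + spec.fov_margin_mm)
    nx = int(np.ceil(2 * r_fov / dx))
    ny = int(np.ceil(2 * r_fov / dy))
    z_half = spec.post_length_mm / 2 + 10.0
    nz = int(np.ceil(2 * z_half / dz))
    origin = (-nx * dx / 2, -ny * dy / 2, -nz * dz / 2)

    xc = origin[0] + (np.arange(nx) + 0.5) * dx
    yc = origin[1] + (np.arange(ny) + 0.5) * dy
    zc = origin[2] + (np.arange(nz) + 0.5) * dz

    values = np.full((nx, ny, nz), -1000.0, dtype=np.float32)
    in_resin_xy = (xc[:, None] ** 2 + yc[None, :] ** 2) <= spec.background_radius_mm**2
    in_slab_z = np.abs(zc) <= spec.post_length_mm / 2
    values[in_resin_xy[:, :, None] & in_slab_z[None, None, :]] = spec.background_mu_hu

    # post discs are anti-aliased: edge voxels get the occupancy-weighted HU
    # (sub-voxel partial volume, as a real CT reconstruction would show)
    sub_n = 4
    off = (np.arange(sub_n) + 0.5) / sub_n - 0.5
    for post in posts:
        ix = np.where(np.abs(xc - post.x_mm) <= post.diameter_mm / 2 + dx)[0]
        iy = np.where(np.abs(yc - post.y_mm) <= post.diameter_mm / 2 + dy)[0]
        iz = np.where(np.abs(zc) <= post.length_mm / 2)[0]
        if not (len(ix) and len(iy) and len(iz)):
            continue
        frac = np.zeros((len(ix), len(iy)), dtype=np.float32)
        for ox in off:
            for oy in off:
                r2 = ((xc[ix][:, None] + ox * dx - post.x_mm) ** 2
                      + (yc[iy][None, :] + oy * dy - post.y_mm) ** 2)
                frac += r2 <= (post.diameter_mm / 2) ** 2
        frac /= sub_n**2
        enhancement = spec.true_slope_hu_per_mg_ml * post.concentration_mg_ml
        sub = values[np.ix_(ix, iy, iz)]
        sub += (frac * enhancement)[:, :, None]
        values[np.ix_(ix, iy, iz)] = sub

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm / 2.3548 / np.asarray(spec.spacing_mm)
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if spec.background_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.standard_normal(values.shape, dtype=np.float32) \
            * np.float32(spec.background_sigma_hu)

    grid = VoxelGrid(values=np.asarray(values, dtype=np.float64),
                     spacing=spec.spacing_mm, origin=origin, unit="HU")
    return grid, posts


# -- virtual subjects -----------------------------------------------------

@dataclass
class TreeDepositionParams:
    """Branching-segment deposition model inside the liver.

    A random binary tree of cylindrical segments starts at an entry point
    on the liver surface; each branch carries a lognormal concentration
    multiplier, and the resulting vessel-bound weight is spread into the
    surrounding perfusion territory by a Gaussian of ``territory_fwhm_mm``
    (microspheres lodge in the capillary bed around arterial branches, not
    in the vessel lumen).  Defaults are calibrated once so the CT-grid
    liver dose heterogeneity (COV) is ~2.
    """

    n_generations: int = 8
    initial_length_mm: float = 18.0
    length_decay: float = 0.78
    initial_radius_mm: float = 2.0
    radius_decay: float = 0.85
    branch_angle_sd_rad: float = 0.6
    lognormal_sigma: float = 0.5
    territory_fwhm_mm: float = 4.0
    max_retries: int = 40


@dataclass
class VirtualSubject:
    """Ground truth plus simulated CT/PET for one synthetic subject."""

    truth_activity: VoxelGrid  # Bq on the CT grid
    ct: VoxelGrid              # HU on the CT grid
    pet: VoxelGrid             # Bq/mL on the PET grid
    masks: dict[str, StructureMask]
    record: SubjectRecord
    true_slope_hu_per_mg_ml: float
    seed: int
    background_mu_hu: float = 0.0


def _ellipsoid_mask(grid: VoxelGrid, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    ax = [grid.voxel_centers(a) for a in range(3)]
    t = ((ax[0][:, None, None] - center[0]) / semi[0]) ** 2 \
        + ((ax[1][None, :, None] - center[1]) / semi[1]) ** 2 \
        + ((ax[2][None, None, :] - center[2]) / semi[2]) ** 2
    return t <= 1.0


def _rasterize_segment(grid: VoxelGrid, p0: np.ndarray, p1: np.ndarray,
                       radius: float, weight: float, out: np.ndarray) -> None:
    """Add ``weight`` (spread uniformly) to voxels within ``radius`` of segment."""
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    sl = []
    for a in range(3):
        c = grid.voxel_centers(a)
        i0 = np.searchsorted(c, lo[a])
        i1 = np.searchsorted(c, hi[a]) + 1
        sl.append((max(i0 - 1, 0), min(i1 + 1, grid.shape[a])))
    ax = [grid.voxel_centers(a)[sl[a][0]:sl[a][1]] for a in range(3)]
    if any(len(a) == 0 for a in ax):
        return
    pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    hit = dist <= radius
    n = int(hit.sum())
    if n == 0:
        return
    region = out[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]]
    region[hit] += weight / n


def _grow_tree(grid: VoxelGrid, liver: np.ndarray, center: np.ndarray,
               semi: np.ndarray, params: TreeDepositionParams,
               rng: np.random.Generator) -> np.ndarray:
    """Deposit relative microsphere weight along a random branching tree."""
    out = np.zeros(grid.shape)
    entry = center + np.array([-semi[0], 0.0, 0.0])
    direction = np.array([1.0, 0.0, 0.0])
    tips = [(entry, direction, params.initial_length_mm,
             params.initial_radius_mm, 1.0)]
    inside = lambda p: bool(
        ((p - center) / semi) @ ((p - center) / semi) <= 1.0
    )
    for _ in range(params.n_generations):
        new_tips = []
        for p0, d0, length, radius, w in tips:
            for _branch in range(2):
                ok = False
                for _try in range(params.max_retries):
                    tx, ty = rng.normal(scale=params.branch_angle_sd_rad, size=2)
                    d = d0 + tx * _perp(d0, 0) + ty * _perp(d0, 1)
                    d = d / np.linalg.norm(d)
                    p1 = p0 + d * length
                    if inside(p1):
                        ok = True
                        break
                if not ok:
                    # steer back toward the liver center as a last resort
                    d = (center - p0)
                    d = d / np.linalg.norm(d)
                    p1 = p0 + d * length
                    if not inside(p1):
                        raise RuntimeError("deposition tree escaped the liver mask")
                wb = w * rng.lognormal(mean=0.0, sigma=params.lognormal_sigma)
                _rasterize_segment(grid, p0, p1, radius, wb, out)
                new_tips.append((p1, d, length * params.length_decay,
                                 radius * params.radius_decay, wb))
        tips = new_tips
    out[~liver] = 0.0
    return out


def _perp(d: np.ndarray, which: int) -> np.ndarray:
    a = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    return e1 if which == 0 else np.cross(d, e1)


def generate_virtual_subject(
    liver_volume_ml: float = 79.0,
    administered_activity_bq: float = 144.2e6,
    deposition: TreeDepositionParams | None = None,
    ct_noise_hu: float = 4.0,
    pet_fwhm_mm: float = 7.0,
    resp_amplitude_mm: float = 5.0,
    seed: int = 0,
    true_slope_hu_per_mg_ml: float = 14.13,
    background_mu_hu: float = 90.0,
    contrast_nonuniformity_hu: float = 1.0,
    pet_noise_frac: float = 0.0,
    pet_positivity_bias: bool = False,
    ct_spacing_mm: tuple[float, float, float] = CT_SPACING_MM,
    pet_spacing_mm: tuple[float, float, float] = PET_SPACING_MM,
    microspheres_per_mg: float = 24_460.0,
    activity_per_sphere_bq: float = 156.0,
) -> VirtualSubject:
    """Simulate one virtual subject with paired ground truth, CT and PET.

    The administered activity is deposited entirely inside the liver along
    a branching-tree model (sum of the truth grid equals the administered
    activity exactly); the CT is the forward calibration model; the PET is
    the truth resampled to the coarse grid, expressed as Bq/mL, blurred
    with ``pet_fwhm_mm`` and averaged over a uniform cranial-caudal
    displacement of +/- ``resp_amplitude_mm``/2.
    """
    if not (20.0 <= liver_volume_ml <= 500.0):
        raise ValueError("liver_volume_ml outside plausible range")
    if resp_amplitude_mm < 0:
        raise ValueError("resp_amplitude_mm must be >= 0")
    deposition = deposition or TreeDepositionParams()
    rng = np.random.default_rng(seed)

    # liver ellipsoid with mild anisotropy; volume fixes the scale
    shape_factors = np.array([1.25, 1.0, 0.8])
    scale = (3 * liver_volume_ml * 1000.0 / (4 * np.pi * np.prod(shape_factors))) ** (1 / 3)
    semi = shape_factors * scale
    body_semi = semi * 1.9 + 12.0

    dx, dy, dz = ct_spacing_mm
    half = body_semi + 6.0
    n = (np.ceil(2 * half / np.array(ct_spacing_mm))).astype(int)
    origin = tuple(-n * np.array(ct_spacing_mm) / 2)
    ct_grid = VoxelGrid(values=np.zeros(tuple(n)), spacing=ct_spacing_mm,
                        origin=origin, unit="HU")
    center = np.zeros(3)
    liver = _ellipsoid_mask(ct_grid, center, semi)
    body = _ellipsoid_mask(ct_grid, center, body_semi)

    weights = _grow_tree(ct_grid, liver, center, semi, deposition, rng)
    if deposition.territory_fwhm_mm > 0:
        weights = ndimage.gaussian_filter(
            weights,
            sigma=deposition.territory_fwhm_mm / 2.3548 / np.asarray(ct_spacing_mm))
        weights[~liver] = 0.0
    total_w = weights.sum()
    if total_w <= 0:
        raise RuntimeError("deposition tree produced no in-liver weight")
    truth_bq = weights * (administered_activity_bq / total_w)

    # background region: the liver octant farthest from the entry with no deposit
    l_bkg = _find_background_region(ct_grid, liver, truth_bq, rng)

    # CT forward model: HU = slope * concentration + background (+ fields)
    v_ml = ct_grid.voxel_volume_ml
    conc = truth_bq / (microspheres_per_mg * activity_per_sphere_bq * v_ml)
    hu = np.full(ct_grid.shape, -1000.0)
    hu[body] = 40.0
    hu[liver] = background_mu_hu
    if contrast_nonuniformity_hu > 0:
        field = rng.standard_normal(ct_grid.shape)
        field = ndimage.gaussian_filter(field, sigma=np.array([15.0, 15.0, 10.0])
                                        / np.array(ct_spacing_mm))
        field -= field[liver].mean()
        sd = field[liver].std()
        if sd > 0:
            hu[liver] += contrast_nonuniformity_hu / sd * field[liver]
    hu += true_slope_hu_per_mg_ml * conc
    if ct_noise_hu > 0:
        hu = hu + rng.normal(0.0, ct_noise_hu, size=hu.shape)
    ct = ct_grid.with_values(hu, "HU")

    # PET: conservative binning of truth to the coarse grid, then blur + smear
    pet_n = (np.ceil(2 * half / np.array(pet_spacing_mm))).astype(int)
    pet_origin = tuple(-pet_n * np.array(pet_spacing_mm) / 2)
    pet_grid = VoxelGrid(values=np.zeros(tuple(pet_n)), spacing=pet_spacing_mm,
                         origin=pet_origin, unit="Bq/mL")
    pet_bq = _bin_activity(ct_grid, truth_bq, pet_grid)
    pet_conc = pet_bq / pet_grid.voxel_volume_ml
    if pet_fwhm_mm > 0:
        pet_conc = ndimage.gaussian_filter(
            pet_conc, sigma=pet_fwhm_mm / 2.3548 / np.array(pet_spacing_mm))
    if resp_amplitude_mm > 0:
        size_vox = max(int(round(resp_amplitude_mm / pet_spacing_mm[2])), 1)
        pet_conc = ndimage.uniform_filter1d(pet_conc, size=size_vox, axis=2)
    if pet_noise_frac > 0:
        scale_noise = pet_noise_frac * max(pet_conc.max(), 1.0)
        pet_conc = pet_conc + rng.normal(0.0, scale_noise, size=pet_conc.shape)
        if pet_positivity_bias:
            pet_conc = np.maximum(pet_conc, 0.0)
    pet = pet_grid.with_values(pet_conc, "Bq/mL")

    masks = {
        "L": StructureMask(liver, ct_grid),
        "L_bkg": l_bkg,
        "B": StructureMask(body, ct_grid),
    }
    masks["L_shell"] = expand_mask(masks["L"], 10.0)
    record = SubjectRecord(
        administered_activity_bq=administered_activity_bq,
        residual_fraction=0.0,
        activity_per_sphere_bq=activity_per_sphere_bq,
        microspheres_per_mg=microspheres_per_mg,
        masks=masks,
    )
    return VirtualSubject(
        truth_activity=ct_grid.with_values(truth_bq, "Bq"),
        ct=ct,
        pet=pet,
        masks=masks,
        record=record,
        true_slope_hu_per_mg_ml=true_slope_hu_per_mg_ml,
        seed=seed,
        background_mu_hu=background_mu_hu,
    )


def _find_background_region(grid: VoxelGrid, liver: np.ndarray,
                            truth_bq: np.ndarray,
                            rng: np.random.Generator) -> StructureMask:
    """Union of up to three deposit-free ~5 mm spheres inside the liver.

    Multiple disjoint background regions average over slow contrast
    nonuniformity much better than a single one (using only one makes the
    per-subject intercept sensitive to where it happens to be placed).
    """
    radius = 5.0
    spacing = np.asarray(grid.spacing)
    # the perfusion-territory blur leaves a negligible activity tail
    # everywhere, so "deposit-free" means below 1e-6 of the peak
    deposit = truth_bq > 1e-6 * truth_bq.max()
    dist = ndimage.distance_transform_edt(~deposit, sampling=spacing)
    dist[~liver] = 0.0
    order = np.argsort(dist.ravel())[::-1]
    union = np.zeros(grid.shape, dtype=bool)
    centers: list[np.ndarray] = []
    for flat in order[:4000:25]:
        if len(centers) >= 3:
            break
        idx = np.unravel_index(flat, grid.shape)
        c = np.array([grid.voxel_centers(a)[idx[a]] for a in range(3)])
        if any(np.linalg.norm(c - prev) < 3 * radius for prev in centers):
            continue
        sph = _ellipsoid_mask(grid, c, np.full(3, radius))
        if sph.any() and np.all(liver[sph]) and not deposit[sph].any():
            union |= sph
            centers.append(c)
    if not union.any():
        # fall back: the farthest-from-deposit neighbourhood inside the liver
        idx = np.unravel_index(order[0], grid.shape)
        c = np.array([grid.voxel_centers(a)[idx[a]] for a in range(3)])
        union = _ellipsoid_mask(grid, c, np.full(3, radius)) & liver
    return StructureMask(union, grid)


def _bin_activity(src: VoxelGrid, values: np.ndarray, target: VoxelGrid) -> np.ndarray:
    """Sum-preserving binning of per-voxel activity onto a coarser grid."""
    out = np.zeros(target.shape)
    idx = []
    ok_all = []
    for a in range(3):
        c = src.voxel_centers(a)
        i = np.floor((c - target.origin[a]) / target.spacing[a]).astype(int)
        ok = (i >= 0) & (i < target.shape[a])
        idx.append(np.clip(i, 0, target.shape[a] - 1))
        ok_all.append(ok)
    mask = ok_all[0][:, None, None] & ok_all[1][None, :, None] & ok_all[2][None, None, :]
    flat_idx = (idx[0][:, None, None] * target.shape[1] + idx[1][None, :, None]) \
        * target.shape[2] + idx[2][None, None, :]
    np.add.at(out.ravel(), flat_idx[mask], values[mask])
    return out
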