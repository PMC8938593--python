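"""Shared fixtures: small synthetic phantoms/subjects and cached kernels.

Heavy objects (the full-geometry phantom, the two Monte-Carlo kernels) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from y90dose import calibration as cal
from y90dose import kernels as krn
from y90dose.grids import VoxelGrid
from y90dose.synthetic import PhantomSpec, generate_phantom_ct, generate_virtual_subject


def make_grid(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), unit="HU"):
    return VoxelGrid(values=np.asarray(values, dtype=float), spacing=spacing,
                     origin=origin, unit=unit)


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-geometry phantom: 3 diameters x 3 concentrations, 0.5 mm grid."""
    spec = PhantomSpec(
        post_diameters_mm=(2, 4, 15),
        post_axis_radius_mm=30.0,
        background_radius_mm=50.0,
        fov_margin_mm=12.0,
        spacing_mm=(0.5, 0.5, 2.0),
        seed=7,
    )
    grid, posts = generate_phantom_ct(spec)
    return spec, grid, posts


@pytest.fixture(scope="session")
def full_phantom():
    """Full 27-post phantom at the CT acquisition resolution."""
    spec = PhantomSpec(seed=11)
    grid, posts = generate_phantom_ct(spec)
    return spec, grid, posts


@pytest.fixture(scope="session")
def full_phantom_calibration(full_phantom):
    spec, grid, posts = full_phantom
    seg = cal.segment_posts(posts, grid)
    table = cal.post_mean_table(seg, grid)
    p15 = table[table.diameter_mm == 15]
    curve = cal.fit_calibration(list(zip(p15.concentration_mg_ml, p15.mean_hu)))
    return table, curve


@pytest.fixture(scope="session")
def dvk_pet():
    """Monte-Carlo kernel at the PET voxel geometry (reduced histories)."""
    return krn.simulate_dvk((2.039, 2.039, 2.039), histories=120_000, seed=5)


@pytest.fixture(scope="session")
def dvk_ct():
    """Monte-Carlo kernel at the CT voxel geometry (reduced histories)."""
    return krn.simulate_dvk((0.313, 0.313, 2.0), histories=120_000, seed=5)


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free virtual subject on a coarse grid (fast closure checks)."""
    return generate_virtual_subject(
        liver_volume_ml=79.0,
        administered_activity_bq=144.2e6,
        ct_noise_hu=0.0,
        contrast_nonuniformity_hu=0.0,
        pet_fwhm_mm=0.0,
        resp_amplitude_mm=0.0,
        ct_spacing_mm=(1.0, 1.0, 2.0),
        seed=3,
    )


@pytest.fixture(scope="session")
def noisy_subject():
    """Realistic virtual subject on a coarse grid (noise, blur, motion)."""
    return generate_virtual_subject(
        liver_volume_ml=79.0,
        administered_activity_bq=144.2e6,
        ct_noise_hu=4.0,
        pet_fwhm_mm=7.0,
        resp_amplitude_mm=5.0,
        ct_spacing_mm=(1.0, 1.0, 2.5),
        seed=9,
    )
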