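"""Dose statistics, cumulative DVHs, D_x, detectability, boundary fractions."""

import numpy as np
import pytest

from y90dose import metrics as met
from y90dose.calibration import BackgroundStats, CalibrationCurve
from y90dose.grids import StructureMask
from y90dose.quantify import SubjectRecord
from conftest import make_grid


def _dose_and_mask(values):
    values = np.asarray(values, dtype=float)
    n = values.size
    grid = make_grid(values.reshape(n, 1, 1), unit="Gy")
    return grid, StructureMask(np.ones((n, 1, 1), bool), grid)


class TestDoseStats:
    def test_uniform_dose(self):
        dose, mask = _dose_and_mask(np.full(8, 10.0))
        rep = met.dose_stats(dose, mask)
        assert rep.d_med_gy == rep.d_max_gy == rep.d_mean_gy == rep.d70_gy == 10.0
        assert rep.cov == 0.0

    def test_one_to_ten(self):
        dose, mask = _dose_and_mask(np.arange(1, 11))
        rep = met.dose_stats(dose, mask)
        assert rep.d_mean_gy == 5.5
        assert rep.d_med_gy == 5.5
        assert rep.d_max_gy == 10.0
        assert rep.sigma_gy == pytest.approx(np.arange(1, 11).std())

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(0)
        vals = rng.random(50) * 100
        d1, m1 = _dose_and_mask(vals)
        d2, m2 = _dose_and_mask(vals * 3.0)
        r1, r2 = met.dose_stats(d1, m1), met.dose_stats(d2, m2)
        for attr in ("d_med_gy", "d_max_gy", "d_mean_gy", "sigma_gy", "d70_gy"):
            assert getattr(r2, attr) == pytest.approx(3 * getattr(r1, attr))
        assert r2.cov == pytest.approx(r1.cov)

    def test_empty_mask_rejected(self):
        dose, _ = _dose_and_mask(np.ones(4))
        empty = StructureMask(np.zeros((4, 1, 1), bool), dose)
        with pytest.raises(ValueError, match="empty"):
            met.dose_stats(dose, empty)


class TestCdvh:
    def test_uniform_dose_step_function(self):
        # fraction receiving >= d stays at 1 all the way to the dose level
        dose, mask = _dose_and_mask(np.full(10, 5.0))
        c = met.cdvh(dose, mask, bins=50)
        assert c.at(0.0) == 1.0
        assert c.at(4.9) == 1.0
        assert np.all(c.volume_fraction == 1.0)

    def test_two_voxel_plateau(self):
        dose, mask = _dose_and_mask([0.0, 100.0])
        c = met.cdvh(dose, mask, bins=101)
        assert c.at(50.0) == pytest.approx(0.5, abs=0.02)

    def test_non_increasing(self):
        rng = np.random.default_rng(1)
        dose, mask = _dose_and_mask(rng.random(100) * 40)
        c = met.cdvh(dose, mask)
        assert np.all(np.diff(c.volume_fraction) <= 1e-12)

    def test_bins_floor(self):
        dose, mask = _dose_and_mask(np.ones(4))
        with pytest.raises(ValueError):
            met.cdvh(dose, mask, bins=1)


class TestDx:
    def test_one_to_ten_d70_is_4(self):
        dose, mask = _dose_and_mask(np.arange(1, 11))
        assert met.d_x(dose, mask, 70.0) == 4.0

    def test_uniform_any_x(self):
        dose, mask = _dose_and_mask(np.full(7, 12.0))
        for x in (1, 50, 100):
            assert met.d_x(dose, mask, x) == 12.0

    def test_x_100_is_minimum(self):
        dose, mask = _dose_and_mask([3.0, 9.0, 1.0, 7.0])
        assert met.d_x(dose, mask, 100.0) == 1.0

    def test_order_statistic_oracle_on_random_sets(self):
        """Exhaustive oracle: d_x = max d with >= x% of voxels >= d."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            vals = rng.integers(0, 30, size=rng.integers(3, 40)).astype(float)
            dose, mask = _dose_and_mask(vals)
            x = float(rng.integers(1, 101))
            got = met.d_x(dose, mask, x)
            candidates = [d for d in vals
                          if (vals >= d).sum() / vals.size >= x / 100.0]
            assert got == max(candidates)

    def test_dx_non_increasing_in_x_and_bounded(self):
        rng = np.random.default_rng(3)
        dose, mask = _dose_and_mask(rng.random(60) * 100)
        xs = [10, 30, 50, 70, 90, 100]
        ds = [met.d_x(dose, mask, x) for x in xs]
        assert all(a >= b for a, b in zip(ds, ds[1:]))
        rep = met.dose_stats(dose, mask)
        assert rep.d70_gy <= rep.d_med_gy <= rep.d_max_gy

    def test_cdvh_at_d70_covers_70_percent(self):
        rng = np.random.default_rng(4)
        dose, mask = _dose_and_mask(rng.random(200) * 50)
        d70 = met.d_x(dose, mask, 70.0)
        vals = mask.values_in(dose)
        assert (vals >= d70).sum() / vals.size >= 0.70


class TestDetectability:
    def _curve(self):
        return CalibrationCurve(slope_hu_per_mg_ml=14.13,
                                slope_ci95=(13.14, 15.12), intercept_hu=0.0,
                                r_squared=0.999, residual_sd_hu=1.0,
                                fit_points=[(0.5, 7.0), (5.0, 70.0), (25.0, 353.0)])

    def _record(self):
        return SubjectRecord(administered_activity_bq=1e8,
                             activity_per_sphere_bq=156.0,
                             microspheres_per_mg=24_460.0)

    def test_mda_from_known_lod(self):
        # sigma chosen so LOD = 0.22 mg/mL in delta-HU mode
        sigma = 0.22 * 14.13 / (2 * 1.645)
        bkg = BackgroundStats(0.0, sigma, 1000)
        res = met.detectability(bkg, sigma, self._curve(), self._record(),
                                delta_hu_mode=True)
        assert res.lod_mg_ml == pytest.approx(0.22, rel=1e-9)
        assert res.mda_bq_ml == pytest.approx(0.84e6, rel=0.01)

    def test_zero_sigma_zero_lod(self):
        bkg = BackgroundStats(0.0, 0.0, 1000)
        res = met.detectability(bkg, 0.0, self._curve(), self._record(),
                                delta_hu_mode=True)
        assert res.lob_hu == 0.0
        assert res.lod_mg_ml == 0.0
        assert res.mda_bq_ml == 0.0

    def test_mda_linear_in_per_sphere_activity(self):
        bkg = BackgroundStats(0.0, 1.0, 1000)
        r1 = self._record()
        r2 = SubjectRecord(administered_activity_bq=1e8,
                           activity_per_sphere_bq=312.0,
                           microspheres_per_mg=24_460.0)
        m1 = met.detectability(bkg, 1.0, self._curve(), r1, delta_hu_mode=True)
        m2 = met.detectability(bkg, 1.0, self._curve(), r2, delta_hu_mode=True)
        assert m2.mda_bq_ml == pytest.approx(2 * m1.mda_bq_ml)

    def test_lod_at_least_lob(self):
        bkg = BackgroundStats(50.0, 3.0, 1000)
        res = met.detectability(bkg, 2.0, self._curve(), self._record())
        assert res.lod_hu >= res.lob_hu


class TestBoundaryFraction:
    def test_activity_adjacent_to_boundary_is_100(self):
        act = make_grid(np.zeros((5, 5, 5)), unit="Bq")
        vox = np.ones((5, 5, 5), bool)
        act.values[0, 2, 2] = 50.0
        out = met.boundary_activity_fraction(act, StructureMask(vox, act), 1.0)
        assert out == 100.0

    def test_uniform_sphere_shell_fraction(self):
        # analytic: fraction within 2.4 mm of a 10 mm sphere surface
        n = 60
        grid = make_grid(np.zeros((n, n, n)), spacing=(0.5, 0.5, 0.5), unit="Bq")
        c = (np.arange(n) + 0.5) * 0.5 - n * 0.25
        r = np.sqrt(c[:, None, None] ** 2 + c[None, :, None] ** 2
                    + c[None, None, :] ** 2)
        sphere = r <= 10.0
        act = grid.with_values(sphere.astype(float), "Bq")
        out = met.boundary_activity_fraction(act, StructureMask(sphere, grid), 2.4)
        expected = 100 * (1 - (7.6 / 10.0) ** 3)  # 56.1%
        assert out == pytest.approx(expected, rel=0.06)

    def test_depth_larger_than_mask_gives_100(self):
        act = make_grid(np.ones((6, 6, 6)), unit="Bq")
        vox = np.zeros((6, 6, 6), bool)
        vox[2:4, 2:4, 2:4] = True
        out = met.boundary_activity_fraction(act, StructureMask(vox, act), 50.0)
        assert out == 100.0

    def test_negative_depth_rejected(self):
        act = make_grid(np.ones((3, 3, 3)), unit="Bq")
        with pytest.raises(ValueError):
            met.boundary_activity_fraction(
                act, StructureMask(np.ones((3, 3, 3), bool), act), -1.0)
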