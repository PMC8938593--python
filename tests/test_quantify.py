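"""HU -> concentration -> activity conversion and PET utilities."""

import numpy as np
import pytest

from y90dose import quantify as qty
from y90dose.grids import StructureMask
from y90dose.quantify import SubjectRecord
from conftest import make_grid


def _record():
    return SubjectRecord(administered_activity_bq=1.324e8,
                         activity_per_sphere_bq=156.0,
                         microspheres_per_mg=24_460.0)


class TestConcentration:
    def test_intercept_maps_to_zero(self):
        ct = make_grid(np.full((3, 3, 3), 110.0))
        out = qty.ct_to_concentration(ct, 14.13, 110.0)
        assert np.all(out.values == 0.0)
        assert out.unit == "mg/mL"

    def test_one_slope_above_intercept_is_one_mg_ml(self):
        ct = make_grid(np.full((3, 3, 3), 110.0 + 14.13))
        out = qty.ct_to_concentration(ct, 14.13, 110.0)
        assert out.values.flat[0] == pytest.approx(1.0)

    def test_below_intercept_clamped_to_zero(self):
        ct = make_grid(np.full((3, 3, 3), 60.0))
        out = qty.ct_to_concentration(ct, 14.13, 110.0)
        assert np.all(out.values == 0.0)

    def test_unclamped_inversion_is_exactly_affine(self):
        rng = np.random.default_rng(0)
        ct = make_grid(rng.normal(100, 50, (4, 4, 4)))
        out = qty.ct_to_concentration(ct, 14.13, 110.0, clamp=False)
        np.testing.assert_allclose(out.values, (ct.values - 110.0) / 14.13)

    def test_clamping_never_increases_total_concentration_magnitude(self):
        rng = np.random.default_rng(1)
        ct = make_grid(rng.normal(110, 30, (5, 5, 5)))
        clamped = qty.ct_to_concentration(ct, 14.13, 110.0, clamp=True)
        raw = qty.ct_to_concentration(ct, 14.13, 110.0, clamp=False)
        assert clamped.values.sum() >= raw.values.sum()
        assert np.all(clamped.values >= 0)

    def test_mask_zeroes_outside(self):
        ct = make_grid(np.full((3, 3, 3), 200.0))
        vox = np.zeros((3, 3, 3), bool)
        vox[1, 1, 1] = True
        out = qty.ct_to_concentration(ct, 14.13, 110.0,
                                      mask=StructureMask(vox, ct))
        assert out.values[1, 1, 1] > 0
        assert out.values.sum() == out.values[1, 1, 1]


class TestActivity:
    def test_ct_voxel_conversion_factor(self):
        # 1 mg/mL on a 0.313 x 0.313 x 2.0 mm voxel -> ~747.7 Bq
        conc = make_grid(np.ones((2, 2, 2)), spacing=(0.313, 0.313, 2.0),
                         unit="mg/mL")
        out = qty.concentration_to_activity(conc, _record())
        expected = 24_460.0 * 156.0 * (0.313 * 0.313 * 2.0 / 1000.0)
        assert out.values.flat[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(747.7, abs=0.1)

    def test_zero_concentration_gives_zero(self):
        conc = make_grid(np.zeros((2, 2, 2)), unit="mg/mL")
        assert qty.concentration_to_activity(conc, _record()).values.sum() == 0

    def test_linearity_in_voxel_volume(self):
        conc1 = make_grid(np.ones((2, 2, 2)), spacing=(1, 1, 1), unit="mg/mL")
        conc2 = make_grid(np.ones((2, 2, 2)), spacing=(1, 1, 2), unit="mg/mL")
        a1 = qty.concentration_to_activity(conc1, _record()).values.flat[0]
        a2 = qty.concentration_to_activity(conc2, _record()).values.flat[0]
        assert a2 == pytest.approx(2 * a1)

    def test_wrong_unit_rejected(self):
        with pytest.raises(ValueError, match="mg/mL"):
            qty.concentration_to_activity(make_grid(np.ones((2, 2, 2))), _record())


class TestRecovery:
    def test_full_recovery_is_100(self):
        act = make_grid(np.full((3, 3, 3), 10.0), unit="Bq")
        mask = StructureMask(np.ones((3, 3, 3), bool), act)
        assert qty.recovery_coefficient(act, mask, 270.0) == pytest.approx(100.0)

    def test_rc_monotone_in_mask(self):
        rng = np.random.default_rng(2)
        act = make_grid(rng.random((4, 4, 4)), unit="Bq")
        small = np.zeros((4, 4, 4), bool)
        small[1:3, 1:3, 1:3] = True
        big = np.ones((4, 4, 4), bool)
        rc_small = qty.recovery_coefficient(act, StructureMask(small, act), 1.0)
        rc_big = qty.recovery_coefficient(act, StructureMask(big, act), 1.0)
        assert rc_big >= rc_small

    def test_invalid_a0_rejected(self):
        act = make_grid(np.ones((2, 2, 2)), unit="Bq")
        mask = StructureMask(np.ones((2, 2, 2), bool), act)
        with pytest.raises(ValueError):
            qty.recovery_coefficient(act, mask, 0.0)


class TestPostfilter:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(3)
        pet = make_grid(rng.random((5, 5, 5)), unit="Bq/mL")
        out = qty.gaussian_postfilter(pet, 0.0)
        np.testing.assert_array_equal(out.values, pet.values)

    def test_uniform_field_unchanged_in_interior(self):
        pet = make_grid(np.full((11, 11, 11), 7.0), spacing=(2.039,) * 3,
                        unit="Bq/mL")
        out = qty.gaussian_postfilter(pet, 4.0)
        assert out.values[5, 5, 5] == pytest.approx(7.0, rel=1e-6)

    def test_noise_suppression_matches_kernel_l2_norm(self):
        # white-noise SD is scaled by the l2 norm of the discrete kernel
        from scipy.ndimage import gaussian_filter
        spacing = np.array([2.039] * 3)
        sigma_vox = 4.0 / 2.3548 / spacing
        impulse = np.zeros((41, 41, 41))
        impulse[20, 20, 20] = 1.0
        kernel = gaussian_filter(impulse, sigma=sigma_vox)
        predicted = np.sqrt((kernel**2).sum())
        rng = np.random.default_rng(4)
        pet = make_grid(rng.normal(0, 1, (60, 60, 60)), spacing=tuple(spacing),
                        unit="Bq/mL")
        out = qty.gaussian_postfilter(pet, 4.0)
        measured = out.values[10:-10, 10:-10, 10:-10].std()
        assert measured == pytest.approx(predicted, rel=0.05)
        # a few-fold suppression of white noise (correlated reconstruction
        # noise in real scans is suppressed less, ~2.5-fold)
        assert 2.0 < 1 / predicted < 8.0


class TestPetToActivity:
    def test_pet_voxel_volume_factor(self):
        pet = make_grid(np.full((2, 2, 2), 1.0e6), spacing=(2.039,) * 3,
                        unit="Bq/mL")
        out = qty.pet_to_activity(pet)
        assert out.values.flat[0] == pytest.approx(8477.0, rel=1e-3)

    def test_zero_grid(self):
        pet = make_grid(np.zeros((2, 2, 2)), unit="Bq/mL")
        assert qty.pet_to_activity(pet).values.sum() == 0

    def test_wrong_unit_rejected(self):
        with pytest.raises(ValueError, match="Bq/mL"):
            qty.pet_to_activity(make_grid(np.zeros((2, 2, 2)), unit="Bq"))


class TestActivityRatio:
    def _setup(self, inner_val, outer_val):
        act = make_grid(np.zeros((6, 6, 6)), unit="Bq")
        inner = np.zeros((6, 6, 6), bool)
        inner[2:4, 2:4, 2:4] = True
        outer = np.ones((6, 6, 6), bool)
        act.values[inner] = inner_val
        act.values[~inner] = outer_val
        return act, StructureMask(inner, act), StructureMask(outer, act)

    def test_all_inside_inner_is_zero(self):
        act, inner, outer = self._setup(5.0, 0.0)
        assert qty.activity_ratio_outside(act, inner, outer) == 0.0

    def test_all_outside_inner_is_100(self):
        act, inner, outer = self._setup(0.0, 5.0)
        assert qty.activity_ratio_outside(act, inner, outer) == 100.0

    def test_non_subset_rejected(self):
        act, inner, outer = self._setup(1.0, 1.0)
        with pytest.raises(ValueError, match="subset"):
            qty.activity_ratio_outside(act, outer, inner)


class TestPipelineClosure:
    def test_noiseless_subject_recovers_administered_activity(self, clean_subject):
        from y90dose import calibration as cal
        bkg = cal.BackgroundStats.from_region(clean_subject.ct,
                                              clean_subject.masks["L_bkg"])
        b = cal.compute_intercept(bkg)
        conc = qty.ct_to_concentration(clean_subject.ct,
                                       clean_subject.true_slope_hu_per_mg_ml, b,
                                       mask=clean_subject.masks["L"])
        act = qty.concentration_to_activity(conc, clean_subject.record)
        rc = qty.recovery_coefficient(act, clean_subject.masks["L"], 144.2e6)
        assert rc == pytest.approx(100.0, abs=1.0)


def test_microspheres_per_mg_from_mean_sphere_mass():
    assert qty.microspheres_per_mg(4.09e-5) == pytest.approx(24_450.0, rel=1e-3)
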