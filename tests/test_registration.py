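import numpy as np
import pytest

from hotspot_overlap import (
    BoundingBox,
    PhantomConfig,
    RigidTransform,
    ScalarVolume,
    VoiMask,
    generate_case,
)
from hotspot_overlap.registration import (
    apply_transform,
    dissimilarity,
    register_elastic,
    register_rigid,
)
from hotspot_overlap.transforms import rigid_discrepancy

FOCUS = BoundingBox.around((72.0, 60.0, 72.0), (40.0, 40.0, 40.0))


@pytest.fixture(scope="module")
def still_case():
    return generate_case(PhantomConfig(seed=21))


@pytest.fixture(scope="module")
def shifted_case():
    # known misalignment: 5 degrees about x, 5 mm along y
    return generate_case(PhantomConfig(rigid_error=(5, 0, 0, 0, 5, 0), seed=22))


class TestRegisterRigid:
    def test_identity_recovered_when_aligned(self, still_case):
        tfm = register_rigid(still_case.ct_a, still_case.ct_r, FOCUS)
        rot, trans = rigid_discrepancy(tfm, RigidTransform(), probe_radius_mm=40)
        assert rot < 0.1
        assert trans < 0.1

    def test_known_misalignment_recovered(self, shifted_case):
        tfm = register_rigid(shifted_case.ct_a, shifted_case.ct_r, FOCUS)
        rot, trans = rigid_discrepancy(tfm, shifted_case.true_rigid, probe_radius_mm=40)
        assert rot < 0.5
        assert trans < 0.5

    def test_noise_degrades_gracefully(self):
        case = generate_case(
            PhantomConfig(rigid_error=(5, 0, 0, 0, 5, 0), ct_noise_hu=10.0, seed=23)
        )
        tfm = register_rigid(case.ct_a, case.ct_r, FOCUS)
        rot, trans = rigid_discrepancy(tfm, case.true_rigid, probe_radius_mm=40)
        assert rot < 1.0
        assert trans < 1.0

    def test_registration_improves_similarity(self, shifted_case):
        tfm = register_rigid(shifted_case.ct_a, shifted_case.ct_r, FOCUS)
        before = dissimilarity(shifted_case.ct_a, shifted_case.ct_r, None, FOCUS)
        after = dissimilarity(shifted_case.ct_a, shifted_case.ct_r, tfm, FOCUS)
        assert after < before


class TestRegisterElastic:
    def test_nothing_to_recover_gives_small_field(self, still_case):
        field = register_elastic(still_case.ct_a, still_case.ct_r, RigidTransform())
        assert field.magnitude().max() <= 0.5

    def test_known_sinusoid_recovered_over_lesion(self):
        case = generate_case(
            PhantomConfig(
                deformation_amplitude_mm=4.0, deformation_wavelength_mm=80.0,
                position_group="NTP", seed=24,
            )
        )
        field = register_elastic(case.ct_a, case.ct_r, RigidTransform())
        err = np.linalg.norm(
            case.true_deformation.mapped_points() - field.mapped_points(), axis=-1
        )
        mean_err = err[case.true_lesion_a.mask].mean()
        unregistered = case.true_deformation.magnitude()[case.true_lesion_a.mask].mean()
        assert mean_err < 1.5
        assert mean_err < unregistered

    def test_metric_after_elastic_not_worse_than_rigid(self):
        case = generate_case(
            PhantomConfig(
                rigid_error=(0, 5, 2, 5, -3, 2), deformation_amplitude_mm=4.0,
                position_group="NTP", noise_sd=0.3, ct_noise_hu=3.0, seed=25,
            )
        )
        rigid = register_rigid(case.ct_a, case.ct_r, FOCUS)
        field = register_elastic(case.ct_a, case.ct_r, rigid)
        from hotspot_overlap.registration import _masked_dissimilarity

        body = case.ct_a.data > -200.0
        mse_rigid = _masked_dissimilarity(case.ct_a, case.ct_r, rigid, body)
        mse_elastic = _masked_dissimilarity(case.ct_a, case.ct_r, field, body)
        assert mse_elastic <= mse_rigid


class TestApplyTransform:
    def _vol(self, rng, shape=(12, 12, 10)):
        return ScalarVolume(rng.random(shape), (2, 2, 3), (0, 0, 0), "PET")

    def test_identity_bit_exact(self, rng):
        vol = self._vol(rng)
        out = apply_transform(vol, RigidTransform(), vol)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_integer_voxel_translation_is_array_shift(self, rng):
        vol = self._vol(rng)
        # map p -> p + (4, 0, 0) mm = 2 voxels along x; resampled output at
        # index i samples input at i+2
        tfm = RigidTransform(translation_mm=(4.0, 0.0, 0.0))
        out = apply_transform(vol, tfm, vol)
        np.testing.assert_allclose(out.data[:-2], vol.data[2:], atol=1e-9)
        np.testing.assert_allclose(out.data[-2:], 0.0, atol=1e-9)

    def test_mask_volume_nearly_preserved_under_rigid(self):
        case = generate_case(PhantomConfig(seed=26))
        mask = case.true_lesion_a
        tfm = RigidTransform((np.radians(4), 0, np.radians(7)), (3.3, -2.1, 4.9),
                             (64.0, 64.0, 70.0))
        warped = apply_transform(mask, tfm, case.pet_a)
        # binary warping (trilinear + 0.5 cut) keeps the volume within a few
        # per cent on fixture spheres at this grid resolution
        assert abs(warped.volume_cc - mask.volume_cc) <= 0.04 * mask.volume_cc

    def test_grid_mismatch_for_field_errors(self, rng):
        vol = self._vol(rng)
        from hotspot_overlap import DeformationField

        field = DeformationField(
            displacement=np.zeros((5, 5, 5, 3)), spacing=(2, 2, 3), origin=(0, 0, 0),
            control_spacing_mm=16.0,
        )
        with pytest.raises(ValueError, match="does not match"):
            apply_transform(vol, field, vol)

    def test_mask_warp_binarizes(self, rng):
        vol = self._vol(rng)
        mask = VoiMask(rng.random(vol.shape) < 0.5, vol.spacing, vol.origin, label="m")
        tfm = RigidTransform(translation_mm=(1.0, 0.5, 0.7))
        out = apply_transform(mask, tfm, vol)
        assert out.mask.dtype == bool
        assert out.label == "m"
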