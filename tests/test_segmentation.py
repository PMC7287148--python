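import numpy as np
import pytest

from hotspot_overlap import (
    BoundingBox,
    ScalarVolume,
    StudyConfig,
    compute_uptake_metrics,
    delineate_all,
    delineate_voi,
)
from conftest import make_core_rim_pet


class TestDelineateVoi:
    def test_homogeneous_sphere_fully_segmented(self, lesion_box):
        pet = make_core_rim_pet(suv_rim=10.0, suv_core=10.0, core_radius=1.0)
        sphere = pet.data == 10.0
        for x in (0.3, 0.5, 0.9):
            voi = delineate_voi(pet, lesion_box, x)
            np.testing.assert_array_equal(voi.mask, sphere)

    def test_core_rim_threshold_split(self, core_rim_pet, lesion_box):
        # core SUV 20, rim SUV 8: x=0.5 cuts at 10 (core only), x=0.3 at 6 (both)
        core_only = delineate_voi(core_rim_pet, lesion_box, 0.5)
        both = delineate_voi(core_rim_pet, lesion_box, 0.3)
        np.testing.assert_array_equal(core_only.mask, core_rim_pet.data == 20.0)
        np.testing.assert_array_equal(both.mask, core_rim_pet.data >= 8.0)

    def test_nested_thresholds_shrink(self, core_rim_pet, lesion_box):
        vols = [
            delineate_voi(core_rim_pet, lesion_box, x / 100).voxel_count
            for x in range(30, 100, 10)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_scale_invariance(self, core_rim_pet, lesion_box):
        ref = delineate_voi(core_rim_pet, lesion_box, 0.4)
        for factor in (0.25, 3.0, 117.0):
            scaled = ScalarVolume(
                core_rim_pet.data * factor, core_rim_pet.spacing,
                core_rim_pet.origin, "PET",
            )
            voi = delineate_voi(scaled, lesion_box, 0.4)
            np.testing.assert_array_equal(voi.mask, ref.mask)

    def test_matches_brute_force_enumeration(self, rng, lesion_box):
        # random smooth-ish uptake: single connected component around the max
        for trial in range(5):
            pet = make_core_rim_pet(
                rim_radius=rng.uniform(6, 12),
                core_radius=rng.uniform(2, 5),
                suv_rim=rng.uniform(5, 9),
                suv_core=rng.uniform(15, 25),
            )
            x = rng.uniform(0.2, 0.9)
            voi = delineate_voi(pet, lesion_box, x)
            sel = lesion_box.region_mask(pet)
            # documented contract: inclusive cut with 1e-9 relative tolerance
            expected = sel & (pet.data >= x * pet.data[sel].max() * (1 - 1e-9))
            # fixture lesions are single connected blobs: no component pruning
            np.testing.assert_array_equal(voi.mask, expected)

    def test_remote_uptake_excluded_by_connectivity(self):
        pet = make_core_rim_pet()
        data = pet.data.copy()
        data[1, 1, 1] = 15.0  # bright but disconnected physiological focus
        pet2 = ScalarVolume(data, pet.spacing, pet.origin, "PET")
        box = BoundingBox((0.0, 0.0, 0.0), (59.0, 59.0, 58.0))
        voi = delineate_voi(pet2, box, 0.5)
        assert not voi.mask[1, 1, 1]
        assert voi.mask.sum() == (pet.data == 20.0).sum()

    def test_all_zero_region_errors(self):
        pet = ScalarVolume(np.zeros((10, 10, 10)), (2, 2, 2), (0, 0, 0), "PET")
        with pytest.raises(ValueError, match="no positive SUV"):
            delineate_voi(pet, BoundingBox((0, 0, 0), (18, 18, 18)), 0.4)

    def test_tie_break_deterministic(self):
        data = np.zeros((8, 8, 8))
        data[2, 2, 2] = data[5, 5, 5] = 10.0  # two disconnected SUVmax voxels
        pet = ScalarVolume(data, (2, 2, 2), (0, 0, 0), "PET")
        box = BoundingBox((0, 0, 0), (14, 14, 14))
        voi = delineate_voi(pet, box, 0.5)
        assert voi.mask[2, 2, 2] and not voi.mask[5, 5, 5]


class TestDelineateAll:
    def test_default_yields_nine_masks(self, core_rim_pet, lesion_box):
        study = StudyConfig()
        masks = delineate_all(core_rim_pet, core_rim_pet, lesion_box, lesion_box, study)
        assert len(masks) == 9
        assert sorted(masks) == [
            "A_30", "A_40", "A_50", "A_60", "A_70", "A_80", "A_90", "R_40", "R_70",
        ]

    def test_custom_threshold_count(self, core_rim_pet, lesion_box):
        study = StudyConfig(baseline_thresholds=(30, 50, 70))
        masks = delineate_all(core_rim_pet, core_rim_pet, lesion_box, lesion_box, study)
        assert len(masks) == 5


class TestUptakeMetrics:
    def test_homogeneous_lesion_formulas(self):
        # 2.0 cc sphere at SUV 5: suv_mean = suv_max = 5, tlg = 10 g
        pet = make_core_rim_pet(
            shape=(40, 40, 40), spacing=(1.0, 1.0, 1.0), center=(20, 20, 20),
            rim_radius=7.816, core_radius=1.0, suv_rim=5.0, suv_core=5.0,
        )
        n_vox = int((pet.data == 5.0).sum())
        box = BoundingBox((5, 5, 5), (35, 35, 35))
        m = compute_uptake_metrics(pet, box)
        assert m.suv_max == 5.0
        assert m.suv_mean == 5.0
        assert m.mtv_cc == pytest.approx(n_vox / 1000.0)
        assert m.mtv_cc == pytest.approx(2.0, rel=0.02)  # raster ~ analytic
        assert m.tlg_g == pytest.approx(5.0 * m.mtv_cc)

    def test_mtv_equals_brute_force_a40_volume(self, core_rim_pet, lesion_box):
        m = compute_uptake_metrics(core_rim_pet, lesion_box)
        sel = lesion_box.region_mask(core_rim_pet)
        cut = 0.4 * core_rim_pet.data[sel].max() * (1 - 1e-9)
        expected_vox = int((core_rim_pet.data[sel] >= cut).sum())
        assert m.mtv_cc == pytest.approx(expected_vox * 12.0 / 1000.0)

    def test_tlg_definitional(self, rng, lesion_box):
        for _ in range(3):
            pet = make_core_rim_pet(suv_rim=rng.uniform(4, 9), suv_core=rng.uniform(12, 25))
            m = compute_uptake_metrics(pet, lesion_box)
            assert m.tlg_g == m.suv_mean * m.mtv_cc
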