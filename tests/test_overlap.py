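import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hotspot_overlap import VoiMask, classify_agreement, compute_overlap, overlap_matrix
from hotspot_overlap.overlap import INDEX_NAMES
from conftest import random_mask


def mask_from_flags(flags, shape=(4, 4, 4), label="m"):
    arr = np.zeros(shape, dtype=bool)
    arr.flat[: len(flags)] = flags
    return VoiMask(arr, (2, 2, 3), (0, 0, 0), label=label)


class TestComputeOverlap:
    def test_identical_masks_all_ones(self, rng):
        m = random_mask(rng, label="A_40")
        m2 = VoiMask(m.mask.copy(), m.spacing, m.origin, label="R_40")
        res = compute_overlap(m, m2)
        assert all(v == 1.0 for v in res.indices().values())

    def test_disjoint_masks_all_zeros(self):
        a = mask_from_flags([1, 1, 0, 0], label="A_40")
        b = mask_from_flags([0, 0, 1, 1], label="R_40")
        res = compute_overlap(a, b)
        assert all(v == 0.0 for v in res.indices().values())

    def test_hand_computed_example(self):
        # |A| = 8, |R| = 4, |A n R| = 2 on a 4x4x4 grid
        a = np.zeros(64, dtype=bool)
        r = np.zeros(64, dtype=bool)
        a[:8] = True
        r[6:10] = True
        res = compute_overlap(
            mask_from_flags(a, label="A_40"), mask_from_flags(r, label="R_40")
        )
        assert res.dice == pytest.approx(1 / 3)
        assert res.jaccard == pytest.approx(0.2)
        assert res.common_over_a == pytest.approx(0.25)
        assert res.common_over_r == pytest.approx(0.5)
        assert res.of == pytest.approx(0.5)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(25):
            a = random_mask(rng, p=rng.uniform(0.2, 0.7), label="A")
            b = random_mask(rng, p=rng.uniform(0.2, 0.7), label="R")
            if a.voxel_count == 0 and b.voxel_count == 0:
                continue
            res = compute_overlap(a, b)
            sa = set(map(tuple, np.argwhere(a.mask)))
            sb = set(map(tuple, np.argwhere(b.mask)))
            inter, union = len(sa & sb), len(sa | sb)
            assert res.dice == pytest.approx(
                2 * inter / (len(sa) + len(sb)) if sa or sb else 0
            )
            assert res.jaccard == pytest.approx(inter / union if union else 0)
            if sa and sb:
                assert res.of == pytest.approx(inter / min(len(sa), len(sb)))
                assert res.common_over_a == pytest.approx(inter / len(sa))
                assert res.common_over_r == pytest.approx(inter / len(sb))
            # algebraic identities
            assert res.dice == pytest.approx(2 * res.jaccard / (1 + res.jaccard), abs=1e-12)
            assert res.of == pytest.approx(max(res.common_over_a, res.common_over_r), abs=1e-12)

    def test_symmetry_under_swap(self, rng):
        a = random_mask(rng, label="A_40")
        b = random_mask(rng, label="R_40")
        ab = compute_overlap(a, b)
        ba = compute_overlap(b, a)
        assert ab.dice == ba.dice
        assert ab.jaccard == ba.jaccard
        assert ab.of == ba.of
        assert ab.common_over_a == ba.common_over_r
        assert ab.common_over_r == ba.common_over_a

    def test_empty_mask_ratio_warns_and_is_zero(self):
        a = mask_from_flags([0, 0, 0, 0], label="A_90")
        b = mask_from_flags([1, 1, 0, 0], label="R_40")
        with pytest.warns(UserWarning, match="empty denominator"):
            res = compute_overlap(a, b)
        assert res.common_over_a == 0.0
        assert res.dice == 0.0

    def test_both_empty_errors(self):
        a = mask_from_flags([0], label="A")
        b = mask_from_flags([0], label="R")
        with pytest.raises(ValueError, match="both masks empty"):
            compute_overlap(a, b)

    def test_grid_mismatch_errors(self):
        a = mask_from_flags([1], label="A")
        b = VoiMask(np.ones((4, 4, 4), dtype=bool), (1, 1, 1), (0, 0, 0), label="R")
        with pytest.raises(ValueError, match="different grids"):
            compute_overlap(a, b)


class TestOverlapMatrix:
    def _masks(self, rng, labels):
        return {
            lbl: random_mask(rng, p=0.5, label=lbl) for lbl in labels
        }

    def test_default_grid_gives_140_index_values(self, rng):
        a = self._masks(rng, [f"A_{x}" for x in range(30, 100, 10)])
        r = self._masks(rng, ["R_40", "R_70"])
        per_method = overlap_matrix("c1", "TP", "RR", a, r)
        assert len(per_method) == 7 * 2
        n_values = 2 * len(per_method) * len(INDEX_NAMES)  # both methods
        assert n_values == 140

    def test_single_pair_gives_five_values(self, rng):
        res = overlap_matrix("c", "TP", "RR", self._masks(rng, ["A_40"]), self._masks(rng, ["R_40"]))
        assert len(res) == 1
        assert len(res[0].indices()) == 5

    def test_results_ordered_by_threshold(self, rng):
        a = self._masks(rng, ["A_90", "A_30", "A_40"])
        r = self._masks(rng, ["R_70", "R_40"])
        res = overlap_matrix("c", "TP", "ER", a, r)
        assert [x.a_label for x in res] == ["A_30", "A_30", "A_40", "A_40", "A_90", "A_90"]
        assert [x.r_label for x in res[:2]] == ["R_40", "R_70"]


class TestClassifyAgreement:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.0, "poor"),
            (0.2, "poor"),
            (0.21, "fair"),
            (0.38, "fair"),
            (0.41, "moderate"),
            (0.60, "moderate"),
            (0.64, "good"),
            (0.80, "good"),
            (0.81, "very good"),
            (1.0, "very good"),
        ],
    )
    def test_banding(self, value, band):
        assert classify_agreement(value) == band

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            classify_agreement(1.2)
        with pytest.raises(ValueError):
            classify_agreement(-0.1)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_total_partition(self, value):
        assert classify_agreement(value) in {"poor", "fair", "moderate", "good", "very good"}
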