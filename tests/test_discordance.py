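"""Multi-class Dice discordance statistic and its aggregations."""

import warnings

import numpy as np
import pytest

from crowdseg import (
    LabelMask,
    Participant,
    VacuousDiscordanceWarning,
    correction_discordance,
    dice_discordance,
    disagreement_map,
    pairwise_discordance,
    per_class_discordance,
)
from crowdseg.discordance import DiscordanceMatrix, dice_counts

from conftest import random_mask
import _oracles

ALL4 = ["tumor", "stroma", "lymphocytic_infiltrate", "necrosis"]


def mask_of(taxonomy, labels) -> LabelMask:
    return LabelMask(np.asarray(labels, dtype=np.int64), taxonomy)


class TestDiceDiscordance:
    def test_identical_masks_have_zero_discordance(self, taxonomy):
        m = random_mask(np.random.default_rng(1), taxonomy)
        assert dice_discordance(m, m, ALL4) == 0.0

    def test_disjoint_support_is_one(self, small_taxonomy):
        I = mask_of(small_taxonomy, np.full((4, 4), 1))  # all tumor
        J = mask_of(small_taxonomy, np.full((4, 4), 4))  # all necrosis
        assert dice_discordance(I, J, ["tumor", "necrosis"]) == 1.0

    def test_worked_two_class_example(self, small_taxonomy):
        # I: 8 tumor + 8 stroma; J: two tumor pixels flipped to stroma
        I = np.full((4, 4), 2)
        I[:2] = 1
        J = I.copy()
        J[0, :2] = 2
        value = dice_discordance(mask_of(small_taxonomy, I), mask_of(small_taxonomy, J),
                                 ["tumor", "stroma"])
        assert value == pytest.approx(1 - 2 * (6 + 8) / (8 + 6 + 8 + 10), abs=1e-12)
        assert value == pytest.approx(0.125, abs=1e-12)

    def test_symmetry_and_range_on_random_pairs(self, taxonomy):
        rng = np.random.default_rng(2)
        for _ in range(50):
            I = random_mask(rng, taxonomy)
            J = random_mask(rng, taxonomy)
            d_ij = dice_discordance(I, J, ALL4)
            assert d_ij == dice_discordance(J, I, ALL4)
            assert 0.0 <= d_ij <= 1.0

    def test_matches_counting_oracle(self, taxonomy):
        rng = np.random.default_rng(3)
        codes = [taxonomy.code(c) for c in ALL4]
        for _ in range(25):
            I = random_mask(rng, taxonomy)
            J = random_mask(rng, taxonomy)
            expected = _oracles.dice_discordance_oracle(I.labels, J.labels, codes)
            assert dice_discordance(I, J, ALL4) == pytest.approx(expected, abs=1e-12)

    def test_vacuous_channels_warn_and_return_zero(self, small_taxonomy):
        I = mask_of(small_taxonomy, np.full((4, 4), 2))
        with pytest.warns(VacuousDiscordanceWarning):
            assert dice_discordance(I, I, ["necrosis"]) == 0.0

    def test_label_zero_pixels_excluded(self, small_taxonomy):
        I = np.full((4, 4), 1)
        J = np.full((4, 4), 1)
        J[0] = 4  # disagreement confined to a region that is outside ROI in I
        I2 = I.copy()
        I2[0] = 0
        assert dice_discordance(mask_of(small_taxonomy, I2), mask_of(small_taxonomy, J),
                                ["tumor", "necrosis"]) == 0.0

    def test_shape_mismatch_errors(self, small_taxonomy):
        I = mask_of(small_taxonomy, np.full((4, 4), 1))
        J = mask_of(small_taxonomy, np.full((5, 4), 1))
        with pytest.raises(ValueError, match="shapes differ"):
            dice_discordance(I, J, ["tumor"])


class TestPerClassDiscordance:
    def test_absent_from_both_is_vacuous_zero(self, small_taxonomy):
        I = mask_of(small_taxonomy, np.full((4, 4), 2))
        with pytest.warns(VacuousDiscordanceWarning):
            assert per_class_discordance(I, I, "necrosis") == 0.0

    def test_present_in_exactly_one_is_one(self, small_taxonomy):
        I = mask_of(small_taxonomy, np.full((4, 4), 2))
        J = np.full((4, 4), 2)
        J[1, 1] = 4
        assert per_class_discordance(I, mask_of(small_taxonomy, J), "necrosis") == 1.0

    def test_equals_one_minus_sorensen_dice_similarity(self, taxonomy):
        # independent similarity route: sklearn's F1 on binary channels is Dice
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(4)
        for _ in range(20):
            I = random_mask(rng, taxonomy)
            J = random_mask(rng, taxonomy)
            a = I.channel("tumor").ravel()
            b = J.channel("tumor").ravel()
            if not (a.any() or b.any()):
                continue
            assert per_class_discordance(I, J, "tumor") == pytest.approx(
                1.0 - f1_score(a, b, zero_division=0), abs=1e-12)


class TestPairwiseDiscordance:
    def _masks(self, taxonomy, n_participants, n_rois, seed=0):
        rng = np.random.default_rng(seed)
        tiers = ["SP", "NP"]
        return {
            Participant(f"p{i:02d}", tiers[i % 2]): [
                random_mask(rng, taxonomy) for _ in range(n_rois)
            ]
            for i in range(n_participants)
        }

    def test_identical_masks_give_zero_matrix(self, taxonomy):
        shared = [random_mask(np.random.default_rng(0), taxonomy) for _ in range(2)]
        masks = {Participant(f"p{i}", "NP"): list(shared) for i in range(4)}
        m = pairwise_discordance(masks, ALL4, "pooled")
        assert (m.values == 0).all()

    @pytest.mark.parametrize("aggregation", ["pooled", "per_roi_median"])
    def test_matrix_equals_direct_evaluation(self, taxonomy, aggregation):
        masks = self._masks(taxonomy, 3, 2, seed=5)
        m = pairwise_discordance(masks, ALL4, aggregation)
        parts = m.participants
        codes = [taxonomy.code(c) for c in ALL4]
        for a in range(3):
            for b in range(a + 1, 3):
                ma, mb = masks[parts[a]], masks[parts[b]]
                if aggregation == "pooled":
                    # pooled ratio == statistic on the concatenated masks
                    cat_a = np.concatenate([x.labels for x in ma], axis=1)
                    cat_b = np.concatenate([x.labels for x in mb], axis=1)
                    expected = _oracles.dice_discordance_oracle(cat_a, cat_b, codes)
                else:
                    expected = float(np.median([
                        _oracles.dice_discordance_oracle(x.labels, y.labels, codes)
                        for x, y in zip(ma, mb)
                    ]))
                assert m.values[a, b] == pytest.approx(expected, abs=1e-12)

    def test_25_participants_give_300_unique_pairs(self, taxonomy):
        masks = self._masks(taxonomy, 25, 1)
        m = pairwise_discordance(masks, ALL4)
        assert m.n_unique_pairs() == 300
        assert len(list(m.unique_pairs())) == 300

    def test_differing_roi_counts_error(self, taxonomy):
        masks = self._masks(taxonomy, 2, 2)
        masks[Participant("p99", "NP")] = [random_mask(np.random.default_rng(9), taxonomy)]
        with pytest.raises(ValueError, match="differing ROI counts"):
            pairwise_discordance(masks, ALL4)

    def test_matrix_invariants_enforced(self, taxonomy):
        parts = tuple(Participant(f"p{i}", "NP") for i in range(2))
        with pytest.raises(ValueError, match="symmetric"):
            DiscordanceMatrix(parts, np.array([[0, 0.2], [0.4, 0]]), ("tumor",), "pooled")
        with pytest.raises(ValueError, match="zero diagonal"):
            DiscordanceMatrix(parts, np.array([[0.1, 0.2], [0.2, 0]]), ("tumor",), "pooled")


class TestCorrectionDiscordance:
    def test_no_corrections_is_zero(self, taxonomy):
        m = random_mask(np.random.default_rng(0), taxonomy)
        assert correction_discordance(m, m, ALL4) == 0.0

    def test_closed_form_for_k_relabeled_pixels(self, small_taxonomy):
        # n tumor pixels, k flipped to necrosis: channels tumor and necrosis change
        n, k = 12, 5
        pre = np.full((4, 4), 2)
        pre.ravel()[:n] = 1
        post = pre.copy()
        post.ravel()[:k] = 4
        value = correction_discordance(mask_of(small_taxonomy, pre),
                                       mask_of(small_taxonomy, post), ["tumor", "necrosis"])
        # intersection n-k of sizes n + (n-k) + 0 + k
        assert value == pytest.approx(1 - 2 * (n - k) / (2 * n), abs=1e-12)

    def test_untouched_class_subset_monotonicity(self, small_taxonomy):
        # corrections touching only non-tumor classes: tumor-only <= all-class
        pre = np.full((6, 6), 2)
        pre[:2] = 1
        post = pre.copy()
        post[4:, 4:] = 4  # stroma -> necrosis, tumor untouched
        pre_m, post_m = mask_of(small_taxonomy, pre), mask_of(small_taxonomy, post)
        assert (correction_discordance(pre_m, post_m, ["tumor"])
                <= correction_discordance(pre_m, post_m, ALL4))


class TestDisagreementMap:
    def test_identical_groups_all_zero(self, taxonomy):
        m = random_mask(np.random.default_rng(0), taxonomy)
        dmap = disagreement_map([m, m.copy()], [m.copy(), m.copy()])
        assert (dmap.values == 0).all()

    def test_single_pixel_disagreement_localized(self, small_taxonomy):
        a = np.full((4, 4), 1)
        b = a.copy()
        b[2, 3] = 4
        dmap = disagreement_map([mask_of(small_taxonomy, a)], [mask_of(small_taxonomy, b)])
        assert dmap.values[2, 3] == 1.0
        assert dmap.values.sum() == 1.0

    def test_matches_double_loop_oracle(self, taxonomy):
        rng = np.random.default_rng(6)
        ga = [random_mask(rng, taxonomy, (8, 8)) for _ in range(3)]
        gb = [random_mask(rng, taxonomy, (8, 8)) for _ in range(2)]
        dmap = disagreement_map(ga, gb)
        expected = np.zeros((8, 8))
        for I in ga:
            for J in gb:
                expected += I.labels != J.labels
        np.testing.assert_allclose(dmap.values, expected / 6)

    def test_boundary_erosion_disagrees_only_on_boundary(self, small_taxonomy):
        from scipy.ndimage import binary_erosion

        labels = np.full((16, 16), 2)
        labels[4:12, 4:12] = 1
        eroded = labels.copy()
        shrunk = binary_erosion(labels == 1)
        eroded[(labels == 1) & ~shrunk] = 2
        dmap = disagreement_map([mask_of(small_taxonomy, labels)],
                                [mask_of(small_taxonomy, eroded)])
        boundary = (labels == 1) & ~shrunk
        assert (dmap.values[boundary] == 1).all()
        assert (dmap.values[~boundary] == 0).all()

    def test_empty_group_errors(self, taxonomy):
        m = random_mask(np.random.default_rng(0), taxonomy)
        with pytest.raises(ValueError, match="non-empty"):
            disagreement_map([], [m])
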