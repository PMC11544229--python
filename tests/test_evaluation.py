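"""Segmentation matching metrics, classification metrics and statistics."""

import numpy as np
import pytest
from scipy import stats

import myorecovery as mr


# exhaustive oracles shared with the acceptance suite
from tests_oracles import oracle_max_matching as _oracle_max_matching
from tests_oracles import oracle_mean_iou as _oracle_mean_iou
from tests_oracles import random_label_mask as _random_label_mask


class TestIoU:
    def test_identity(self):
        a = np.zeros((5, 5), dtype=bool)
        a[1:3, 1:3] = True
        assert mr.iou(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((5, 5), dtype=bool)
        b = np.zeros((5, 5), dtype=bool)
        a[0, 0] = True
        b[4, 4] = True
        assert mr.iou(a, b) == 0.0

    def test_shifted_square(self):
        a = np.zeros((4, 5), dtype=bool)
        b = np.zeros((4, 5), dtype=bool)
        a[1:3, 1:3] = True
        b[1:3, 2:4] = True  # shifted one column
        assert mr.iou(a, b) == pytest.approx(2 / 6)

    def test_both_empty_errors(self):
        empty = np.zeros((3, 3), dtype=bool)
        with pytest.raises(ValueError):
            mr.iou(empty, empty)


class TestMeanIoU:
    def test_perfect_predictions(self, small_phantom):
        assert mr.mean_iou(small_phantom.gt_mask, small_phantom.gt_mask) == 1.0

    def test_no_predictions(self):
        gt = np.zeros((8, 8), dtype=int)
        gt[2:4, 2:4] = 1
        assert mr.mean_iou(gt, np.zeros_like(gt)) == 0.0

    def test_empty_ground_truth_errors(self):
        with pytest.raises(ValueError):
            mr.mean_iou(np.zeros((4, 4), dtype=int), np.zeros((4, 4), dtype=int))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            gt = _random_label_mask(rng)
            pred = _random_label_mask(rng)
            if not (gt > 0).any():
                continue
            assert mr.mean_iou(gt, pred) == pytest.approx(_oracle_mean_iou(gt, pred))


class TestF1AtThreshold:
    def test_perfect_predictions(self, small_phantom):
        p, r, f1, match = mr.f1_at_threshold(small_phantom.gt_mask,
                                             small_phantom.gt_mask, 0.7)
        assert (p, r, f1) == (1.0, 1.0, 1.0)
        assert match.fp == match.fn == 0

    def test_zero_predictions(self):
        gt = np.zeros((8, 8), dtype=int)
        gt[2:4, 2:4] = 1
        p, r, f1, match = mr.f1_at_threshold(gt, np.zeros_like(gt), 0.7)
        assert r == 0.0 and f1 == 0.0 and match.fn == 1

    def test_matching_is_one_to_one(self, rng):
        for _ in range(50):
            gt = _random_label_mask(rng)
            pred = _random_label_mask(rng)
            _, _, _, match = mr.f1_at_threshold(gt, pred, 0.5)
            gids = [g for g, _, _ in match.pairs]
            pids = [p for _, p, _ in match.pairs]
            assert len(gids) == len(set(gids)) and len(pids) == len(set(pids))

    def test_matches_maximum_matching_oracle(self, rng):
        for _ in range(100):
            gt = _random_label_mask(rng, max_objects=3)
            pred = _random_label_mask(rng, max_objects=3)
            _, _, _, match = mr.f1_at_threshold(gt, pred, 0.7)
            assert match.tp == _oracle_max_matching(gt, pred, 0.7)

    def test_monotone_nonincreasing_in_tau(self, rng):
        gt = _random_label_mask(rng)
        pred = _random_label_mask(rng)
        f1s = [mr.f1_at_threshold(gt, pred, t)[2] for t in (0.5, 0.6, 0.7, 0.8, 0.9)]
        assert all(a >= b for a, b in zip(f1s, f1s[1:]))

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            mr.f1_at_threshold(np.ones((2, 2), dtype=int),
                               np.ones((2, 2), dtype=int), 0.0)


class TestConfusionAndPRF:
    def test_all_correct(self):
        t = [0, 1, 2, 3, 0, 1]
        matrix, prf = mr.confusion_and_prf(t, t, K=4)
        assert (np.diag(matrix) == [2, 2, 1, 1]).all()
        assert (prf["f1"] == 1.0).all()

    def test_all_predicted_class_zero(self):
        t = [0, 1, 2, 3] * 5
        p = [0] * 20
        matrix, prf = mr.confusion_and_prf(t, p, K=4)
        assert prf.loc[0, "recall"] == 1.0
        assert prf.loc[0, "precision"] == 0.25
        assert (prf.loc[1:, "f1"] == 0.0).all()

    def test_sentinel_cells_excluded(self):
        t = [0, 1, -1, -1]
        p = [0, 1, 2, 3]
        matrix, _ = mr.confusion_and_prf(t, p, K=4, sentinel=-1)
        assert matrix.sum() == 2

    def test_recall_is_diagonal_over_row_sum(self, rng):
        t = rng.integers(0, 4, size=200)
        p = rng.integers(0, 4, size=200)
        matrix, prf = mr.confusion_and_prf(t, p, K=4)
        for k in range(4):
            expected = matrix[k, k] / matrix[k].sum() if matrix[k].sum() else 0.0
            assert prf.loc[k, "recall"] == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mr.confusion_and_prf([0, 1], [0], K=4)


class TestKLEval:
    def test_identical_pairs_all_zero(self):
        props = [np.array([0.4, 0.3, 0.2, 0.1])] * 3
        vals, mean = mr.kl_eval(props, props)
        np.testing.assert_allclose(vals, 0.0, atol=1e-7)
        assert mean == pytest.approx(0.0, abs=1e-7)

    def test_single_pair_ln2(self):
        vals, mean = mr.kl_eval([[1, 0, 0, 0]], [[0.5, 0.5, 0, 0]])
        assert mean == pytest.approx(np.log(2), abs=1e-6)

    def test_mean_is_arithmetic_mean(self, rng):
        t = [rng.dirichlet(np.ones(4)) for _ in range(5)]
        p = [rng.dirichlet(np.ones(4)) for _ in range(5)]
        vals, mean = mr.kl_eval(t, p)
        assert mean == pytest.approx(np.mean(vals))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mr.kl_eval([[1, 0]], [])


class TestMannWhitneyU:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        u, p = mr.mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p > 0.9

    def test_complete_separation_small_p(self, rng):
        x = rng.normal(10, 1, size=20)
        y = rng.normal(0, 1, size=20)
        _, p = mr.mann_whitney_u(x, y)
        assert p < 0.001

    def test_u_complementarity(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=12)
        ux, _ = mr.mann_whitney_u(x, y)
        uy, _ = mr.mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(15 * 12)

    def test_agrees_with_exact_tail_at_small_n(self, rng):
        x = rng.normal(1.0, 1, size=8)
        y = rng.normal(0.0, 1, size=7)
        _, p_asym = mr.mann_whitney_u(x, y)
        p_exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
        assert p_asym == pytest.approx(p_exact, abs=0.05)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mr.mann_whitney_u([], [1.0])


class TestCliffsDelta:
    def test_enumerated_example(self):
        # pairs of (1,2,3) vs (2,3,4): 1 greater, 6 less -> (1-6)/9
        eff = mr.cliffs_delta([1, 2, 3], [2, 3, 4])
        assert eff.delta == pytest.approx(-5 / 9)

    def test_complete_dominance(self):
        eff = mr.cliffs_delta([10, 11, 12], [1, 2, 3])
        assert eff.delta == 1.0

    def test_identical_samples_zero(self):
        eff = mr.cliffs_delta([1, 2, 3], [1, 2, 3])
        assert eff.delta == 0.0

    def test_antisymmetry_and_range(self, rng):
        for _ in range(200):
            x = rng.normal(size=rng.integers(2, 15))
            y = rng.normal(size=rng.integers(2, 15))
            a = mr.cliffs_delta(x, y)
            b = mr.cliffs_delta(y, x)
            assert a.delta == pytest.approx(-b.delta)
            assert -1.0 <= a.delta <= 1.0
            assert a.ci_low <= a.delta <= a.ci_high

    def test_magnitude_bands(self):
        assert mr.cliffs_delta([10, 11], [1, 2]).magnitude == "large"
        assert mr.cliffs_delta([1, 2, 3], [1, 2, 3]).magnitude == "small-or-negligible"

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mr.cliffs_delta([], [1.0])
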