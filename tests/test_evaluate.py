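"""Metric oracles, stratification, grouped CV, confidence intervals."""

import numpy as np
import pytest
from scipy import ndimage, stats

from hepanomaly.core import EvalRecord
from oracles import brute_auroc, brute_dice, brute_hd95, brute_iou
from hepanomaly.evaluate import (dice, fold_ci, grouped_kfold, hd95, iou,
                                 pixel_auroc, stratify_by_size)


def _rand_mask(rng, shape=(12, 12), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)


class TestOverlapMetrics:
    def test_hand_examples(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, :4] = 1  # |P| = 4
        b = np.zeros((4, 4), dtype=np.uint8)
        b[0, :2] = 1  # |T| = 2, overlap 2
        assert dice(a, b) == pytest.approx(2 * 2 / 6)
        assert iou(a, a) == 1.0
        assert dice(a, a) == 1.0
        c = np.zeros((4, 4), dtype=np.uint8)
        c[3, :] = 1
        assert dice(a, c) == 0.0 and iou(a, c) == 0.0

    def test_iou_hand_example(self):
        p = np.zeros((3, 3), dtype=np.uint8)
        p[0] = 1
        t = np.zeros((3, 3), dtype=np.uint8)
        t[:, 0] = 1  # inter {0,0}; |P∪T| ... constructed below instead
        p2 = np.array([[1, 1, 0]], dtype=np.uint8)
        t2 = np.array([[0, 1, 1]], dtype=np.uint8)
        assert iou(np.pad(p2, ((0, 0), (0, 1))), np.pad(t2, ((0, 0), (0, 1)))) == \
            pytest.approx(1 / 3)

    def test_scope_restricts_computation(self, rng):
        pred, truth = _rand_mask(rng), _rand_mask(rng)
        scope = np.zeros((12, 12), dtype=np.uint8)
        scope[:6] = 1
        d1 = dice(pred, truth, scope)
        pred2 = pred.copy()
        pred2[6:] = 1 - pred2[6:]  # flip everything outside scope
        assert dice(pred2, truth, scope) == d1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            pred, truth = _rand_mask(rng, (8, 8)), _rand_mask(rng, (8, 8))
            assert dice(pred, truth) == brute_dice(pred, truth)
            assert iou(pred, truth) == brute_iou(pred, truth)

    def test_dice_iou_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            pred, truth = _rand_mask(rng, (10, 10)), _rand_mask(rng, (10, 10))
            u = iou(pred, truth)
            assert dice(pred, truth) == pytest.approx(2 * u / (1 + u))


class TestHD95:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:5, 2:5] = 1
        assert hd95(m, m) == 0.0

    def test_two_single_pixels_five_apart(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[1, 1] = 1
        b[1, 6] = 1
        assert hd95(a, b) == pytest.approx(5.0)

    def test_empty_mask_flagged_undefined(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        n = m.copy()
        n[1, 1] = 1
        assert np.isnan(hd95(m, n))
        assert np.isnan(hd95(n, m))

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 100:
            pred = ndimage.binary_dilation(_rand_mask(rng, (16, 16), 0.05)).astype(np.uint8)
            truth = ndimage.binary_dilation(_rand_mask(rng, (16, 16), 0.05)).astype(np.uint8)
            if pred.sum() == 0 or truth.sum() == 0:
                continue
            assert hd95(pred, truth) == pytest.approx(brute_hd95(pred, truth), abs=1e-9)
            checked += 1


class TestAUROC:
    def test_perfect_separation(self):
        scope = np.ones((2, 3), dtype=np.uint8)
        truth = np.array([[1, 1, 0], [0, 0, 0]], dtype=np.uint8)
        scores = np.array([[0.9, 0.8, 0.1], [0.2, 0.3, 0.0]])
        assert pixel_auroc(scores, truth, scope) == 1.0

    def test_constant_scores_give_half(self):
        scope = np.ones((2, 3), dtype=np.uint8)
        truth = np.array([[1, 0, 0], [1, 0, 0]], dtype=np.uint8)
        assert pixel_auroc(np.zeros((2, 3)), truth, scope) == pytest.approx(0.5)

    def test_six_pixel_case_matches_pair_counting(self):
        scores = np.array([[0.1, 0.5, 0.5], [0.9, 0.3, 0.7]])
        truth = np.array([[0, 1, 0], [1, 0, 1]], dtype=np.uint8)
        scope = np.ones((2, 3), dtype=np.uint8)
        expected = brute_auroc(scores.ravel(), truth.ravel().astype(bool))
        assert pixel_auroc(scores, truth, scope) == pytest.approx(expected, abs=1e-12)

    def test_single_class_scope_undefined(self):
        scope = np.ones((2, 2), dtype=np.uint8)
        assert np.isnan(pixel_auroc(np.zeros((2, 2)), np.zeros((2, 2), dtype=np.uint8), scope))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 1).reshape(1, -1)
            truth = (rng.random(n) < 0.4).astype(np.uint8).reshape(1, -1)
            scope = np.ones_like(truth)
            if truth.all() or not truth.any():
                continue
            expected = brute_auroc(scores.ravel(), truth.ravel().astype(bool))
            assert pixel_auroc(scores, truth, scope) == pytest.approx(expected, abs=1e-9)


def _records(areas, **kw):
    return [EvalRecord(subject_id=kw.get("sid", f"P{i}"), slice_index=i, dice=0.5,
                       iou=0.33, hd95=1.0, auroc=0.9, tumor_area=a)
            for i, a in enumerate(areas)]


class TestStratify:
    def test_eight_records_quartile_by_hand(self):
        strata = stratify_by_size(_records([1, 2, 3, 4, 5, 6, 7, 8]))
        assert [s.n for s in strata] == [2, 2, 2, 2]
        assert strata[0].area_range == (1, 2)
        assert strata[3].area_range == (7, 8)

    def test_identical_areas_flagged_degenerate(self):
        strata = stratify_by_size(_records([5] * 8))
        assert all(s.degenerate for s in strata)

    def test_counts_sum_and_minimum_size(self):
        recs = _records(list(range(13)))
        assert sum(s.n for s in stratify_by_size(recs)) == 13
        with pytest.raises(ValueError):
            stratify_by_size(recs[:3])


class TestGroupedKFold:
    def _cohort(self, rng, n_subjects, max_slices=6):
        recs = []
        for s in range(n_subjects):
            for i in range(int(rng.integers(1, max_slices))):
                recs.append(EvalRecord(subject_id=f"P{s:03d}", slice_index=i,
                                       dice=0, iou=0, hd95=0, auroc=0, tumor_area=1))
        return recs

    def test_ten_subjects_five_folds_two_each(self, rng):
        recs = self._cohort(rng, 10)
        assign = grouped_kfold(recs, K=5, seed=0)
        counts = np.bincount(list(assign.values()), minlength=5)
        assert (counts == 2).all()

    def test_no_subject_spans_folds_and_partition(self, rng):
        recs = self._cohort(rng, 7)
        assign = grouped_kfold(recs, K=3, seed=1)
        fold_of = [assign[r.subject_id] for r in recs]
        assert len(assign) == 7
        by_subject = {}
        for r, f in zip(recs, fold_of):
            by_subject.setdefault(r.subject_id, set()).add(f)
        assert all(len(v) == 1 for v in by_subject.values())

    def test_balanced_over_many_random_cohorts(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            n = int(rng.integers(5, 25))
            recs = self._cohort(rng, n)
            assign = grouped_kfold(recs, K=5, seed=trial)
            counts = np.bincount(list(assign.values()), minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            grouped_kfold(self._cohort(rng, 3), K=5)

    def test_deterministic_for_seed(self, rng):
        recs = self._cohort(rng, 12)
        assert grouped_kfold(recs, K=5, seed=3) == grouped_kfold(recs, K=5, seed=3)


class TestFoldCI:
    def test_identical_values_zero_width(self):
        mean, half = fold_ci([0.5, 0.5, 0.5])
        assert mean == 0.5 and half == 0.0

    def test_two_fold_closed_form(self):
        mean, half = fold_ci([0.0, 1.0])
        t_crit = stats.t.ppf(0.975, 1)
        assert mean == 0.5
        assert half == pytest.approx(t_crit * np.std([0, 1], ddof=1) / np.sqrt(2))
        assert half == pytest.approx(6.353, abs=1e-3)

    def test_interval_contains_mean_and_needs_two(self):
        mean, half = fold_ci([0.2, 0.4, 0.9])
        assert mean - half <= mean <= mean + half
        with pytest.raises(ValueError):
            fold_ci([0.5])
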