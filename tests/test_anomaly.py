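"""Anomaly maps, post-processing steps, F1-optimal thresholding."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk

from oracles import brute_f1_threshold
from hepanomaly.anomaly import (PostprocessParams, base_map, binarize,
                                f1_optimal_threshold, postprocess, score_slice)
from hepanomaly.core import SlicePairRecord


class TestBaseMap:
    def test_zero_when_equal_and_symmetric(self, rng):
        a = rng.standard_normal((6, 6))
        b = rng.standard_normal((6, 6))
        m = np.ones((6, 6), dtype=np.uint8)
        assert np.all(base_map(a, a, m) == 0)
        np.testing.assert_array_equal(base_map(a, b, m), base_map(b, a, m))

    def test_three_by_three_hand_case(self):
        orig = np.arange(9, dtype=float).reshape(3, 3)
        recon = np.zeros((3, 3))
        mask = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]], dtype=np.uint8)
        out = base_map(orig, recon, mask)
        expected = np.array([[0, 1, 0], [3, 4, 0], [0, 0, 0]], dtype=float)
        np.testing.assert_array_equal(out, expected)

    def test_out_of_mask_perturbation_invariance(self, rng):
        orig = rng.standard_normal((8, 8))
        recon = rng.standard_normal((8, 8))
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        ref = base_map(orig, recon, mask)
        orig2, recon2 = orig.copy(), recon.copy()
        orig2[mask == 0] += 100
        recon2[mask == 0] -= 50
        np.testing.assert_array_equal(base_map(orig2, recon2, mask), ref)


class TestPostprocess:
    def test_all_zero_params_is_identity(self, rng):
        mask = np.ones((8, 8), dtype=np.uint8)
        score = np.abs(rng.standard_normal((8, 8))) * mask
        clean, binary = postprocess(score, mask, PostprocessParams(0, 0, 0, 0))
        np.testing.assert_array_equal(clean, score)
        assert binary is None

    def test_single_pixel_removed_by_opening(self):
        mask = np.ones((5, 5), dtype=np.uint8)
        score = np.zeros((5, 5))
        score[2, 2] = 1.0
        params = PostprocessParams(0, 0, open_radius=1, close_radius=0)
        binary = binarize(score, mask, 0.5, params)
        assert binary.sum() == 0

    def test_boundary_ring_zeroed_matches_erosion_oracle(self, rng):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[2:14, 2:14] = 1
        score = np.abs(rng.standard_normal((16, 16))) * mask + mask * 0.1
        params = PostprocessParams(0, boundary_margin=2, open_radius=0, close_radius=0)
        clean, _ = postprocess(score, mask, params)
        interior = ndimage.binary_erosion(mask.astype(bool), disk(2))
        assert np.all(clean[~interior] == 0)
        np.testing.assert_array_equal(clean[interior], score[interior])

    def test_binary_map_confined_to_liver(self, rng):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[3:9, 3:9] = 1
        score = np.abs(rng.standard_normal((12, 12)))
        clean, binary = postprocess(score * mask, mask, PostprocessParams(), threshold=0.1)
        assert np.all(binary[mask == 0] == 0)

    def test_positive_count_monotone_in_threshold(self, rng):
        mask = np.ones((10, 10), dtype=np.uint8)
        score = np.abs(rng.standard_normal((10, 10)))
        params = PostprocessParams(0, 0, 0, 0)
        counts = [binarize(score, mask, tau, params).sum()
                  for tau in np.linspace(0, score.max() + 0.1, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestF1Threshold:
    def test_worked_example(self):
        tau = f1_optimal_threshold(np.array([0.1, 0.4, 0.35, 0.8]),
                                   np.array([0, 0, 1, 1]))
        assert tau == pytest.approx(0.35)

    def test_perfectly_separated_returns_smallest_tumor_score(self, rng):
        healthy = rng.uniform(0, 0.4, 50)
        tumor = rng.uniform(0.6, 1.0, 30)
        scores = np.concatenate([healthy, tumor])
        labels = np.concatenate([np.zeros(50), np.ones(30)]).astype(bool)
        assert f1_optimal_threshold(scores, labels) == pytest.approx(tumor.min())

    def test_shift_equivariance(self, rng):
        scores = rng.standard_normal(100)
        labels = rng.random(100) > 0.6
        tau = f1_optimal_threshold(scores, labels)
        assert f1_optimal_threshold(scores + 5.0, labels) == pytest.approx(tau + 5.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            f1_optimal_threshold(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_matches_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(10, 500))
            scores = np.round(rng.standard_normal(n), 2)  # force ties
            labels = rng.random(n) > rng.uniform(0.2, 0.8)
            if labels.all() or not labels.any():
                continue
            assert f1_optimal_threshold(scores, labels) == \
                brute_f1_threshold(scores, labels)


class _IdentityModel:
    """Stub reconstructor returning the inpainted channel."""

    def forward(self, x, train=False):
        return x[:, 1:2]


class TestScoreSlice:
    def _record(self, rng):
        liver = np.zeros((16, 16), dtype=np.uint8)
        liver[3:13, 3:13] = 1
        orig = -0.2 + 0.01 * rng.standard_normal((16, 16))
        orig[6:10, 6:10] -= 0.1  # lesion-like hypodense patch
        inp = np.full((16, 16), -0.2)
        return SlicePairRecord(original=orig, inpainted=inp, liver_mask=liver,
                               subject_id="S0", slice_index=0)

    def test_result_respects_invariants(self, rng):
        rec = self._record(rng)
        res = score_slice(_IdentityModel(), rec, PostprocessParams(), 0.05)
        assert np.all(res.score_map[rec.liver_mask == 0] == 0)
        assert np.all(res.binary_map[rec.liver_mask == 0] == 0)
        assert res.binary_map.sum() > 0  # the hypodense patch is detected

    def test_infinite_threshold_gives_empty_map(self, rng):
        rec = self._record(rng)
        res = score_slice(_IdentityModel(), rec, PostprocessParams(), np.inf)
        assert res.binary_map.sum() == 0

    def test_invariant_to_out_of_mask_input_perturbation(self, rng):
        rec = self._record(rng)
        ref = score_slice(_IdentityModel(), rec, PostprocessParams(0, 0, 0, 0), 0.05)
        orig2 = rec.original.copy()
        orig2[rec.liver_mask == 0] += 10
        rec2 = SlicePairRecord(original=orig2, inpainted=rec.inpainted,
                               liver_mask=rec.liver_mask, subject_id="S0", slice_index=0)
        res2 = score_slice(_IdentityModel(), rec2, PostprocessParams(0, 0, 0, 0), 0.05)
        np.testing.assert_array_equal(res2.score_map, ref.score_map)
        np.testing.assert_array_equal(res2.binary_map, ref.binary_map)


def test_params_validation():
    with pytest.raises(ValueError):
        PostprocessParams(smooth_sigma=-1)


def test_healthy_slices_produce_few_false_positives(desk_run):
    """Healthy phantoms scored at the fitted thresholds flag <= 5% of the liver."""
    tau = float(np.mean(list(desk_run["thresholds"].values())))
    model = desk_run["model"]
    for pair in desk_run["train_pairs"][:10]:
        res = score_slice(model, pair, PostprocessParams(), tau)
        assert res.binary_map.sum() <= 0.05 * pair.liver_mask.sum()
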