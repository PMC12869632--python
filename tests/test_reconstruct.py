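"""Masked loss, model contracts, training behaviour of the reconstructor."""

import numpy as np
import pytest

from hepanomaly import _nn
from hepanomaly.core import SlicePairRecord
from hepanomaly.reconstruct import (EncDecConfig, UNetBaselineConfig, build_encdec,
                                    build_unet_baseline, masked_mse, reconstruct_slice,
                                    train_encdec)


def _make_pairs(n, rng, size=16, with_tumor=False):
    pairs = []
    for i in range(n):
        liver = np.zeros((size, size), dtype=np.uint8)
        liver[3:size - 3, 3:size - 3] = 1
        tumor = np.zeros_like(liver)
        if with_tumor:
            tumor[5:7, 5:7] = 1
        base = -0.18 + 0.01 * rng.standard_normal((size, size))
        pairs.append(SlicePairRecord(
            original=base, inpainted=base + 0.005 * rng.standard_normal((size, size)),
            liver_mask=liver, tumor_mask=tumor,
            subject_id=f"S{i:02d}", slice_index=0))
    return pairs


class TestMaskedMSE:
    def test_perfect_prediction_is_zero(self):
        x = np.ones((3, 3))
        assert masked_mse(x, x, np.ones((3, 3))) == 0.0

    def test_hand_computed_two_by_two(self):
        pred = np.array([[1.0, 0.0], [0.0, 0.0]])
        target = np.zeros((2, 2))
        mask = np.array([[1, 1], [0, 0]])
        assert masked_mse(pred, target, mask) == pytest.approx(0.5)

    def test_out_of_mask_pixels_are_ignored_bit_exactly(self, rng):
        pred = rng.standard_normal((5, 5))
        target = rng.standard_normal((5, 5))
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:3, 1:3] = 1
        before = masked_mse(pred, target, mask)
        pred2 = pred.copy()
        pred2[mask == 0] = 999.0
        assert masked_mse(pred2, target, mask) == before

    def test_out_of_mask_gradient_is_exactly_zero(self):
        # finite difference of the loss w.r.t. any out-of-mask pixel
        pred = np.full((4, 4), 0.3)
        target = np.zeros((4, 4))
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0] = 1
        base = masked_mse(pred, target, mask)
        for i, j in [(0, 1), (3, 3), (2, 0)]:
            p = pred.copy()
            p[i, j] += 1e-4
            assert masked_mse(p, target, mask) - base == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_mse(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))


class TestEncDec:
    def test_config_mirror_invariant(self):
        with pytest.raises(ValueError):
            EncDecConfig(encoder_channels=(8, 16, 32), decoder_channels=(32, 8, 16, 1))

    @pytest.mark.parametrize("size", [64, 96])
    def test_output_shape_matches_input(self, size, rng):
        model = build_encdec(EncDecConfig())
        x = rng.standard_normal((1, 2, size, size)).astype(np.float32)
        assert model.forward(x, train=False).shape == (1, 1, size, size)

    def test_eval_mode_deterministic_despite_dropout(self, rng):
        model = build_encdec(EncDecConfig(dropout_rate=0.5))
        x = rng.standard_normal((2, 2, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x, train=False),
                                      model.forward(x, train=False))

    def test_parameter_count_matches_layerwise_tally(self):
        model = build_encdec(EncDecConfig())
        # independent arithmetic over the default layout:
        # convs: 2->8, 8->16, 16->32 (3x3, +bias); convT: 32->16, 16->8 (3x3, +bias);
        # out conv 8->1; batchnorm gamma+beta per width
        conv = lambda ci, co: ci * co * 9 + co
        expected = (conv(2, 8) + conv(8, 16) + conv(16, 32)
                    + conv(32, 16) + conv(16, 8) + conv(8, 1)
                    + 2 * (8 + 16 + 32 + 16 + 8))
        assert model.n_params == expected


class TestUNetBaseline:
    def test_shape_and_bottleneck_width(self, rng):
        model = build_unet_baseline(UNetBaselineConfig())
        x = rng.standard_normal((1, 2, 64, 64)).astype(np.float32)
        assert model.forward(x, train=False).shape == (1, 1, 64, 64)
        assert model.bottleneck_width == 256

    def test_width_doubling_invariant(self):
        with pytest.raises(ValueError):
            UNetBaselineConfig(base_channels=32, bottleneck_channels=128)

    def test_has_more_parameters_than_compact_encdec(self):
        assert build_unet_baseline(UNetBaselineConfig()).n_params \
            > build_encdec(EncDecConfig()).n_params


class TestTraining:
    def test_tumor_pairs_rejected(self, rng):
        pairs = _make_pairs(2, rng, with_tumor=True)
        with pytest.raises(ValueError, match="healthy"):
            train_encdec(pairs, EncDecConfig(epochs=1))

    def test_zero_epochs_returns_initialization(self, rng):
        pairs = _make_pairs(2, rng)
        cfg = EncDecConfig(epochs=0, seed=5)
        model, losses = train_encdec(pairs, cfg)
        assert losses == []
        init = build_encdec(EncDecConfig(seed=5))
        # trained-for-zero-epochs weights equal a fresh build with the same seed
        s1, s2 = _nn.get_state(model), _nn.get_state(init)
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_loss_decreases_and_seeded_runs_are_identical(self, rng):
        pairs = _make_pairs(6, rng)
        cfg = EncDecConfig(epochs=5, seed=2, batch_size=3)
        m1, l1 = train_encdec(pairs, cfg)
        m2, l2 = train_encdec(pairs, cfg)
        assert l1[-1] <= l1[0]
        assert l1 == l2
        s1, s2 = _nn.get_state(m1), _nn.get_state(m2)
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_reconstruct_slice_deterministic(self, rng):
        pairs = _make_pairs(2, rng)
        model, _ = train_encdec(pairs, EncDecConfig(epochs=1, seed=0))
        np.testing.assert_array_equal(reconstruct_slice(model, pairs[0]),
                                      reconstruct_slice(model, pairs[0]))


def test_reconstruction_error_concentrates_in_lesions(desk_run):
    """The healthy-trained reconstructor's error is larger inside tumors than
    in healthy parenchyma — the premise of difference-based detection."""
    from hepanomaly.anomaly import PostprocessParams, base_map, postprocess
    model = desk_run["model"]
    tumor_scores, healthy_scores = [], []
    for p in desk_run["eval_pairs"]:
        recon = reconstruct_slice(model, p)
        clean, _ = postprocess(base_map(p.original, recon, p.liver_mask),
                               p.liver_mask, PostprocessParams())
        t = p.tumor_mask.astype(bool)
        liv = p.liver_mask.astype(bool)
        tumor_scores.append(clean[t & liv].mean())
        healthy_scores.append(clean[liv & ~t].mean())
    assert np.mean(tumor_scores) > 2 * np.mean(healthy_scores)
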