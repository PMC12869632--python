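"""Healthy-liver reconstruction: compact encoder-decoder and U-Net baseline.

The reconstructor consumes a 2-channel input — the original slice
concatenated with its liver-inpainted pseudo-normal counterpart, in that
fixed channel order — and emits a 1-channel reconstruction of the same
spatial size. It is trained exclusively on healthy pairs with an MSE loss
averaged over liver-mask pixels only, so out-of-mask content carries exactly
zero gradient; the target is the original (healthy) slice with the inpainted
slice acting as healthy-context conditioning.

Architecture (channel widths 8-16-32 mirrored to 32-16-8-1): stride-2
convolutions downsample twice, transposed convolutions mirror them, every
encoder block is Conv-BatchNorm-ReLU-Dropout. Kernel size 3, dropout 0.1 and
the Adam optimiser are pinned package defaults; the widths are the
architecture's defining contract. The U-Net baseline (2->1 channels, three
levels, 32 base channels doubling to a 256-channel bottleneck, additive skip
connections) provides the generic-reconstruction comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, ReLU, Sequential
from .core import SlicePairRecord

__all__ = [
    "EncDecConfig", "UNetBaselineConfig", "masked_mse",
    "build_encdec", "train_encdec", "reconstruct_slice", "build_unet_baseline",
    "EncDec", "UNetBaseline",
]


@dataclass
class EncDecConfig:
    encoder_channels: tuple[int, ...] = (8, 16, 32)
    decoder_channels: tuple[int, ...] = (32, 16, 8, 1)
    dropout_rate: float = 0.1
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    dtype: type = np.float32

    def __post_init__(self):
        mirror = tuple(reversed(self.encoder_channels)) + (1,)
        if self.decoder_channels != mirror:
            raise ValueError(
                f"decoder must mirror encoder widths and end in 1 channel: "
                f"expected {mirror}, got {self.decoder_channels}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class UNetBaselineConfig:
    levels: int = 3
    base_channels: int = 32
    bottleneck_channels: int = 256
    input_channels: int = 2
    output_channels: int = 1
    seed: int = 0
    dtype: type = np.float32

    def __post_init__(self):
        widths = [self.base_channels * 2 ** i for i in range(self.levels)]
        if widths[-1] * 2 != self.bottleneck_channels:
            raise ValueError("channel widths must double per level up to the bottleneck")


def masked_mse(prediction, target, mask):
    """Mean squared error over mask-positive pixels only."""
    prediction = np.asarray(prediction, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mask = np.asarray(mask)
    if not (prediction.shape == target.shape == mask.shape):
        raise ValueError("prediction, target and mask shapes must match")
    m = mask.astype(bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("masked_mse is undefined for an empty mask")
    d = prediction[m] - target[m]
    return float(np.mean(d * d))


class EncDec:
    """Compact encoder-decoder; ``forward`` maps (N, 2, H, W) -> (N, 1, H, W)."""

    def __init__(self, cfg: EncDecConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        c = cfg.encoder_channels
        kw = dict(rng=rng, dtype=cfg.dtype)
        layers = [Conv2d(2, c[0], **kw), BatchNorm2d(c[0], dtype=cfg.dtype), ReLU(), Dropout(cfg.dropout_rate, rng)]
        for cin, cout in zip(c[:-1], c[1:]):
            layers += [Conv2d(cin, cout, stride=2, **kw), BatchNorm2d(cout, dtype=cfg.dtype),
                       ReLU(), Dropout(cfg.dropout_rate, rng)]
        for cin, cout in zip(c[::-1][:-1], c[::-1][1:]):
            layers += [ConvTranspose2d(cin, cout, **kw), BatchNorm2d(cout, dtype=cfg.dtype), ReLU()]
        layers += [Conv2d(c[0], 1, **kw)]
        layers[-1].params["W"][:] = 0  # start from a zero reconstruction
        self.net = Sequential(layers)

    def layers_dict(self):
        return {"net": self.net}

    @property
    def n_params(self):
        return sum(l.params[k].size for _, l, k in _nn.collect_params(self))

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[1] != 2:
            raise ValueError("expected input of shape (N, 2, H, W)")
        return self.net.forward(x.astype(self.cfg.dtype, copy=False), train)

    def backward(self, gy):
        return self.net.backward(gy)


class UNetBaseline:
    """Three-level U-Net autoencoder with additive skip connections."""

    def __init__(self, cfg: UNetBaselineConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        w = [cfg.base_channels * 2 ** i for i in range(cfg.levels)]  # e.g. 32,64,128
        kw = dict(rng=rng, dtype=cfg.dtype)

        def block(cin, cout, stride=1):
            return Sequential([Conv2d(cin, cout, stride=stride, **kw),
                               BatchNorm2d(cout, dtype=cfg.dtype), ReLU()])

        self.enc = [block(cfg.input_channels, w[0])] + \
                   [block(w[i], w[i + 1], stride=2) for i in range(cfg.levels - 1)]
        self.bottleneck = block(w[-1], cfg.bottleneck_channels, stride=2)
        self.ups = []
        self.dec = []
        chain = [cfg.bottleneck_channels] + w[::-1]  # 256,128,64,32
        for cin, cout in zip(chain[:-1], chain[1:]):
            self.ups.append(ConvTranspose2d(cin, cout, **kw))
            self.dec.append(block(cout, cout))
        self.out = Conv2d(w[0], cfg.output_channels, **kw)

    def layers_dict(self):
        d = {f"enc{i}": l for i, l in enumerate(self.enc)}
        d["bottleneck"] = self.bottleneck
        d.update({f"up{i}": l for i, l in enumerate(self.ups)})
        d.update({f"dec{i}": l for i, l in enumerate(self.dec)})
        d["out"] = self.out
        return d

    @property
    def n_params(self):
        return sum(l.params[k].size for _, l, k in _nn.collect_params(self))

    @property
    def bottleneck_width(self):
        return self.bottleneck.layers[0].params["W"].shape[0]

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[1] != self.cfg.input_channels:
            raise ValueError(f"expected input of shape (N, {self.cfg.input_channels}, H, W)")
        x = x.astype(self.cfg.dtype, copy=False)
        skips = []
        for enc in self.enc:
            x = enc.forward(x, train)
            skips.append(x)
        x = self.bottleneck.forward(x, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = dec.forward(up.forward(x, train) + skip, train)
        return self.out.forward(x, train)

    def backward(self, gy):
        g = self.out.backward(gy)
        skip_grads = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            g = dec.backward(g)
            skip_grads.append(g)  # branch into the matching encoder output
            g = up.backward(g)
        g = self.bottleneck.backward(g)
        for enc, sg in zip(reversed(self.enc), reversed(skip_grads)):
            g = enc.backward(g + sg)
        return g


def build_encdec(cfg: EncDecConfig) -> EncDec:
    """Construct the reconstruction model (parameter count at ``model.n_params``)."""
    return EncDec(cfg, rng=np.random.default_rng(cfg.seed))


def build_unet_baseline(cfg: UNetBaselineConfig) -> UNetBaseline:
    return UNetBaseline(cfg, rng=np.random.default_rng(cfg.seed))


def _pair_batch(pairs, dtype):
    x = np.stack([np.stack([p.original, p.inpainted]) for p in pairs]).astype(dtype)
    y = np.stack([p.original for p in pairs]).astype(dtype)[:, None]
    m = np.stack([p.liver_mask for p in pairs]).astype(dtype)[:, None]
    return x, y, m


def train_encdec(pairs: list[SlicePairRecord], cfg: EncDecConfig, model=None):
    """Train a reconstructor on healthy pairs with the liver-masked MSE loss.

    Rejects any pair whose tumor mask is nonempty (training purity: only
    healthy slices may shape the healthy prior). Returns (model, losses)
    with one mean-loss entry per epoch; deterministic for a fixed seed.
    """
    if not pairs:
        raise ValueError("no training pairs")
    for p in pairs:
        if p.tumor_mask is not None and p.tumor_mask.sum() > 0:
            raise ValueError(
                f"pair {p.subject_id}/{p.slice_index} contains tumor pixels; "
                "the reconstructor must be trained on healthy slices only")
    loop_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    if model is None:
        model = build_encdec(cfg)
    opt = Adam(model, lr=cfg.learning_rate)
    losses = []
    for _ in range(cfg.epochs):
        order = loop_rng.permutation(len(pairs))
        epoch_losses = []
        for start in range(0, len(pairs), cfg.batch_size):
            batch = [pairs[i] for i in order[start:start + cfg.batch_size]]
            x, y, m = _pair_batch(batch, cfg.dtype)
            pred = model.forward(x, train=True)
            diff = (pred - y) * m
            per_mask = m.sum(axis=(1, 2, 3), keepdims=True)
            loss = float(np.mean((diff ** 2).sum(axis=(1, 2, 3)) / per_mask[:, 0, 0, 0]))
            gy = (2.0 * diff / per_mask / len(batch)).astype(cfg.dtype)
            model.backward(gy)
            opt.step()
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
    return model, losses


def reconstruct_slice(model, record: SlicePairRecord) -> np.ndarray:
    """Deterministic (eval-mode) healthy reconstruction of one slice pair."""
    x = np.stack([record.original, record.inpainted])[None]
    return np.asarray(model.forward(x, train=False), dtype=np.float64)[0, 0]
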