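"""Unconditional DDPM healthy prior: cosine schedule, epsilon U-Net, training, sampling.

The forward process is the standard variance-preserving Gaussian corruption
x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps with a cosine cumulative
schedule abar_t = f(t)/f(0), f(t) = cos^2(((t/T + s)/(1 + s)) * pi/2).
The model predicts the injected noise (epsilon parameterisation) and is
trained by plain MSE over uniformly sampled timesteps; reverse sampling is
the ancestral chain with the fixed posterior variance
beta~_t = beta_t (1 - abar_{t-1}) / (1 - abar_t).

An exponential-moving-average copy of the weights is maintained during
training and is, by default, what the inpainting stage consumes. Sampling
exposes a guidance-scale hook for API compatibility with guided samplers,
but the healthy prior carries no conditioning signal, so the default (and
only meaningful) setting is plain unconditional sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Linear

__all__ = [
    "cosine_alpha_bar", "NoiseSchedule", "forward_diffuse",
    "EpsilonModelSpec", "EpsilonUNet", "DDPMTrainConfig",
    "train_ddpm", "ema_update", "reverse_step", "sample", "as_eps_fn",
]

ema_update = _nn.ema_update  # re-exported: part of this module's surface


def cosine_alpha_bar(t, T: int, s: float = 0.008):
    """Cumulative signal retention abar_t of the cosine schedule; abar_0 = 1."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0) or np.any(t > T):
        raise ValueError("t must lie in [0, T]")

    def f(u):
        return np.cos(((u / T + s) / (1 + s)) * math.pi / 2.0) ** 2

    return f(t) / f(0.0)


@dataclass
class NoiseSchedule:
    """Per-step diffusion quantities; ``alpha_bar[t]`` is indexed t = 0..T."""

    T: int
    beta: np.ndarray       # shape (T,), beta[t-1] is the step t variance
    alpha_bar: np.ndarray  # shape (T+1,), alpha_bar[0] == 1

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.alpha_bar = np.asarray(self.alpha_bar, dtype=np.float64)
        if self.beta.shape != (self.T,) or self.alpha_bar.shape != (self.T + 1,):
            raise ValueError("schedule array lengths inconsistent with T")
        if abs(self.alpha_bar[0] - 1.0) > 1e-9:
            raise ValueError("alpha_bar[0] must equal 1")
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")
        if np.any(self.beta <= 0) or np.any(self.beta >= 1):
            raise ValueError("beta must lie in (0, 1)")

    @classmethod
    def cosine(cls, T: int, s: float = 0.008, max_beta: float = 0.999) -> "NoiseSchedule":
        abar = cosine_alpha_bar(np.arange(T + 1), T, s)
        beta = np.clip(1.0 - abar[1:] / abar[:-1], 1e-8, max_beta)
        # re-accumulate so alpha_bar = prod(1 - beta) holds exactly after clipping
        abar = np.concatenate([[1.0], np.cumprod(1.0 - beta)])
        return cls(T=T, beta=beta, alpha_bar=abar)


def forward_diffuse(x0: np.ndarray, t, noise: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) noise; t may be scalar or per-sample."""
    x0 = np.asarray(x0)
    noise = np.asarray(noise)
    if x0.shape != noise.shape:
        raise ValueError("x0 and noise shapes differ")
    t = np.asarray(t)
    abar = schedule.alpha_bar[t]
    if abar.ndim > 0 and abar.ndim < x0.ndim:  # per-sample t on a batch
        abar = abar.reshape((-1,) + (1,) * (x0.ndim - 1))
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * noise


# ---------------------------------------------------------------------------
# epsilon model
# ---------------------------------------------------------------------------

@dataclass
class EpsilonModelSpec:
    """Architecture descriptor for the multi-scale epsilon predictor."""

    image_size: int = 64
    base_channels: int = 32
    channel_mult: tuple[int, ...] = (1, 2, 4)  # three resolution levels
    time_dim: int = 64
    dtype: type = np.float32

    def __post_init__(self):
        if len(self.channel_mult) != 3:
            raise ValueError("this epsilon U-Net is three-level")
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4")


def _sinusoidal_embedding(t, dim, dtype):
    t = np.asarray(t, dtype=np.float64).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(dtype)


class EpsilonUNet:
    """Three-level additive-skip U-Net predicting the diffusion noise.

    Timestep information enters as a per-channel bias (a linear projection of
    a sinusoidal embedding passed through a small MLP) added before each
    Conv-BN-ReLU block. Forward/backward are hand-chained over the layer
    objects in :mod:`hepanomaly._nn`.
    """

    def __init__(self, spec: EpsilonModelSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        c0, c1, c2 = (spec.base_channels * m for m in spec.channel_mult)
        dt = spec.time_dim
        kw = dict(rng=rng, dtype=spec.dtype)
        emb_in = 32  # sinusoidal embedding width
        self.emb_in = emb_in
        self.mlp1 = Linear(emb_in, dt, **kw)
        self.mlp2 = Linear(dt, dt, **kw)
        self.conv_in = Conv2d(1, c0, **kw)
        self.cv0, self.bn0, self.tb0 = Conv2d(c0, c0, **kw), BatchNorm2d(c0, dtype=spec.dtype), Linear(dt, c0, **kw)
        self.down1 = Conv2d(c0, c1, stride=2, **kw)
        self.cv1, self.bn1, self.tb1 = Conv2d(c1, c1, **kw), BatchNorm2d(c1, dtype=spec.dtype), Linear(dt, c1, **kw)
        self.down2 = Conv2d(c1, c2, stride=2, **kw)
        self.cv2, self.bn2, self.tb2 = Conv2d(c2, c2, **kw), BatchNorm2d(c2, dtype=spec.dtype), Linear(dt, c2, **kw)
        self.cvm, self.bnm, self.tbm = Conv2d(c2, c2, **kw), BatchNorm2d(c2, dtype=spec.dtype), Linear(dt, c2, **kw)
        self.up1 = ConvTranspose2d(c2, c1, **kw)
        self.cv3, self.bn3, self.tb3 = Conv2d(c1, c1, **kw), BatchNorm2d(c1, dtype=spec.dtype), Linear(dt, c1, **kw)
        self.up2 = ConvTranspose2d(c1, c0, **kw)
        self.cv4, self.bn4, self.tb4 = Conv2d(c0, c0, **kw), BatchNorm2d(c0, dtype=spec.dtype), Linear(dt, c0, **kw)
        self.conv_out = Conv2d(c0, 1, **kw)
        # zero-init the output head: the reverse chain starts as near-identity
        self.conv_out.params["W"][:] = 0
        self._relu_masks = {}

    def layers_dict(self):
        return {name: obj for name, obj in vars(self).items()
                if isinstance(obj, (Conv2d, ConvTranspose2d, BatchNorm2d, Linear))}

    @property
    def n_params(self):
        return sum(l.params[k].size for _, l, k in _nn.collect_params(self))

    # -- forward -----------------------------------------------------------
    def _block(self, name, x, e, cv, bn, tb, train):
        pre = cv.forward(x, train) + tb.forward(e, train)[:, :, None, None]
        h = bn.forward(pre, train)
        mask = h > 0
        self._relu_masks[name] = mask
        return h * mask

    def forward(self, x, t, train=True):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (N, 1, H, W)")
        x = x.astype(self.spec.dtype, copy=False)
        emb = _sinusoidal_embedding(t, self.emb_in, self.spec.dtype)
        e = self.mlp1.forward(emb, train)
        self._e_mask = e > 0
        e = self.mlp2.forward(e * self._e_mask, train)

        h0 = self.conv_in.forward(x, train)
        a0 = self._block("b0", h0, e, self.cv0, self.bn0, self.tb0, train)
        a1 = self._block("b1", self.down1.forward(a0, train), e, self.cv1, self.bn1, self.tb1, train)
        a2 = self._block("b2", self.down2.forward(a1, train), e, self.cv2, self.bn2, self.tb2, train)
        m = self._block("bm", a2, e, self.cvm, self.bnm, self.tbm, train)
        u1 = self.up1.forward(m, train) + a1
        b3 = self._block("b3", u1, e, self.cv3, self.bn3, self.tb3, train)
        u2 = self.up2.forward(b3, train) + a0
        b4 = self._block("b4", u2, e, self.cv4, self.bn4, self.tb4, train)
        return self.conv_out.forward(b4, train)

    # -- backward ----------------------------------------------------------
    def _block_back(self, name, gy, cv, bn, tb):
        gpre = bn.backward(gy * self._relu_masks[name])
        de = tb.backward(gpre.sum((2, 3)))
        return cv.backward(gpre), de

    def backward(self, gy):
        g = self.conv_out.backward(gy)
        g, de = self._block_back("b4", g, self.cv4, self.bn4, self.tb4)
        ga0 = g  # skip branch into a0
        g = self.up2.backward(g)
        g, d = self._block_back("b3", g, self.cv3, self.bn3, self.tb3)
        de += d
        ga1 = g
        g = self.up1.backward(g)
        g, d = self._block_back("bm", g, self.cvm, self.bnm, self.tbm)
        de += d
        g, d = self._block_back("b2", g, self.cv2, self.bn2, self.tb2)
        de += d
        g = self.down2.backward(g) + ga1
        g, d = self._block_back("b1", g, self.cv1, self.bn1, self.tb1)
        de += d
        g = self.down1.backward(g) + ga0
        g, d = self._block_back("b0", g, self.cv0, self.bn0, self.tb0)
        de += d
        g = self.conv_in.backward(g)
        de = self.mlp2.backward(de)
        self.mlp1.backward(de * self._e_mask)
        return g

    def __call__(self, x, t, train=False):
        return self.forward(x, t, train)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class DDPMTrainConfig:
    batch_size: int = 4
    learning_rate: float = 1e-4
    ema_momentum: float = 0.999
    train_steps: int = 1000  # desk default; paper-scale runs use far more
    seed: int = 0
    log_every: int = 100

    def __post_init__(self):
        if not (0.0 < self.ema_momentum <= 1.0):
            raise ValueError("ema_momentum must be in (0, 1]")


def train_ddpm(slices, spec: EpsilonModelSpec, cfg: DDPMTrainConfig,
               schedule: NoiseSchedule | None = None):
    """Train the epsilon predictor on normalized healthy slices.

    ``slices`` is an (N, H, W) stack (or list of 2-D grids) in [-1, 1];
    tumor-free content is the caller's contract. Returns
    ``(model, ema_state, losses)`` where ``ema_state`` is a flat
    {path: array} weight dict and ``losses`` the per-log-interval mean MSE.
    """
    x = np.stack([np.asarray(s, dtype=np.float64) for s in slices])
    if np.any(np.abs(x) > 1.0 + 1e-6):
        raise ValueError("training slices must be normalized to [-1, 1]")
    schedule = schedule or NoiseSchedule.cosine(250)
    master = np.random.SeedSequence(cfg.seed)
    init_rng, loop_rng = (np.random.default_rng(s) for s in master.spawn(2))
    model = EpsilonUNet(spec, rng=init_rng)
    ema = _nn.get_state(model)
    opt = Adam(model, lr=cfg.learning_rate)
    x = x.astype(spec.dtype)

    losses = []
    acc = []
    for step in range(cfg.train_steps):
        idx = loop_rng.integers(0, len(x), size=cfg.batch_size)
        t = loop_rng.integers(1, schedule.T + 1, size=cfg.batch_size)
        x0 = x[idx][:, None]
        noise = loop_rng.standard_normal(x0.shape).astype(spec.dtype)
        xt = forward_diffuse(x0, t, noise, schedule).astype(spec.dtype)
        pred = model.forward(xt, t, train=True)
        diff = pred - noise
        loss = float(np.mean(diff ** 2))
        model.backward((2.0 / diff.size) * diff.astype(spec.dtype))
        opt.step()
        _nn.ema_update(ema, _nn.get_state(model), cfg.ema_momentum)
        acc.append(loss)
        if (step + 1) % cfg.log_every == 0 or step + 1 == cfg.train_steps:
            losses.append(float(np.mean(acc)))
            acc = []
    return model, ema, losses


def as_eps_fn(model, ema_state=None):
    """Wrap a model (optionally with EMA weights swapped in) as eps(x, t)."""
    if ema_state is not None:
        _nn.set_state(model, ema_state)

    def fn(x, t):
        return model.forward(x, np.broadcast_to(np.asarray(t), (x.shape[0],)), train=False)

    return fn


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def reverse_step(eps_fn, x, t: int, schedule: NoiseSchedule, noise,
                 variance: str = "fixed_large"):
    """One ancestral reverse step x_t -> x_{t-1}.

    ``variance`` selects the fixed reverse variance: ``"fixed_large"``
    (sigma_t^2 = beta_t, the default) or ``"fixed_small"``
    (sigma_t^2 = beta~_t = beta_t (1 - abar_{t-1}) / (1 - abar_t)). The
    large choice is exact for unit-variance Gaussian data at any step count,
    which is what the sampler-correctness tests exploit; the small choice is
    the conditional-on-x0 posterior variance. No noise is added at t = 1.
    """
    beta = schedule.beta[t - 1]
    alpha = 1.0 - beta
    abar_t = schedule.alpha_bar[t]
    abar_prev = schedule.alpha_bar[t - 1]
    eps = np.asarray(eps_fn(x, t), dtype=np.float64)
    mean = (x - beta / math.sqrt(1.0 - abar_t) * eps) / math.sqrt(alpha)
    if t == 1:
        return mean
    if variance == "fixed_large":
        var = beta
    elif variance == "fixed_small":
        var = beta * (1.0 - abar_prev) / (1.0 - abar_t)
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    return mean + math.sqrt(var) * noise


def sample(eps_fn, schedule: NoiseSchedule, shape, seed: int, guidance_scale: float = 1.0,
           variance: str = "fixed_large", clip: bool = True):
    """Draw samples by iterative denoising from Gaussian noise.

    ``eps_fn(x, t)`` maps an (N, 1, H, W) batch and step index to predicted
    noise (an :class:`EpsilonUNet` works directly; see :func:`as_eps_fn` for
    EMA weights). ``guidance_scale`` is accepted for interface compatibility
    but must be 1.0: the healthy prior is unconditional. ``clip`` clamps the
    final output to the normalized [-1, 1] range; disable it only to study
    the raw chain (e.g. moment checks against an analytic score).
    """
    if guidance_scale != 1.0:
        raise ValueError("no conditioning signal exists; guidance_scale must be 1.0")
    if len(shape) != 4 or shape[1] != 1:
        raise ValueError("shape must be (N, 1, H, W)")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(shape)
    for t in range(schedule.T, 0, -1):
        noise = rng.standard_normal(shape) if t > 1 else None
        x = reverse_step(eps_fn, x, t, schedule, noise, variance)
    return np.clip(x, -1.0, 1.0) if clip else x
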