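# Methods

## The model

`hepanomaly` detects focal liver lesions on 2-D axial CT slices by comparing
each slice against a synthesized *healthy* version of itself, with every
learning, inference and evaluation step scoped to a whole-liver mask that is
supplied as input (in clinical use it would come from an automatic organ
segmenter; here it is produced by the phantom generator or read from NIfTI).

The pipeline has four stages.

**1 — Healthy prior (DDPM).** An unconditional denoising diffusion
probabilistic model is trained on healthy slices normalized to [-1, 1]. The
forward corruption is the variance-preserving kernel

    x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps,   eps ~ N(0, I),

with the cosine cumulative schedule `abar_t = f(t)/f(0)`,
`f(t) = cos^2(((t/T + s)/(1 + s)) pi/2)`, offset `s = 0.008`. A three-level
additive-skip U-Net predicts `eps` from `(x_t, t)`; the timestep enters as a
per-channel bias computed from a sinusoidal embedding through a two-layer
MLP. Training minimises plain MSE on `eps` over uniformly sampled `t`, with
Adam and an exponential-moving-average (EMA) copy of the weights; the EMA
weights are what the inpainting stage consumes (conventional choice — the
raw weights remain available).

**2 — Liver-masked inpainting (RePaint).** For each slice the whole liver
region is regenerated under the healthy prior: at every reverse step the
extrahepatic ("known") region is replaced by the forward-noised original at
the matching noise level, the liver ("unknown") region keeps the model's
denoised content, and `r` resampling cycles per step re-noise and re-denoise
the composite so the regions harmonise. Because the known region never
includes the liver, the inpainted liver is lesion-free by construction. The
final output pastes the exact original pixels outside the mask, so the
background is preserved bit-exactly. The whole liver mask — not a lesion
prior — defines the inpainting region; this is what removes the circular
dependency of detectors that must first localise the anomaly to inpaint it.

**3 — Healthy reconstruction.** A compact convolutional encoder–decoder
(channel widths 8→16→32 mirrored to 32→16→8→1; stride-2 convolutions down,
transposed convolutions up; Conv–BatchNorm–ReLU blocks with dropout in the
encoder) maps the 2-channel concatenation (original, inpainted) to a
1-channel reconstruction of the original. It is trained **only on healthy
pairs** with an MSE loss averaged over liver pixels; out-of-mask pixels
carry exactly zero gradient. A guard rejects any training pair whose tumor
mask is nonempty.

**4 — Anomaly scoring.** The anomaly signal is `|x_original - x_recon|`
inside the liver, zero outside. Post-processing runs in order: Gaussian
smoothing (sigma 1 px), zeroing of scores within 2 px of the liver boundary
(mask erosion), thresholding, then binary opening and closing (disk radius
1 px); any step is disabled by a zero parameter. The operating threshold
maximises pixel-level F1 over the ROC operating points of the pooled
in-liver scores, fitted once per evaluation fold (a per-slice variant is
available but is unstable for small lesions).

**Evaluation.** Liver-masked Dice, IoU, HD95 and per-slice pixel AUROC;
quartile stratification by tumor pixel area; patient-grouped K-fold
cross-validation (all slices of a subject share a fold, folds greedily
balanced to within one subject); 95% confidence intervals from the
t-distribution on per-slice or per-fold means. Ablations evaluate, under
identical folds and threshold protocol: the full model, the full model with
post-processing disabled, and the inpainting-only score
`|x_original - x_inpainted|` with no learned reconstruction.

## Parameters that matter

| parameter | default | desk-scale run | meaning |
|---|---|---|---|
| clip window | [-1000, 1600] HU | same | air through dense contrast-enhanced tissue |
| mu_w | 0.192 cm^-1 | same | water attenuation constant of the HU→attenuation map |
| stride / min liver px | 3 / 100 | 1 / 100 | slice subsampling, then retention rule |
| T (diffusion steps) | 250 | 50 | sampling cost is linear in T |
| r (resampling cycles) | 10 | 4 | RePaint harmonisation passes per step |
| jump length | 1 | 1 | forward re-noising span per cycle |
| batch / lr / EMA | 4 / 1e-4 / 0.999 | 4 / 2e-3 / 0.99 | DDPM training |
| encoder widths | (8, 16, 32) | same | reconstructor capacity |
| dropout | 0.1 | same | reconstructor regularisation |
| smoothing / margin / open / close | 1 px / 2 px / 1 px / 1 px | same | smallest nontrivial "light" post-processing |
| K (folds) | 5 | 5 | patient-grouped CV |

The normalization maps HU to linear attenuation `mu = mu_w (1 + HU/1000)`
and then affinely rescales the clip window onto [-1, 1]; since the
HU→attenuation map is itself affine, the composition is an affine map of
clipped HU — the only mapping consistent with both the mu_w
parameterisation and the stated output range. The midpoint 300 HU maps to 0.

## Numerical choices

- **Reverse variance.** The ancestral sampler uses the fixed "large"
  variance `sigma_t^2 = beta_t` by default, with the conditional posterior
  variance `beta~_t = beta_t (1 - abar_{t-1})/(1 - abar_t)` selectable. The
  large choice is exactly correct for unit-variance Gaussian data at any
  step count, which makes the sampler verifiable against an analytic score
  oracle at desk-scale T; the small choice provably under-disperses short
  chains (about -24% variance at T=50 for a 0.2-SD Gaussian). No noise is
  added at the final step.
- **beta clipping and re-accumulation.** Cosine-schedule betas are clipped
  to [1e-8, 0.999] and `abar` is then re-accumulated as `prod(1 - beta)`, so
  the product identity holds exactly rather than to rounding.
- **Epsilon-model output head is zero-initialised**, so an untrained model
  predicts zero noise and the chain starts near-identity; the reconstructor's
  output convolution is likewise zero-initialised so training starts from a
  zero reconstruction instead of He-init noise.
- **Training length of the reconstructor is deliberately modest** (20 epochs
  at desk scale). Its job is a smooth, anatomically coherent healthy prior;
  trained to convergence on healthy pairs a convolutional network drifts
  toward the identity map on the original channel, which would reproduce
  lesions and null the anomaly signal. Early stopping plus dropout keeps it
  on the healthy manifold. This mirrors the capacity/stability trade-off any
  reconstruction-based detector must make.
- **HD95** uses 8-connectivity boundary pixels (a pixel is boundary if any
  8-neighbour, or the image border, is background) and pools the
  bidirectional nearest-boundary distances before the 95th percentile
  (linear interpolation). Empty masks yield an undefined flag (NaN),
  excluded from means with the count reported.
- **Both-empty Dice/IoU are defined as 1.0**; the case cannot occur in the
  abnormal evaluation cohort (every slice carries a lesion) and only arises
  in healthy sanity checks.
- **Thresholding** happens after smoothing and boundary suppression and
  before morphology. The F1-optimal threshold is fitted on the same fold it
  evaluates (the protocol the evaluation design implies); a held-out variant
  is a one-line change in `evaluate_cohort`.
- **Channel order** of the reconstructor input is pinned as (original,
  inpainted).
- Neural-network arithmetic is float32 (im2col + BLAS matmul); metrics and
  normalization are float64. All randomness flows through seeded
  `numpy.random.Generator` streams spawned per stage and per slice, so runs
  are bit-reproducible and batched inpainting does not depend on how a
  cohort is chunked into equal-size batches.

## The phantom generator

The generator emulates exactly the features the pipeline depends on: an air
background (-1000 HU), an elliptical soft-tissue body (~40 HU) with a
subcutaneous fat rim (~-100 HU), a star-convex liver (~60 HU, Fourier-
perturbed ellipse boundary, guaranteed single connected component,
correlated Gaussian texture of 10 HU SD), extrahepatic context (spine ~350
HU, aorta ~180 HU, a gastric shadow ~-60 HU) so inpainting has anatomy to
condition on, and hypodense lesions (default -40 HU contrast) with soft
1-2 px edges. Lesion pixel areas are exact by construction — the tumor mask
is the set of the A smallest values of a smooth radial field — and cohort
generation cycles lesion areas through four log-width bands so size
quartiles are populated.

It does **not** emulate: 3-D anatomy or inter-slice continuity, beam
hardening or other physics, contrast-phase differences, scanner noise
spectra, anatomical variability beyond smooth-blob geometry, or
isodense/hyperdense lesions (contrast is configurable but the default study
is hypodense). Passing the synthetic tests therefore demonstrates that the
pipeline's machinery — masking, inpainting conservation, healthy-prior
reconstruction, scoring, metrics, CV bookkeeping — behaves correctly and
that detection improves with lesion size under controlled contrast; it does
not certify clinical performance, which depends on real parenchymal
texture, mask quality and acquisition variability.

## Desk-scale study

The reference configuration (`pipeline.desk_scale_config`) uses 64 px
phantoms: 300 healthy slices (30 subjects) train the DDPM for 1,500 steps;
48 healthy slices are inpainted (T=50, r=4) to train the reconstructor for
20 epochs; a 32-slice abnormal cohort (8 subjects, one lesion per slice,
areas 12-160 px across four size bands) is inpainted, scored and evaluated
with patient-grouped 5-fold CV. These sizes were chosen as the smallest
study that exercises every stage meaningfully — quartiles of 8 slices,
folds of 1-2 subjects — while training the numpy networks to a useful prior.

## Known limitations

- 2-D slices only; no volumetric context.
- The numpy network stack is CPU-bound; paper-scale (512 px, T=250, 1M
  steps) is configurationally supported but not practical without a GPU
  framework.
- The liver mask is trusted as given; segmentation errors propagate
  directly into scope and scores (soft masks are not supported).
- Very small lesions are penalised by the 2 px boundary suppression and the
  1 px opening, an intended trade against speckle false positives.
- The detection premise (reconstruction stays healthy on lesions) is
  enforced by limited training, not by an architectural guarantee.
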