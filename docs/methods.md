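# Methods

## The generative problem

Leaf-disease image collections pair a large healthy class with scarce
disease classes. Both augmentation routes in this package synthesize
diseased leaves from healthy ones under binary-mask guidance; the package's
job is to implement the machinery faithfully and make its contracts
testable at desk scale.

## Diffusion core

The forward chain is the standard Gaussian corruption
`q(x_t | x_{t-1}) = N(sqrt(1-β_t) x_{t-1}, β_t I)`, t = 1…T (t = 0 is the
clean image). Independence of the per-step noise gives the cumulative
signal retention `ᾱ_t = Π_{s≤t}(1-β_s)` and the single-draw marginal
`x_t = sqrt(ᾱ_t) x_0 + sqrt(1-ᾱ_t) ε`. The learned reverse kernel is
Gaussian; its mean is derived from a noise-prediction network via the usual
posterior-mean formula, and the network is trained with the simple MSE
objective on ε.

Choices where the design was open:

- **β schedule.** Linear interpolation between `beta_min` and `beta_max`
  (defaults 1e-4 → 0.02 at full scale; the 50-step desk profile uses
  1e-4 → 0.25 so that ᾱ_T ≈ 2·10⁻³, i.e. the chain actually reaches
  noise). A squared-cosine ᾱ profile is available as `kind="cosine"`.
- **Reverse variance.** The reverse kernel's variance is not pinned down by
  the training objective; we default to the fixed posterior variance
  β̃_t = (1-ᾱ_{t-1})/(1-ᾱ_t)·β_t and offer `variance="beta"`. The final
  step (t = 1) is deterministic, which makes oracle round-trips exact.
- **Sampler.** Ancestral (DDPM) sampling is the primary route because the
  inpainting equations are written against it; a deterministic DDIM-style
  sampler (`ddim_sample`, η = 0) is exposed as an option.
- **Value range.** Images are [0,1] at I/O boundaries, mapped to [-1,1]
  inside the chain; clipping happens only at emission.
- **Timestep conditioning** is a normalized scalar embedding: the network
  receives (t/T, sin 2πt/T, cos 2πt/T).

### The noise-prediction network

The ε-model is a deliberately small fully-connected network (two ReLU
hidden layers, width = the `model.channels` config knob), written in numpy
with hand-derived backprop and Adam. Internally it is clean-image
parameterized:

    x0_hat  = template + MLP(x_t, t)
    eps_hat = (x_t - sqrt(ᾱ_t) x0_hat) / sqrt(1 - ᾱ_t)

with a learned per-pixel `template`. The two parameterizations are
algebraically interchangeable, but at small widths the x0 form is far
better conditioned: even a weak correction network yields a denoiser that
pulls samples toward the learned data template rather than toward zero,
which is what makes 2000-step training on 64 tiny images produce usable
samples. Externally the model honours the plain `(x_t, t) → ε̂` contract,
so any other callable (including the test-time oracles) drops in.

The desk-scale default (16×16×3 rasters, width 28) has ≈45k parameters.
The documented full-scale settings — 4000 steps, 128 channels, attention at
resolutions 32/16/8, 16-bit precision, 256×256 images — are recorded in
`config.FULL_SCALE_SETTINGS` for reference; the dense network does not
interpret the attention or precision entries. The full-scale record also
carries a "learning rate kernel standard deviation: 2" entry verbatim from
the upstream configuration; its semantics are undefined here and it is
deliberately not implemented.

Checkpoints are single-file NPZ archives (format tag `leafdiffuse-ckpt-1`)
holding parameters, the β schedule and a JSON config header.

## Mask-conditioned inpainting

At each reverse step the known region (mask = 1) is sampled from the
forward marginal of the untouched input and the unknown region from the
learned kernel, composed as `x_{t-1} = m ⊙ x_known + (1-m) ⊙ x_unknown`.
Notes on the details:

- **Marginal index.** The state produced *for* step t-1 uses ᾱ_{t-1}
  (with ᾱ_0 = 1), so the last known-region draw is exactly the input.
  At t = 0 the known region is additionally hard-copied from the input,
  guaranteeing bit-exact known-region fidelity at emission.
- **Resampling.** After each stretch of denoising the composite is
  re-diffused `jump_length` steps and re-descended, `n_resamples` passes
  per jump point; (1,1) degenerates exactly to the plain conditioned
  chain. Defaults (10,10) follow the established convention for this
  sampler; the values are not derivable from first principles and are
  fully configurable.
- **Noise sharing.** Known and unknown branches draw independent noise, in
  a documented order (known first) from the single chain rng. Degenerate
  masks short-circuit to the single active branch; this is mathematically
  identical and keeps the rng stream aligned, so an all-unknown mask
  reproduces the unconditional sampler draw for draw under the same seed.
- **Convention safety.** Masks carry an explicit tag, `instance-marks-1`
  (1 = leaf) or `known-marks-1` (1 = kept context). Inpainting operations
  refuse instance-tagged masks: inverting an instance mask masks the whole
  leaf, leaves no context, and produces the ghost-leaf failure (a second
  leaf hallucinated inside a background-filled outline). A warning fires
  when the unknown fraction exceeds 0.98.

## Mask preparation

- **Otsu extraction.** Our own histogram implementation (exhaustive scan of
  the between-class-variance criterion, threshold reported as a bin edge),
  followed by polarity resolution (auto mode picks the side occupying the
  image center), largest-connected-component retention and hole filling.
  The cleanup steps are independently switchable because each corresponds
  to a distinct observed failure (shadows, specular holes).
- **Dilation** uses a discrete disk (radius-1 disk = the 5-pixel plus
  shape); the default radius is 3% of the shorter raster side — enough of
  a boundary band to anchor inpainting without hiding the leaf edge. The
  exact amount used in the original experiments is not recorded anywhere,
  so this is a package default, not a reproduction.
- **Split masks.** The default catalogue holds ten templates — four
  halves, four quadrants, a center window and a border band — sampled
  uniformly at random. The catalogue is symmetric left/right and
  top/bottom so expected symptom coverage is balanced across the leaf,
  including edges; it is user-extensible.
- **mIoU** handles the empty-union edge case as 1.0 (two empty masks agree).
  The supervised U-Net segmenter that produced the strongest published
  masks is out of scope as training code; any external segmenter's PNG
  masks drop in through the same scoring path.

## Translation losses

The loss family is implemented as pure functions over generator and
discriminator callables. The L1 terms are sums of absolute differences
over image and mask elements. Where the source material leaves gaps:

- The context-preserving weight map has no printed formula; we use the
  original convention w = 1 exactly on pixels that are background in every
  mask of both sets, and the weight function is pluggable.
- λ_cyc = λ_idt = λ_ctx = 10 by default (unstated upstream; these are the
  conventional values for this loss family), configurable.
- The printed adversarial expression mixes discriminator and generator
  roles; we implement the standard two-sided least-squares split
  (discriminator targets 1/0, generator targets 1) and expose both forms.
- The sequential mini-batch loss partitions the instance masks into M
  contiguous groups, scores the adversarial term on cumulative translated
  masks and the content terms on the current group; M = 1 reduces exactly
  (to 1e-12) to the combined loss by construction.

The bundled reference networks (single 3×3 conv encoders, residual
translator, linear-head discriminator) are forward-only and deterministic
from their seed: they exist to exercise the loss surface on CPU, not to
train. The documented full-scale translation settings (batch 1, 64
filters, lr 2e-4 with decay after 100 iterations, instance norm, no
dropout, flip/resize-crop, load 220 / fine 200) are in
`config.FULL_SCALE_SETTINGS`.

## Evaluation metrics

- PSNR = 20·log10(MAX/√MSE), +inf sentinel at MSE = 0.
- SSIM is implemented in its global single-window form (whole-image means,
  variances, covariance; stabilizers c1 = (0.01 L)², c2 = (0.03 L)²); a
  sliding-window variant is behind `windowed=True`.
- Inception Score: exp of the mean KL between per-sample class posteriors
  and the split marginal, over 10 splits by default, mean ± std.
- FID: squared mean difference plus covariance trace term; the matrix
  square root is computed by eigendecomposition of the symmetrized product
  `S1^{1/2} S2 S1^{1/2}`, clipping eigenvalues above −1e-6 to zero and
  raising on anything more negative.
- KID: unbiased MMD² with the degree-3 polynomial kernel
  `(x·y/d + 1)³`, averaged over seeded subsets (defaults: 100 subsets of
  size min(n, 1000)), reported mean ± std.

The feature extractor is a pluggable callable. The default is a
deterministic offline embedding (average-pool to a 4×4 grid, fixed seeded
Gaussian projection, tanh); an adapter wrapping a pretrained image
classifier satisfies the same contract. Absolute FID/KID values are
extractor-dependent, so only within-extractor comparisons are meaningful —
which is also why published absolute scores from pretrained-Inception
pipelines are not comparable to the toy extractor's numbers.

## Synthetic leaves

The generator emulates controlled-capture collections: one leaf per image
on a uniform bright background with an exact instance mask. The contour is
a star-shaped polar curve (ellipse radius modulated by a short Fourier
series plus tip taper), which cannot self-intersect; occupancy outside
[0.2, 0.8] of the raster is rejected. Disease overlays are stylized
renderers — dark spots, concentric rings, edge necrosis, yellow mottle,
whole-leaf yellowing — that only ever touch leaf pixels. Symptom sites are
pre-drawn once per call so the changed-pixel count is monotone in
intensity under a fixed seed, and `edge_bias=1` confines all changes to a
distance-transform boundary band (many real diseases concentrate at leaf
edges, and split masks exist precisely so synthetic symptoms can reach
them). The demo dataset assembly mirrors the 10:8:7:6:5:4:3:2:1 imbalance
of a curated tomato subset with a 12-unit healthy class.

What the generator does *not* emulate: real leaf texture, venation
diversity, lighting variation, camera noise, or inter-class shape
differences. Passing tests therefore demonstrate the correctness of the
algorithms and their contracts on in-distribution synthetic data, not
photorealistic augmentation quality.

## Problem sizes and numerical choices

The test and acceptance profiles use 16×16 rasters, T = 50 steps
(β 1e-4 → 0.25), a width-28 network trained 2000 Adam steps (lr 1e-3,
batch 32) on 64 images, and 4 inpainting repeats — sizes chosen so the
entire suite exercises every chain end to end in seconds while leaving
Monte-Carlo tolerances (3–4σ) comfortably resolvable. Schedule consistency
is enforced to 1e-12; FID clipping tolerance is 1e-6; mask PNGs are 0/255
thresholded at 128 on read, with the convention tag in a JSON sidecar.
All randomness flows through `numpy.random.Generator`; the pipeline derives
per-stage generators from the single run seed via `SeedSequence(seed,
spawn_key=(stage_index,))`, making runs bit-reproducible.

## Known limitations

- The dense ε-network cannot capture fine spatial structure; generated
  regions reproduce distribution-level statistics (mean color, coarse
  shape) rather than sharp symptom morphology. Scaling up requires swapping
  in a convolutional/attention network behind the same callable contract.
- Global-form SSIM ignores local structure by design; use the windowed
  variant for spatially resolved comparison.
- Otsu extraction assumes a single leaf on a roughly uniform background;
  cluttered scenes need the external-segmenter seam.
- The toy extractor's FID/KID values are not comparable to
  pretrained-Inception numbers.
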