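# Methods

## Model

The package implements unsupervised anomaly segmentation by healthy-image
reconstruction with a denoising diffusion model. The forward process is the
standard variance-preserving corruption

    q(x_t | x_0) = N(√ᾱ_t x_0, (1 − ᾱ_t) I),
    x_t = √ᾱ_t x_0 + √(1 − ᾱ_t) ε,

with a linear schedule β_t from 1e−4 to 0.02 over T = 1000 steps (ᾱ_T ≈
4e−5, i.e. near-total signal destruction at the chain end). ε is not
Gaussian by default but multi-octave simplex noise; the model assumptions
tolerate this because the fields are standardised to zero mean and unit
variance, and summing octaves pushes the amplitude distribution toward
normality while retaining low-frequency dominance.

A noise-prediction network ε_θ(x_t, t) is trained on healthy images only,
minimising E‖ε − ε_θ(x_t, t)‖² with t uniform on {1..T}. Two reconstruction
routes are implemented:

* **iterative (DDPM)**: x_{t−1} = (x_t − β_t/√(1−ᾱ_t) ε_θ)/√α_t + σ_t z,
  run from t = λ down to 1 — λ network evaluations;
* **single-step**: x̂_0 = (x_λ − √(1−ᾱ_λ) ε_θ(x_λ, λ))/√ᾱ_λ — one network
  evaluation. This is the exact algebraic inversion of the closed-form
  forward equation using the predicted noise in place of the true noise.

Partial diffusion (λ ≪ T, default 300, window 250–400) preserves global
anatomy so the model can reconstruct a plausible healthy version of the
input; anomalies — absent from the training distribution — are replaced by
healthy tissue, and the squared difference (x_0 − x̂_0)² localises them.

## Fixed choices the literature leaves open

* **Reverse-step variance**: σ_t² = β_t (the simpler of the two standard
  fixed-variance choices); deterministic mode and the final step t = 1 use
  z = 0.
* **Single-step formula**: the closed-form inversion above; the reconstruction
  is clipped to the declared intensity range before the error map is
  computed (the unclipped estimate is available via `clip=None`).
* **Threshold semantics**: τ applies to the squared error of unit-range
  [0, 1] images; τ = 0.3 therefore corresponds to an amplitude difference of
  √0.3 ≈ 0.55. This calibration suits high-contrast MRI anomalies; lower
  contrast data needs a smaller τ (the phantom benchmark tunes τ on a
  validation split for exactly this reason, typically landing near 0.15).
* **Postprocessing**: 3×3 binary dilation, then keep the largest
  8-connected component (keep_k = 1) with area ≥ 5 px. Connectivity and the
  number of kept regions are configurable.
* **Ensemble**: votes are counted on the pre-postprocessing thresholded
  masks at λ ∈ {250, 300, 350, 400}; the default vote requirement is the
  majority ⌈M/2⌉; postprocessing is applied once to the voted mask.
* **λ selection**: fixed per run by default (λ = 300); a seeded uniform draw
  from the window is available by passing `lam=None`.

## Network

The noise predictor is a UNet in the DDPM lineage: residual blocks
(GroupNorm → SiLU → 3×3 conv, twice, with the sinusoidal timestep embedding
linearly projected and added channel-wise between them; zero-initialised
second conv), multi-head self-attention blocks (pre-norm, 1×1 qkv,
zero-initialised output projection) at configured spatial resolutions,
stride-2 convolution downsampling and nearest-neighbour upsampling. The
decoder mirrors the encoder with one concatenated pass-through skip per
resolution; the bottleneck is residual/attention/residual. This symmetric
skip topology (rather than the one-skip-per-residual-block variant of some
DDPM codebases) roughly halves decoder compute on a CPU and satisfies the
same contract: skips connect equal resolutions, output shape equals input
shape.

The network and its training are implemented directly on numpy with
hand-written reverse-mode gradients (the test suite checks every layer and
the assembled UNet against central finite differences at 1e−5 relative
tolerance). Parameters are float32; diffusion arithmetic is float64.

Two profiles ship:

| | paper | mini |
|---|---|---|
| image size | 256 | 64 |
| base channels | 128 | 16 |
| channel multipliers | 1,1,2,3,4 | 1,2,2 |
| residual blocks / level | 2 | 1 |
| attention resolutions | 32, 16 | 16 |
| attention heads | 2 | 2 |
| dropout | 0 | 0 |
| T / schedule | 1000 linear(1e−4, 0.02) | same |
| optimiser | AdamW lr 1e−4, β 0.9/0.999, wd 0 | AdamW lr 3e−4 |
| EMA decay | 0.9999 | 0.995 |
| batch size | 1 | 1 |
| iterations | 100 000 | 2000 |

The mini profile is the package's own desk-scale design: attention
resolutions are the full-scale ones rescaled by the 256→64 image ratio; the
learning rate is raised and the EMA shortened because 2000 updates would
otherwise leave the average dominated by the initialisation. Inference uses
the EMA parameters.

## Noise generator

2D simplex noise is generated on a skewed triangular lattice with a seeded
256-entry gradient permutation table; per-sample variation comes from random
lattice translations per octave (the gradient table itself is fixed by the
seed, so identical specs reproduce identical fields, while a persistent
generator yields a fresh field per training iteration). Octave k runs at
frequency ν·2ᵏ with amplitude γᵏ; defaults ν = 2⁻⁶ cycles/pixel, N = 6
octaves, γ = 0.8. ν is interpreted as cycles per pixel, giving a 64-pixel
characteristic scale on a 256-pixel image. Each summed field is standardised
per sample to exactly zero mean and unit variance, as the forward equation
assumes unit-variance noise.

## Synthetic phantoms

The phantom generator emulates the one property the method actually relies
on: a single-class population with stable global structure. Each sample is a
soft-edged ellipse (semi-axes 0.30–0.38 of the image, small jitter in
centre, size and orientation), a gentle radial intensity falloff from 0.5,
smooth Gaussian-filtered texture of amplitude 0.05, and an exactly-zero
background; pairwise correlation between samples exceeds 0.8. Anomalies are
soft-edged disks (radius 4–8 px, intensity offset +0.4, 1.5 px taper)
painted inside the shape, so the ground-truth mask — the set of modified
pixels — is exact by construction, and the offset is a calibrated difficulty
dial (detection collapses as it approaches 0).

What the phantoms do **not** emulate: MRI physics (bias fields, Rician
noise, partial-volume effects), anatomical variability across subjects,
heterogeneous or infiltrating lesion appearance, and 3D context. Passing the
phantom benchmark therefore demonstrates that the machinery — schedules,
samplers, training, thresholds, metrics — is correct and that the method's
core mechanism works on a faithful single-class population; it does not
certify clinical performance, which requires the real volumes and full-scale
training.

## Problem sizes used by the tests and the reproduction script

The end-to-end benchmark trains the mini profile on 200 healthy 64×64
phantoms for 2000 iterations (~4 minutes on one CPU core), tunes τ on 10
validation phantoms, and evaluates on 50 held-out anomalous phantoms at
λ = 300, against an untrained network (τ tuned identically) and random masks
of equal area, plus a 25-phantom sweep over anomaly offsets {0.4, 0.2, 0.1}.
Representative results (seed 1): mean IoU ≈ 0.84 trained vs ≈ 0.035 untrained
and ≈ 0.013 random; mean pixel AUC ≈ 0.97. The bit-reproducibility check runs
a reduced 32×32/150-iteration pipeline twice, since the property under test
is determinism, not quality. Unit tests exercising training use the same
reduced size.

## Numerical notes and degenerate cases

* Schedules validate β_t ∈ (0,1) and strict monotonicity of ᾱ; timesteps
  are 1-based.
* The single-step inversion is exact to machine precision when fed the true
  noise; the acceptance check bounds it at 1e−5 before clipping.
* Constant slices contrast-stretch to all zeros rather than dividing by a
  zero window; constant simplex fields (impossible at supported sizes)
  raise.
* Empty-vs-empty masks score Dice = IoU = precision = recall = 1; empty
  prediction against non-empty truth scores 0. Pixel AUC raises on
  single-class truth rather than returning a placeholder.
* Mean/std aggregation uses the population standard deviation.
* The evaluation counter on the denoiser handle is the sole mechanism for
  asserting the O(1) vs O(λ) sampling claim; no test measures wall-clock
  for it.

## Known limitations

* CPU-scale training only; the full 256×256 profile builds and runs forward
  passes but training it to convergence is out of reach without accelerator
  support.
* The slice pipeline is strictly 2D; volumes are segmented slice-wise.
* Checkpoints store raw arrays (npz); no format migration is attempted.
* A layer instance caches one in-flight forward pass, so handles are not
  re-entrant or thread-safe.
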