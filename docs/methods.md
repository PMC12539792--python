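# Methods

This note documents the models, estimators, samplers, and numerical
conventions implemented in `idealobs`, the choices made where the design
was open, and what the synthetic studies do and do not demonstrate.

## Imaging model

Square images of side `N` (default 64) with 0-based integer pixel-center
coordinates `r_m = (row, col)`. Under the signal-present hypothesis,

    g = A_s · s_ref + b + n,

where `n` is i.i.d. Gaussian pixel noise of sd `σ_n`, and `s_ref` is the
unit-amplitude signal after blur by an isotropic Gaussian point response
function (PRF) of height `h` and width `w_m`. Because a Gaussian signal of
width `w_s` convolved with a Gaussian PRF is again Gaussian, the signal
image is evaluated in closed form,

    s_ref[m] = h w_s² / (w_m² + w_s²) · exp(−‖r_m − r_s‖² / (2(w_m² + w_s²))),

with no explicit convolution. Setting `w_m = 0` (allowed; `h` then acts as
a plain peak height) recovers an unblurred Gaussian signal, which the lumpy
task uses.

Two preset tasks:

| parameter | `sks_bke_gaussian` | `sks_bks_lumpy` |
|---|---|---|
| image side | 64 | 64 |
| signal center `r_s` | (32, 32) | (32, 32) |
| signal width `w_s` | 1 | 3 |
| PRF `h`, `w_m` | 16, 3.87 | 1, 0 (no blur) |
| noise sd `σ_n` | 40 | 0.01 |
| amplitude prior | N(9, 4²) | U(0.05, 0.15) |
| utility width `σ_u` | 3 | 0.05 |
| background | zero (known exactly) | lumpy, random |

Amplitudes drawn from N(9, 4²) are not truncated at zero (negative draws
have prior probability ≈ 0.012 and the conjugate algebra handles them
exactly). Signal-absent images store NaN as their amplitude so accidental
use in a utility computation fails loudly rather than silently scoring 0.

Simulation splits one root seed into separate amplitude / background /
noise streams, so switching the background model on or off leaves the
noise and amplitude draws untouched — useful for paired comparisons.

## Latent generators

A `LatentGenerator` maps `z ~ N(0, I_k)` deterministically to an image;
this is the contract a trained deep generative model would satisfy, and
adapters for external generators only need to provide `latent_dim`,
`generate`, and (for signal models) `param_readout`.

* **Exact signal generator** (SKS/BKE): `k = 1`,
  `θ(z) = μ_A + σ_A z`, `s(z) = θ(z) · s_ref`. The push-forward of the
  latent prior equals the amplitude prior exactly, so latent-space
  posterior sampling is amplitude posterior sampling with no model error.
* **Lumpy background generator** (SKS/BKS): the latent vector encodes lump
  centers through `centers = N · logistic(z)` (a fixed random mixing matrix
  maps `z` to center coordinates when `latent_dim ≠ 2·n_lumps`), and the
  image is a superposition of `n_lumps` Gaussian blobs, min–max normalized
  to [0, 1] per image, mirroring intensity-normalized clinical image
  ensembles. The logistic map keeps `generate` smooth in `z`, so pCN moves
  change the image continuously. Blobs are evaluated on a window of 4
  widths around each center (truncation < 4·10⁻⁴ of the magnitude, far
  below the task's noise floor); this truncated form *is* the model.
  Defaults (20 lumps, width 4, magnitude 1 before normalization) were
  chosen so that lumps are comparable in scale to the signal — the regime
  where backgrounds genuinely confound detection.

Generators are validated spectrally: per image the mean is removed, the 2-D
DFT squared modulus is averaged within integer annuli indexed by the
**ceiling** of the Euclidean distance from the Fourier center, averaged
over images, and normalized to unit maximum. The ceiling convention makes
the maximum radial index 46 for 64×64 and 182 for 256×256 images. No
window or zero-padding is applied. Curves are compared by maximum absolute
difference.

## Analytic ideal observer (conjugate SKS/BKE)

With zero background and Gaussian prior/noise, the amplitude posterior
given `g` under H1 is Gaussian with

    v     = σ_n² σ_A² / (σ_n² + σ_A² ‖s_ref‖²)
    Â(g)  = (σ_A² ⟨s_ref, g⟩ + σ_n² μ_A) / (σ_n² + σ_A² ‖s_ref‖²),

and marginalizing the amplitude gives the exact log likelihood ratio

    log Λ(g) = ½ log(v/σ_A²) + Â(g)²/(2v) − μ_A²/(2σ_A²).

This exact log marginal ratio is the package's canonical detection
statistic: EROC analysis is invariant under strictly monotone transforms,
so any display form of the same statistic produces identical curves, and
agreement with an independent quadrature oracle is asserted by rank
correlation rather than by value equality (the published compact form of
the statistic is typographically ambiguous about denominator placement).

Since the Gaussian utility integrates in closed form against a Gaussian
posterior, the utility-weighted posterior mean is

    U(g) = σ_u / √(σ_u² + v),

*independent of g* in the conjugate case. Consequence: the hybrid statistic
`Λ(g)·U(g)` has exactly the ranks of `Λ(g)`, which is why the analytic and
hybrid observers are statistically equivalent on this task — the MCMC
estimate of `U(g)` can only add zero-mean rank jitter.

Quadrature oracles (adaptive 1-D integration over `[μ_A − 8σ_A, μ_A + 8σ_A]`,
integrands exponent-shifted by their maximum for stability) re-derive the
posterior moments, `log Λ`, and `U(g)` without the closed forms; they
back the unit tests and the conjugate MCMC validation.

## Posterior sampling

`U(g)` is estimated as `Û(g) = (1/J) Σ_j u(θ̂(g), θ_j)` over posterior
samples `θ_j`.

**SKS/BKE (latent pCN).** One chain per image in the generator's latent
space; pCN proposal `z* = √(1−β²) z + β ξ` with prior-reversibility making
the acceptance ratio a pure likelihood ratio. Defaults `J = 2000` retained
samples after 500 burn-in, `β = 0.2`, `z₀` drawn from the prior, no
thinning; the conjugate-oracle tests confirm these suffice. For the exact
(linear-in-`s_ref`) generator the likelihood difference depends on the
image only through `⟨s_ref, g⟩`, which lets all per-image chains advance in
lockstep with vectorized arithmetic; each chain remains an ordinary
sequential Metropolis–Hastings run, and the generic image-space path
through the generator contract is tested against the same oracle. With
`β = 0.2` the measured acceptance rate on this task is ≈ 0.94 — the 1-D
latent posterior is nearly as wide as the prior, so pCN accepts almost
everything; the acceptance-rate diagnostic (healthy band (0.1, 0.9))
therefore warns on this task, by design.

**SKS/BKS (joint chains).** State `(θ, z)`: symmetric Gaussian proposal on
the amplitude (uniform prior; out-of-support candidates rejected before any
likelihood evaluation, preserving detailed balance for the truncated
prior) and pCN on the background latent, accepted jointly with the
likelihood-ratio probability. The general prior/proposal-weighted
acceptance ratio is supported through optional callables and tested to
coincide with the simplified one whenever the simplifying conditions hold.
With `σ_n = 0.01` over 4096 pixels the posterior is extremely concentrated:
step sizes default to `β = 2·10⁻⁴` and amplitude-proposal sd 0.002 (chosen
by an acceptance-rate pilot, mean acceptance ≈ 0.3–0.5), and the latent
block is initialized at the simulator's recorded background latent — a
prior-initialized chain cannot reach the posterior's support region in any
reasonable run, and burn-in from the recorded latent still has to find the
joint `(θ, z)` mode. Chains across images are independent; results do not
depend on scheduling.

All acceptance arithmetic is in the log domain with
`log p_a = min(0, Δ)`; residual norms up to 10⁶ cannot overflow.

Monte Carlo standard errors use batch means (20 batches). The sample-based
estimator `argmax_grid (1/J) Σ_j u(candidate, θ_j)` provides a
training-free realization of the ideal estimator; ties break toward the
smaller amplitude.

## Learned observers

The detection network approximates `Pr(H1|g)` by minimizing mean binary
cross-entropy; `Λ = [p/(1−p)]/prior_odds` with equal class priors assumed
(balanced sets). The estimation network minimizes the negative mean
Gaussian utility against the true amplitudes, warm-started with a few
squared-error epochs because the utility loss has vanishing gradients far
from the truth.

Architecture is configuration, not contract. The default is a
shrinkage-regularized **linear** readout over 4×4-average-pooled,
standardized pixels: for these low-contrast Gaussian tasks the ideal
statistic is essentially linear in the image, and measured on the SKS/BKE
task at 10⁴ training images a hidden layer only adds estimation variance
(≈ 0.01–0.03 AUC loss); hidden layers remain available via
`NetHyperparams(hidden_sizes=...)`. Training is full-batch gradient
descent with momentum and a ridge penalty, output layer initialized at
zero: at the shrinkage levels these tasks need, stochastic-gradient noise
and adaptive per-parameter step normalization both measurably distort the
learned template, while deterministic ridge-path descent reproduces the
efficient strongly-shrunk solution. 90/10 train/validation split with
early stopping on validation loss; everything is seeded.

Every learned component has a closed-form or sample-based substitute, and
the default ("oracle") pipeline — including everything the acceptance
script computes — runs with zero training. On the lumpy task, where no
analytic `Λ` exists, the learned detection net supplies the statistic for
*both* the hybrid and the sub-ideal observer, and the learned estimator
supplies both observers' amplitude estimates, so their comparison isolates
the `U(g)` factor. (On that task the single-pass estimation net does no
better than predicting the prior midpoint — background variability masks
the amplitude unless the background is inferred, which is exactly the
MCMC's job.)

## EROC / AEROC

For threshold `t`, the curve plots
`y(t) = (1/N1) Σ_i u_i · 1[T_i > t]` (utility averaged over *all*
signal-present cases, so the curve is non-decreasing and its right
endpoint is the mean utility) against `x(t) = (1/N0) #{j: T_j > t}`, with
thresholds at midpoints between distinct pooled statistic values plus
±∞ sentinels. The trapezoidal area then equals the two-sample form

    AEROC = (1/(N1 N0)) Σ_i Σ_j u_i (1[T_i > T_j] + ½·1[T_i = T_j])

exactly (asserted to 10⁻¹²); ties get half credit. With `u ≡ 1` the AEROC
is the Wilcoxon AUC. Uncertainty is a stratified case bootstrap (resample
within each class, 2000 resamples default, 95% percentile half-width);
paired comparisons resample the same case indices for both observers.
Note the bootstrap half-width at 400+400 images is ≈ 0.03 — consistent
with the Hanley–McNeil closed form for an AUC-type statistic at these
sample sizes.

Curve comparison interpolates both curves onto the union of their fpf
grids; dominance means nowhere lower on that grid. Curves carry a hash of
the evaluation batch's pixel data, and comparing curves from different
batches is an error.

## Problem sizes

The shipped studies use: SKS/BKE, 400+400 evaluation images with 2000
retained samples per chain (seconds on one CPU); SKS/BKS, 2000 images per
class for network training and 100+100 evaluation images with 1000
retained joint-chain samples per image (a few minutes). The SKS/BKS
evaluation size trades Monte Carlo resolution for turnaround; the ordering
property it checks (hybrid ⪰ sub-ideal) is resolved well beyond its
bootstrap uncertainty at this size.

## What the synthetic studies do and do not show

The conjugate SKS/BKE study validates the full hybrid machinery against an
exact closed form — sampler, utility estimator, statistic composition, and
EROC analysis — with zero model error in the generator. The lumpy SKS/BKS
study exercises the regime the method exists for (no tractable likelihood
in image space, posterior reachable only through a generator) and checks
the ideal-observer ordering against the sub-ideal bound. Neither study
involves a *trained* generative model: generator model error — a trained
generator whose push-forward only approximates the true signal/object
distribution — is exactly what the latent-generator contract abstracts
away, so passing tests here say nothing about how well any particular GAN
captures a real image ensemble (the spectral diagnostic is a necessary,
second-order-only check, not a sufficient one). Real backgrounds are also
far richer than smooth lump superpositions, and the lumpy task's
concentrated posterior (noise sd 0.01) makes its chains short-range
samplers around an informed initialization rather than global explorers.

## Known limitations

* Amplitude is the only random signal parameter; location/shape estimation
  and multi-signal images are out of scope.
* No adaptive step-size tuning, tempering, or convergence diagnostics
  beyond batch-means standard errors and acceptance-rate warnings.
* The analytic observer exists only for the Gaussian-prior BKE task; for
  the uniform-prior or random-background tasks only bounds (sub-ideal
  ordering) are available.
* Bootstrap uncertainty is the declared convention throughout; no analytic
  AUC variance estimators are provided.
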