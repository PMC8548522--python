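# Methods

## Model

A tracked particle's position in each spatial dimension is modeled as a
Gaussian process with the fractional-Brownian-motion (FBM) kernel

    Σ_{D,α}(t, t′) = D (|t|^α + |t′|^α − |t − t′|^α),

the unique covariance of a Gaussian process with stationary increments and
power-law variance, pinned at the origin (B(0) = 0). The two parameters are
the apparent diffusion coefficient `D` (units length²·time^(−α)) and the
anomalous exponent `α ∈ (0, 2)`; `α = 1` is ordinary Brownian motion
(Σ = 2D·min(t, t′)), `α < 1` sub-diffusion, `α > 1` super-diffusion. The
mean squared displacement implied by the kernel is ⟨r²⟩ = 2·n_dims·D·t^α.

Observations add independent Gaussian localization noise, entering the
covariance as a diagonal term σ_i² δ_ij; occluded frames are simply absent
rows, which the GP handles natively (no imputation). Spatial dimensions are
independent GPs sharing (D, α), so the total log-likelihood is the sum over
dimensions — consistent with the n-degrees-of-freedom MSD convention.

### Time anchoring

Each track is re-referenced to its first observation: the analysis uses the
displacements r(t_i) − r(t_0) at times t_i − t_0, i ≥ 1, and the anchor
point is consumed. This pins the latent path at the origin and avoids a
singular covariance row at t = 0. Anchored displacements have exactly zero
mean under the model, so the constant per-dimension offset μ is fixed at 0
by default; `mu_mode="free"` estimates it instead (profiled in closed form
for the MAP, sampled by MH) for tracks with genuine drift or offset.
Fitting μ when it is truly 0 is not free: it absorbs part of the path's own
excursion and measurably inflates the D error on the benchmark, which is
why fixed is the default. One knowingly accepted approximation: the
anchor's own localization noise would, strictly, add a rank-one σ₀²·11ᵀ term
to the displacement noise covariance; we keep the diagonal-only form. For
the noise levels in scope (σ ≲ 0.25 px against multi-pixel excursions) the
effect on the estimates is negligible, and it keeps the covariance assembly
identical for single tracks and ensembles.

### Substrate motion

When K ≥ 2 particles share a cell, their observed motion is modeled as
r_k(t) = a_k(t) + R(t): an own FBM a_k plus one shared FBM substrate R
(cell displacement, drift, media flow). Marginalizing R yields a joint
Gaussian over the stacked tracks with block covariance

    diag blocks:  Σ_k + Σ_R + diag(σ_k²)
    off-diag:     Σ_R   (for every particle pair)

so the substrate appears on every block and induces the cross-correlation
that identifies it. Tracks anchored at different absolute times are coupled
through the increment covariance
Cov[B(t)−B(u), B(s)−B(v)] = D(|t−v|^α + |s−u|^α − |t−s|^α − |u−v|^α),
which reduces to the standard kernel on shifted times when anchors
coincide. The substrate mean is fixed at 0 (particle means absorb any
constant offset; the pair (μ_k, μ_R) is not separately identifiable).

### Substrate path reconstruction

The conditional distribution of R given all tracks is computed as a GP
conditional under the joint covariance: ⟨R⟩ = Σ_{R,joint} J⁻¹ (r − μ) with
pointwise variance Σ_R − Σ_{R,joint} J⁻¹ Σ_{R,joint}ᵀ. On a common grid this
is algebraically the precision form
(Σ₁⁻¹ + Σ₂⁻¹ + Σ_R⁻¹)⁻¹ (Σ₁⁻¹(r₁−μ₁) + Σ₂⁻¹(r₂−μ₂)). The overall sign of
this expression is easy to get wrong when assembled from the three-block
precision matrix; we resolved it by simulation: the implemented conditional
mean minimizes the mean squared error against the true simulated substrate
path, while its negation mirrors it (test
`test_sign_convention_minimizes_error`). The reconstruction quality grows
with D_R relative to the particle D's.

## Inference

**Parameterization.** θ = (log D, log(α/(2−α)), μ). Flat priors are placed
in natural (D, α, μ) space; the sampler applies the Jacobian
|dD/dθ₁|·|dα/dθ₂| = D·α(2−α)/2 explicitly.

**MAP.** Nelder-Mead simplex over (log D, logit(α/2)); μ is 0 by default.
In `mu_mode="free"` the Gaussian likelihood is quadratic in μ, so the
optimal μ̂ = (1ᵀA⁻¹r)/(1ᵀA⁻¹1) per dimension (for ensembles, a K×K
normal-equation solve per dimension) is substituted in closed form —
profiling changes nothing about the optimum, it only removes flat
directions from the simplex.
Three starts: an MSD-based moment estimate (clipped into the domain) plus
two fixed perturbations; best final value wins, ties broken toward lower α.
Failure to converge flags the result rather than raising.

**Posterior sampling.** Per-coordinate Gaussian random-walk
Metropolis–Hastings initialized at the MAP. Proposal scales adapt every 50
iterations during burn-in toward 20–40% acceptance and are frozen
afterwards (preserving detailed balance for the retained samples).
Defaults: 10,000 samples after 2,000 burn-in; the calibration studies in
this repository use shorter chains (1,200–1,500 samples), which already
localize the 95% quantiles to within a few percent. Chains are reproducible
from the seed.

**Ensembles.** The joint fit optimizes (D_k, α_k) for each of 2–5 particles
plus (D_R, α_R) — 2K+2 free coordinates. Two starts: substrate initialized
at half, then at 5%, of the median independent-fit D. In 2K+2 ≥ 6
dimensions a plain simplex stalls well short of the optimum (verified
against restarts from the truth), so the joint fit uses L-BFGS-B with
finite-difference gradients followed by a short simplex polish — an order
of magnitude faster and it reaches the same optimum the restarted simplex
eventually finds. Single-track fits keep the plain simplex (2-D, no such
pathology). The independent (uncorrected) per-track fits are always
computed and returned alongside for comparison. Tracks with non-overlapping
time windows trigger a warning and fall back to independent fits with a
negligible substrate.

**Interpolation.** Standard GP conditioning under the fitted kernel with
the localization-noise diagonal. The prior mean is μ for t > 0 and 0 at the
pinned origin, so the anchor is returned exactly with a zero-width band;
noiseless observed times are likewise reproduced exactly. Bands are
mean ± 1.96 sd per coordinate.

## Baselines

**MSD.** Sliding-window mean squared displacement
⟨r_n²⟩ = (N−n)⁻¹ Σ (r_{i+n} − r_i)², occlusion-aware (a pair contributes
only if both endpoints were observed), restricted to the first 10% of step
intervals. The model ⟨r²⟩ = 4Dt^α + 2σ² is inverted by ordinary least
squares of log(⟨r²⟩ − 2σ²) on log t ("linear regression" read as log-log
OLS — the conventional choice; it is isolated so a weighted variant can be
swapped in). Lags whose noise-corrected value is non-positive are dropped;
fewer than three usable lags is an estimation failure, and the benchmark
then retries without noise subtraction before giving up on that record.

**DDB.** The 2-D isotropic displacement magnitude at lag t is
Rayleigh-distributed with scale² = 2Dt^α + σ_eff². Magnitudes are pooled
over lags 1–10 by the same sliding window and (D, α) fitted by maximizing
the product likelihood with flat priors. The default is the unbinned
per-displacement likelihood — the bin-width → 0 limit of the histogram
approach, avoiding two undocumented free choices (bin count, range); a
binned Freedman–Diaconis/multinomial mode is provided for comparison.

**Noise-floor convention.** Per-coordinate localization noise σ adds 2σ² to
each coordinate displacement, so both baselines receive the effective scale
σ_eff = √2·σ (making their noise floors 2σ_eff² = 4σ² across two
dimensions — exactly what the simulation produces). Overlapping
displacements are treated as independent by both baselines, as the sliding
window implies; that discarded correlation is precisely the information the
GP likelihood retains.

## Simulator

Paths are sampled exactly: Cholesky of the kernel on the target grid times
standard normal draws, independently per dimension (at N ≈ 250 the cubic
cost is trivial; no circulant embedding needed). A t = 0 anchor row at the
origin is prepended so simulated tracks look like real ones. Corruption
adds i.i.d. N(0, σ²) to every point **including the anchor** (as a real
detector would) and removes round(o·(N−1)) non-anchor points uniformly
without replacement. Path, noise and occlusion use seed-split streams so
each stage is independently reproducible.

The benchmark generator draws (D, α, dt, σ, o) uniformly from
(0.01, 1.5) × (0.01, 1.9) × (0.1, 1.0) × (0.001, 0.25) × (0, 0.8) with
250-point tracks, redrawing dt per trajectory. The substrate study draws
particle (D, α) from (0.1, 1.1) × (0.3, 1.0) and substrate (D_R, α_R) from
(0.1, 1.1) × (0.7, 1.7) at dt = 0.5, σ = 0.1, o = 0.1.

What the simulator does *not* emulate: non-Gaussian diffusion (CTRW,
switching diffusivity), regime crossovers at long times, frame-correlated
noise, motion blur, or detection/linking errors other than clean occlusion.
Passing benchmarks therefore demonstrate correctness *under the FBM
observation model*, not robustness to model violation — that is what the
diagnostics module is for.

## Diagnostics

The empirical velocity autocorrelation
C(τ) = ε⁻²⟨(x(t₀+τ+ε) − x(t₀+τ))(x(t₀+ε) − x(t₀))⟩, averaged over origins,
tracks and dimensions and normalized at τ = 0, is compared with the FBM
prediction ((τ+ε)^α − 2τ^α + |τ−ε|^α)/(2ε^α); ε defaults to one frame and
occluded pairs are dropped, not imputed, keeping the diagnostic model-free.
Self-similarity is checked by rescaling lag-n displacements by
(n·dt)^(−α̂/2) and reporting per-lag KS-normality and excess-kurtosis
statistics plus the maximum pairwise two-sample KS distance across lags
(the collapse statistic). No single "official" Gaussianity statistic is
privileged; both KS and kurtosis are reported.

The variance decomposition uses population variances with member-count
weights — intra = Σ (n_g/N)·var_g, inter = Σ (n_g/N)(mean_g − mean)² — so
the law-of-total-variance identity intra + inter = total holds exactly for
any group sizes (for equal sizes this is the plain group-mean convention).
Singleton groups are excluded with a warning; zero total variance is
flagged degenerate.

## Imaging

Spots are modeled as a rotated 2-D Gaussian
I₀ exp(−½ vᵀ M⁻¹ v) + B_G with M = [[Lx², θLxLy], [θLxLy, Ly²]]; this θ is
a correlation-type parameter bounded in (−1, 1) — deliberately distinct
from the alignment rotation *angle*. Residuals are treated as i.i.d.
Gaussian with the noise variance marginalized out
(log P ∝ −(n/2) log Σ residuals²), fitted by Nelder-Mead in transformed
coordinates (log sizes/intensities, tanh-bounded θ); a short adaptive MH
run around the optimum gives the posterior sd of the center, reported as
the localization error consumed by the diffusion likelihood. Default patch
11×11, centered on the upstream tracker's detection (detection and linking
are out of scope).

Channel alignment composes (scaling)(translation)(rotation)(re-centering)
into one 3×3 matrix and maximizes
−(WH/2) log Σ (I₂(Ω) − I₁)² over (s_x, s_y, d_x, d_y, θ) with the rotation
center fixed at the image center (the likelihood is degenerate in (c, d)
jointly). Intensities are used raw by default with an optional per-frame
median normalization. Resampling is bilinear with border-median fill;
pixel centers sit at integer coordinates, origin top-left, x = column.

## Numerical choices

- Jitter 1e−10 × max(diag) before every Cholesky factorization; solves are
  Cholesky-based throughout (explicit inverses appear only in small test
  oracles).
- Unconstrained coordinates are clamped (α within [1e−9, 2−1e−9]) so a
  wandering simplex cannot step outside the kernel domain.
- Nelder-Mead tolerances: xatol 1e−5 / fatol 1e−7 (single), 1e−4 / 1e−6
  (ensemble), maxiter scaled with dimension.
- Degenerate inputs fail loudly: empty tracks, non-increasing times, D ≤ 0,
  α ∉ (0, 2), fewer than 2 ensemble members, queries before the anchor.

## Reproduction study sizes

The acceptance suite and `scripts/acceptance.py` run scaled-down versions
of the simulation studies, chosen so the orderings and coverages they test
are statistically unambiguous at desk scale: 200 single tracks × 250 points
for the three-way estimator comparison; 40 substrate pairs × 150 points and
a paired 16-replicate 2-vs-5-particle trend at 80 points (the same two
scored particles with and without helper tracks); 150 tracks for
interpolation coverage; 100 tracks × 64 points with 1,200-sample chains for
posterior calibration; 5,000 replicates for simulator fidelity; 400 tracks
per α for the velocity autocorrelation. Coverage assertions use ±3.5
binomial standard errors around 95%.

## Known limitations

- The FBM kernel is the only kernel shipped (the covariance layer is
  pluggable, but confined/Ornstein-Uhlenbeck or crossover kernels are not
  provided).
- Anchor-noise rank-one term ignored (see Time anchoring).
- DDB is 2-D only, matching its derivation; MSD and GP support 1–3
  dimensions.
- Ensemble localization errors use the per-point mean across dimensions in
  the joint covariance (per-dimension σ differs are averaged); single-track
  likelihoods honor per-dimension σ exactly.
- MH adaptation is frozen after burn-in but the chain is not otherwise
  validated; the split-chain mean check and acceptance-rate band are the
  only built-in convergence guards.
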