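# gpfbm

Gaussian-process inference of anomalous diffusion from single-particle
tracks, built around the fractional-Brownian-motion (FBM) kernel

    Σ_{D,α}(t, t′) = D_α (|t|^α + |t′|^α − |t − t′|^α)

For chromatin loci — and most tracked particles in crowded cellular
environments — the mean squared displacement grows as
⟨r²⟩ = 2·n·D_α·t^α with α < 1 (sub-diffusion). Classical estimators (MSD
power-law fits, displacement-distribution fits) reduce a track to isolated
displacements, discarding the temporal correlations that carry much of the
information. This package instead evaluates the **exact Gaussian likelihood
of the whole trajectory** under the FBM kernel, which:

- estimates the apparent diffusion coefficient `D_α` and anomalous exponent
  `α` more precisely than MSD- or displacement-distribution-based (DDB)
  estimators over the same data;
- incorporates per-point localization errors as a diagonal covariance term
  and tolerates occlusions (missing detections) natively;
- interpolates occluded positions with pointwise 95% credible bands;
- and, when two or more particles are tracked in the same cell, separates
  common **substrate motion** (cell displacement, drift) from each
  particle's own diffusion by fitting the joint block covariance
  (diagonal blocks Σ_k + Σ_R + σ²I, off-diagonal blocks Σ_R).

Inference is Bayesian with flat priors: Nelder-Mead for MAP estimates and
an adaptive random-walk Metropolis–Hastings sampler for posterior credible
intervals. A simulator draws exact FBM tracks (single or substrate-coupled)
with controllable noise and occlusion for benchmarking; diagnostics check
the FBM assumptions (velocity autocorrelation, displacement Gaussianity and
self-similarity) and decompose parameter variability into within- and
between-cell parts via the law of total variance. An imaging module refines
tracked spot centers by rotated-2D-Gaussian fitting (with MH-based
localization errors) and registers two-camera channels with an affine
transform.

Intended users: microscopists and quantitative biologists analyzing
live-cell particle-tracking data, and methodologists benchmarking
diffusion estimators.

## Worked example

`examples/01_simulate_and_fit.py` simulates one 250-point sub-diffusive
track (D_α=0.8, α=0.6, frame interval 0.5 s), corrupts it with σ=0.1 px
localization noise and 10% occlusion, and fits it three ways:

```
simulated 250 points, observed 225 after occlusion
truth : D=0.800  alpha=0.600
GP    : D=0.738  alpha=0.680
MSD   : D=0.716  alpha=0.723
DDB   : D=0.720  alpha=0.702
```

All three estimators land near the truth on this easy track; across the
full benchmark ranges the GP estimator's median |relative error| is the
smallest for both parameters (see below). The substrate-correction example
(`examples/03_substrate_correction.py`) shows the effect that matters in
practice — two particles riding a moving substrate (true D=0.40, α=0.50;
substrate D=0.80, α=1.40):

```
particle 0: corrected D=0.374 alpha=0.340 | uncorrected D=1.297 alpha=1.143
particle 1: corrected D=0.395 alpha=0.657 | uncorrected D=1.274 alpha=1.202
substrate estimate: D=0.779 alpha=1.435
correlation of inferred substrate path with truth (x): 0.999
```

Fitting each track alone roughly triples D and doubles α (the substrate
motion is absorbed into the particle parameters); the joint fit recovers
both the particle and substrate parameters and reconstructs the substrate
path itself.

The remaining examples cover posterior sampling, occlusion interpolation
with credible-band coverage, model diagnostics, and spot
refinement/channel alignment. Each prints what it computes and what the
numbers mean. A thin CLI wraps the same pipelines
(`gpfbm simulate|fit|fit-ensemble|interpolate|benchmark|diagnose|refine-spots|align`).

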