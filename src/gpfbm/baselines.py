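"""Reference MSD and displacement-distribution (DDB) estimators.

These are the standard single-particle-tracking baselines the GP approach is
benchmarked against.  Both reduce trajectories to individual displacements,
discarding the higher-order temporal correlations the GP likelihood keeps —
which is exactly why they are less precise.

MSD: sliding-window mean squared displacement
    ⟨r_n²⟩ = 1/(N−n) Σ_i (r_{i+n} − r_i)²,
fitted to ⟨r²⟩ = 4 D t^α + 2σ² by ordinary least squares in log-log space
after subtracting the localization-noise floor.

DDB: the displacement magnitude at lag t is Rayleigh-distributed with scale²
= 2 D t^α + σ² (2-D isotropic diffusion); parameters are fitted by maximum
likelihood pooling lags 1..10, either unbinned (default) or on
Freedman–Diaconis histogram counts (multinomial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .types import DiffusionParams, Trajectory

__all__ = [
    "MSDCurve", "msd_curve", "fit_msd", "fit_ddb", "fit_ddb_samples",
    "EstimationFailure",
]


class EstimationFailure(RuntimeError):
    """Raised when a baseline cannot produce an estimate (too little data)."""


@dataclass(frozen=True)
class MSDCurve:
    """Sliding-window MSD: lag step counts, lag times, values and pair counts."""

    lags: np.ndarray        # step counts n >= 1
    lag_times: np.ndarray   # seconds
    values: np.ndarray      # length² (summed over dimensions)
    counts: np.ndarray      # contributing pairs per lag


def _frame_index(traj: Trajectory) -> tuple[np.ndarray, float]:
    """Map observed times onto an integer frame grid (occlusions = gaps)."""
    t = traj.times - traj.times[0]
    diffs = np.diff(t)
    if diffs.size == 0:
        raise EstimationFailure("trajectory too short")
    dt = np.min(diffs)
    frames = np.rint(t / dt).astype(int)
    return frames, float(dt)


def msd_curve(
    traj: Trajectory, max_lag_fraction: float = 0.1, min_points: int = 10
) -> MSDCurve:
    """Sliding-window MSD over all dimensions, skipping occluded pairs.

    Only the initial ``max_lag_fraction`` of step intervals is used (temporal
    correlations make longer lags unreliable on single tracks); a pair at lag
    n contributes only if both endpoints were observed.
    """
    if traj.n_points < min_points:
        raise EstimationFailure(f"msd_curve needs at least {min_points} points")
    frames, dt = _frame_index(traj)
    n_frames = frames[-1] + 1
    max_lag = max(3, int(np.floor(max_lag_fraction * n_frames)))
    pos = np.full((n_frames, traj.n_dims), np.nan)
    pos[frames] = traj.positions
    lags, times, values, counts = [], [], [], []
    for n in range(1, max_lag + 1):
        d = pos[n:] - pos[:-n]
        ok = ~np.any(np.isnan(d), axis=1)
        if not np.any(ok):
            warnings.warn(f"no valid pairs at lag {n}; lag dropped")
            continue
        sq = np.sum(d[ok] ** 2, axis=1)
        lags.append(n)
        times.append(n * dt)
        values.append(float(np.mean(sq)))
        counts.append(int(ok.sum()))
    return MSDCurve(
        lags=np.asarray(lags), lag_times=np.asarray(times),
        values=np.asarray(values), counts=np.asarray(counts),
    )


def fit_msd(curve: MSDCurve, sigma_mean: float = 0.0) -> DiffusionParams:
    """Invert ⟨r²⟩ = 4 D t^α + 2σ² by log-log ordinary least squares.

    Subtracts the noise floor 2σ², drops lags whose corrected MSD is not
    positive, and regresses log(⟨r²⟩ − 2σ²) on log t: the slope is α̂ and the
    intercept log(4D̂).
    """
    if sigma_mean < 0:
        raise ValueError("sigma_mean must be >= 0")
    corrected = curve.values - 2.0 * sigma_mean**2
    ok = corrected > 0
    if ok.sum() < 3:
        raise EstimationFailure(
            f"only {int(ok.sum())} usable lags after noise subtraction"
        )
    x = np.log(curve.lag_times[ok])
    y = np.log(corrected[ok])
    slope, intercept = np.polyfit(x, y, 1)
    alpha = float(np.clip(slope, 1e-3, 2 - 1e-3))
    D = float(np.exp(intercept) / 4.0)
    return DiffusionParams(D_alpha=max(D, 1e-12), alpha=alpha, mu=np.zeros(2))


def _displacement_samples(traj: Trajectory, max_lag: int = 10):
    """Pooled displacement magnitudes per lag (sliding window, occlusion-aware)."""
    frames, dt = _frame_index(traj)
    n_frames = frames[-1] + 1
    pos = np.full((n_frames, traj.n_dims), np.nan)
    pos[frames] = traj.positions
    out = []
    for n in range(1, max_lag + 1):
        if n >= n_frames:
            break
        d = pos[n:] - pos[:-n]
        ok = ~np.any(np.isnan(d), axis=1)
        if np.any(ok):
            out.append((n * dt, np.linalg.norm(d[ok], axis=1)))
    return out


def _ddb_negloglik(theta, samples, sigma2):
    logD, talpha = theta
    D = np.exp(logD)
    alpha = 2.0 / (1.0 + np.exp(-talpha))
    nll = 0.0
    for t, r in samples:
        s = 2.0 * D * t**alpha + sigma2  # Rayleigh scale²
        nll -= float(np.sum(np.log(r) - np.log(s) - r**2 / (2.0 * s)))
    return nll


def _ddb_negloglik_binned(theta, binned, sigma2):
    logD, talpha = theta
    D = np.exp(logD)
    alpha = 2.0 / (1.0 + np.exp(-talpha))
    nll = 0.0
    for t, edges, counts in binned:
        s = 2.0 * D * t**alpha + sigma2
        cdf = 1.0 - np.exp(-(edges**2) / (2.0 * s))
        p = np.clip(np.diff(cdf), 1e-300, None)
        nll -= float(np.sum(counts * np.log(p)))
    return nll


def fit_ddb(
    traj: Trajectory,
    sigma_mean: float = 0.0,
    max_lag: int = 10,
    binned: bool = False,
) -> DiffusionParams:
    """Maximum-likelihood fit of the Rayleigh displacement model.

    Pools displacement magnitudes at lags 1..``max_lag`` and maximizes the
    product of the θ-integrated densities over (D, α) with flat priors.  The
    default is the unbinned per-displacement likelihood (the bin-width → 0
    limit of the histogram approach); ``binned=True`` uses Freedman–Diaconis
    bins with a multinomial count likelihood instead.
    """
    if traj.n_dims != 2:
        raise ValueError("DDB is defined for 2-D trajectories")
    samples = _displacement_samples(traj, max_lag=max_lag)
    n1 = sum(r.size for _, r in samples[:1])
    if n1 < 10:
        raise EstimationFailure("need >= 10 displacements at lag 1")
    return fit_ddb_samples(samples, sigma_mean, binned=binned)


def fit_ddb_samples(
    samples: list, sigma_mean: float = 0.0, binned: bool = False
) -> DiffusionParams:
    """Fit (D, α) to pooled displacement magnitudes per lag.

    ``samples`` is a list of (lag_time, magnitudes-array) pairs — the form
    the sliding window produces, but usable with magnitudes drawn from any
    source (e.g. straight from the displacement distribution itself).
    """
    sigma2 = float(sigma_mean) ** 2
    if binned:
        data = []
        for t, r in samples:
            iqr = np.subtract(*np.percentile(r, [75, 25]))
            width = 2 * iqr / max(r.size, 1) ** (1 / 3) if iqr > 0 else None
            nbins = max(int(np.ceil((r.max() - r.min()) / width)), 4) if width else 10
            counts, edges = np.histogram(r, bins=min(nbins, 200))
            data.append((t, edges, counts))
        fun, args = _ddb_negloglik_binned, (data, sigma2)
    else:
        fun, args = _ddb_negloglik, (samples, sigma2)

    # moment start: mean square displacement at the shortest two lags
    t1, r1 = samples[0]
    s1 = max(float(np.mean(r1**2)) / 2.0 - sigma2, 1e-8)
    D0 = s1 / (2.0 * t1)
    theta0 = np.array([np.log(max(D0, 1e-8)), 0.0])
    best = None
    for start in (theta0, theta0 + np.array([0.8, 0.6]), theta0 - np.array([0.8, 0.6])):
        res = minimize(fun, start, args=args, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    logD, talpha = best.x
    return DiffusionParams(
        D_alpha=float(np.exp(logD)),
        alpha=float(2.0 / (1.0 + np.exp(-talpha))),
        mu=np.zeros(2),
    )
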