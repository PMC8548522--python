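"""Model-adequacy diagnostics and variance decomposition.

Before trusting FBM-based inference on real tracks, two properties should
hold to a reasonable approximation: displacements are Gaussian and
self-similar (lag-n displacements rescaled by (n·dt)^(α/2) collapse onto one
distribution), and the velocity autocorrelation follows the FBM prediction

    C_ν(τ)/C_ν(0) = ((τ+ε)^α − 2τ^α + |τ−ε|^α) / (2 ε^α),

whose negative dip at τ=ε distinguishes anti-persistent (α<1) motion.

The law of total variance, var(x) = ⟨var(x|y)⟩ + var(⟨x|y⟩), splits the
spread of per-track parameter estimates into within-group (intra-cell) and
between-group (inter-cell) components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import Trajectory

__all__ = [
    "VACFCurve",
    "VarianceDecomposition",
    "empirical_vacf",
    "theoretical_vacf",
    "self_similarity_check",
    "variance_decomposition",
]


@dataclass(frozen=True)
class VACFCurve:
    """Normalized velocity autocorrelation on a lag grid."""

    taus: np.ndarray
    values: np.ndarray
    epsilon: float
    n_pairs: np.ndarray = None


def theoretical_vacf(alpha: float, tau, epsilon: float):
    """FBM velocity autocorrelation, normalized to 1 at τ=0."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    num = (tau + epsilon) ** alpha - 2 * tau**alpha + np.abs(tau - epsilon) ** alpha
    return num / (2 * epsilon**alpha)


def empirical_vacf(
    trajs: list[Trajectory], epsilon: float | None = None, max_lags: int = 20
) -> VACFCurve:
    """Ensemble + time average of the velocity product, occlusions skipped.

    Velocities are finite differences over ε (default one frame interval);
    the product of the lag-τ velocity with the lag-0 velocity is averaged
    over all valid time origins, trajectories and dimensions, then normalized
    by its τ=0 value.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    dts = [float(np.min(np.diff(tr.times))) for tr in trajs if tr.n_points > 1]
    dt = min(dts)
    if epsilon is None:
        epsilon = dt
    e = int(round(epsilon / dt))
    if e < 1:
        raise ValueError("epsilon must be at least one frame interval")
    sums = np.zeros(max_lags + 1)
    counts = np.zeros(max_lags + 1, dtype=int)
    for tr in trajs:
        frames = np.rint((tr.times - tr.times[0]) / dt).astype(int)
        n_frames = frames[-1] + 1
        pos = np.full((n_frames, tr.n_dims), np.nan)
        pos[frames] = tr.positions
        vel = (pos[e:] - pos[:-e]) / epsilon  # velocity at each origin frame
        nv = vel.shape[0]
        for k in range(min(max_lags + 1, nv)):
            prod = vel[k:] * vel[: nv - k]
            ok = ~np.any(np.isnan(prod), axis=1)
            if np.any(ok):
                sums[k] += float(np.sum(prod[ok]))
                counts[k] += int(ok.sum()) * tr.n_dims
    valid = counts > 0
    if not valid[0]:
        raise ValueError("no valid velocity pairs (empty curve)")
    vals = np.where(valid, sums / np.maximum(counts, 1), np.nan)
    vals = vals / vals[0]
    taus = np.arange(max_lags + 1) * dt
    return VACFCurve(taus=taus[valid], values=vals[valid], epsilon=float(epsilon),
                     n_pairs=counts[valid])


@dataclass
class SelfSimilarityReport:
    """Per-lag normality statistics and a cross-lag collapse statistic."""

    lags: np.ndarray
    n_per_lag: np.ndarray
    ks_normality: np.ndarray      # KS distance of rescaled displacements vs N(0, s²)
    excess_kurtosis: np.ndarray
    collapse_ks: float | None     # max pairwise two-sample KS distance
    collapse_pvalue: float | None
    alpha_hat: float
    inconclusive: bool = False


def self_similarity_check(
    trajs: list[Trajectory], lags, alpha_hat: float, min_per_lag: int = 50
) -> SelfSimilarityReport:
    """Check Gaussianity and self-similarity of pooled displacements.

    Lag-n displacements are rescaled by (n·dt)^(−α̂/2); under FBM with
    exponent α̂ every lag then shares one centred normal distribution.
    Reports a KS normality distance and excess kurtosis per lag, and the
    maximum pairwise two-sample KS distance across lags (the collapse
    statistic; undefined with a single usable lag).
    """
    lags = [int(k) for k in lags]
    dt = min(float(np.min(np.diff(tr.times))) for tr in trajs if tr.n_points > 1)
    pooled = {}
    for tr in trajs:
        frames = np.rint((tr.times - tr.times[0]) / dt).astype(int)
        n_frames = frames[-1] + 1
        pos = np.full((n_frames, tr.n_dims), np.nan)
        pos[frames] = tr.positions
        for k in lags:
            if k >= n_frames:
                continue
            d = pos[k:] - pos[:-k]
            d = d[~np.any(np.isnan(d), axis=1)].ravel()
            scale = (k * dt) ** (-alpha_hat / 2.0)
            pooled.setdefault(k, []).append(d * scale)
    usable, ks_list, kurt_list, samples = [], [], [], []
    for k in lags:
        d = np.concatenate(pooled.get(k, [np.empty(0)]))
        if d.size < min_per_lag:
            continue
        usable.append(k)
        s = float(np.std(d))
        ks_list.append(float(stats.kstest(d, "norm", args=(np.mean(d), s)).statistic))
        kurt_list.append(float(stats.kurtosis(d)))
        samples.append(d)
    if not usable:
        return SelfSimilarityReport(
            lags=np.array([]), n_per_lag=np.array([]), ks_normality=np.array([]),
            excess_kurtosis=np.array([]), collapse_ks=None, collapse_pvalue=None,
            alpha_hat=alpha_hat, inconclusive=True,
        )
    collapse, pval = None, None
    if len(usable) >= 2:
        collapse, pval = 0.0, 1.0
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                r = stats.ks_2samp(samples[i], samples[j])
                if r.statistic > collapse:
                    collapse, pval = float(r.statistic), float(r.pvalue)
    return SelfSimilarityReport(
        lags=np.asarray(usable),
        n_per_lag=np.asarray([s.size for s in samples]),
        ks_normality=np.asarray(ks_list),
        excess_kurtosis=np.asarray(kurt_list),
        collapse_ks=collapse,
        collapse_pvalue=pval,
        alpha_hat=alpha_hat,
        inconclusive=False,
    )


@dataclass(frozen=True)
class VarianceDecomposition:
    """Intra/inter-group split of the total population variance."""

    total: float
    intra: float
    inter: float
    intra_fraction: float
    inter_fraction: float
    degenerate: bool = False
    n_groups: int = 0


def variance_decomposition(groups: dict) -> VarianceDecomposition:
    """Split the variance of grouped estimates into within- and between-group parts.

    ``groups`` maps group id (cell) → sequence of per-track values.  Uses
    population variances with member-count weights, so
    intra + inter = total holds exactly for any group sizes.  Singleton
    groups are excluded with a warning; a zero total variance is flagged
    degenerate (fractions undefined, returned as nan).
    """
    kept = {g: np.asarray(v, dtype=float) for g, v in groups.items()
            if np.asarray(v).size >= 2}
    dropped = set(groups) - set(kept)
    if dropped:
        warnings.warn(f"excluding singleton groups: {sorted(map(str, dropped))}")
    if len(kept) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    allv = np.concatenate(list(kept.values()))
    n = allv.size
    total = float(np.var(allv))
    weights = np.array([v.size / n for v in kept.values()])
    means = np.array([float(np.mean(v)) for v in kept.values()])
    variances = np.array([float(np.var(v)) for v in kept.values()])
    intra = float(np.sum(weights * variances))
    inter = float(np.sum(weights * (means - np.mean(allv)) ** 2))
    if total == 0.0:
        return VarianceDecomposition(0.0, 0.0, 0.0, np.nan, np.nan,
                                     degenerate=True, n_groups=len(kept))
    return VarianceDecomposition(
        total=total, intra=intra, inter=inter,
        intra_fraction=intra / total, inter_fraction=inter / total,
        n_groups=len(kept),
    )


def plot_vacf(curve: VACFCurve, alphas=(0.5, 1.0, 1.5), ax=None):
    """Overlay the empirical VACF with theoretical FBM curves (optional plot)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.taus, curve.values, "o-", label="empirical")
    taus = np.linspace(0, curve.taus.max(), 200)
    for a in alphas:
        ax.plot(taus, theoretical_vacf(a, taus, curve.epsilon), "--",
                label=f"FBM α={a}")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("τ (s)")
    ax.set_ylabel("C_ν(τ)/C_ν(0)")
    ax.legend()
    return ax
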