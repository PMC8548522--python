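"""Fractional-Brownian-motion covariance kernels and Gaussian log-likelihoods.

The FBM kernel is

    Σ_{D,α}(t, t′) = D (|t|^α + |t′|^α − |t − t′|^α),

the unique covariance of a Gaussian process with stationary increments and
power-law variance 2D|t|^α pinned at the origin.  α=1 recovers ordinary
Brownian motion, Σ = 2D·min(t, t′).  Localization errors enter as an
independent diagonal term σ_i²δ_ij.  Multi-particle ensembles that share a
substrate motion get a block covariance with the substrate kernel on every
block (diagonal and off-diagonal alike).

All solves are Cholesky-based; a relative jitter of 1e−10 × max(diag) is
added before factorization.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .types import (
    DiffusionParams,
    EnsembleModel,
    EnsembleSizeError,
    ParameterDomainError,
    Trajectory,
)

JITTER_REL = 1e-10

__all__ = [
    "fbm_covariance",
    "fbm_increment_covariance",
    "add_localization_noise",
    "log_likelihood",
    "ensemble_joint_covariance",
    "ensemble_log_likelihood",
    "chol_with_jitter",
    "mvn_logpdf_chol",
]


def _check_params(D_alpha: float, alpha: float) -> None:
    if not np.isfinite(D_alpha) or D_alpha <= 0:
        raise ParameterDomainError(f"D_alpha must be > 0, got {D_alpha}")
    if not np.isfinite(alpha) or not 0 < alpha < 2:
        raise ParameterDomainError(f"alpha must lie in (0, 2), got {alpha}")


def fbm_covariance(times_a, times_b, D_alpha: float, alpha: float) -> np.ndarray:
    """FBM kernel matrix Σ(t_a, t_b) = D(|t_a|^α + |t_b|^α − |t_a − t_b|^α).

    Symmetric positive semi-definite when ``times_a == times_b``; rows or
    columns at t=0 are identically zero (the path is pinned at the origin).
    """
    _check_params(D_alpha, alpha)
    ta = np.atleast_1d(np.asarray(times_a, dtype=float))
    tb = np.atleast_1d(np.asarray(times_b, dtype=float))
    return D_alpha * (
        np.abs(ta[:, None]) ** alpha
        + np.abs(tb[None, :]) ** alpha
        - np.abs(ta[:, None] - tb[None, :]) ** alpha
    )


def fbm_increment_covariance(
    times_a, anchor_a: float, times_b, anchor_b: float, D_alpha: float, alpha: float
) -> np.ndarray:
    """Covariance of FBM increments taken from two (possibly different) anchors.

    Entry (i, j) is Cov[B(t_i) − B(u_a), B(s_j) − B(u_b)] =
    D(|t_i − u_b|^α + |s_j − u_a|^α − |t_i − s_j|^α − |u_a − u_b|^α).
    With equal anchors this reduces to :func:`fbm_covariance` on the shifted
    times, which is how trajectories re-referenced to their first frame are
    coupled through a shared substrate.
    """
    _check_params(D_alpha, alpha)
    ta = np.atleast_1d(np.asarray(times_a, dtype=float))
    tb = np.atleast_1d(np.asarray(times_b, dtype=float))
    ua, ub = float(anchor_a), float(anchor_b)
    return D_alpha * (
        np.abs(ta[:, None] - ub) ** alpha
        + np.abs(tb[None, :] - ua) ** alpha
        - np.abs(ta[:, None] - tb[None, :]) ** alpha
        - abs(ua - ub) ** alpha
    )


def add_localization_noise(cov: np.ndarray, sigmas) -> np.ndarray:
    """Return ``cov + diag(σ_i²)``; off-diagonals untouched."""
    cov = np.asarray(cov, dtype=float)
    s = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"cov must be square, got shape {cov.shape}")
    if s.size == 1:
        s = np.full(cov.shape[0], float(s.ravel()[0]))
    if s.size != cov.shape[0]:
        raise ValueError(f"len(sigmas)={s.size} does not match cov dim {cov.shape[0]}")
    out = cov.copy()
    out[np.diag_indices_from(out)] += s**2
    return out


def chol_with_jitter(cov: np.ndarray):
    """Cholesky factor of ``cov + εI`` with ε = 1e−10·max(diag).

    Raises a numerical error with a diagnostic if the matrix is not positive
    definite even after jitter.
    """
    cov = np.asarray(cov, dtype=float)
    eps = JITTER_REL * max(float(np.max(np.diag(cov))), 1.0)
    try:
        return cho_factor(cov + eps * np.eye(cov.shape[0]), lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(
            f"covariance not positive definite after jitter {eps:.3e} "
            f"(dim {cov.shape[0]})"
        ) from exc


def mvn_logpdf_chol(resid: np.ndarray, chol) -> float:
    """Multivariate-normal log-density of residual columns under a shared factor.

    ``resid`` is (N,) or (N, n_dims); dimensions are independent and share the
    covariance, so one factorization serves all columns.
    """
    r = np.atleast_2d(np.asarray(resid, dtype=float).T).T  # (N, d)
    n = r.shape[0]
    c, lower = chol
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    sol = cho_solve((c, lower), r)
    quad = np.sum(r * sol, axis=0)
    return float(np.sum(-0.5 * quad - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)))


def log_likelihood(traj: Trajectory, params: DiffusionParams) -> float:
    """Exact Gaussian log-likelihood of a trajectory under the FBM kernel.

    Times are interpreted relative to an implicit origin t=0 where the path
    is pinned (use :meth:`Trajectory.anchored` on raw tracks first).  Each
    spatial dimension is an independent GP sharing (D_α, α); the total is the
    sum over dimensions of the multivariate-normal log-density with mean μ
    and covariance Σ + diag(σ²).
    """
    if traj.n_points < 1:
        raise ValueError("empty trajectory")
    if np.any(traj.times <= 0):
        raise ValueError("log_likelihood requires times > 0 (anchor the track first)")
    mu = params.mu
    if mu.size == 1 and traj.n_dims > 1:
        mu = np.full(traj.n_dims, float(mu[0]))
    if mu.size != traj.n_dims:
        raise ValueError(f"mu has {mu.size} entries for a {traj.n_dims}-D trajectory")
    base = fbm_covariance(traj.times, traj.times, params.D_alpha, params.alpha)
    resid = traj.positions - mu[None, :]
    total = 0.0
    # loc_errors may differ by dimension → factor per dimension only if needed
    sig = traj.loc_errors
    if np.allclose(sig, sig[:, :1]):
        chol = chol_with_jitter(add_localization_noise(base, sig[:, 0]))
        total = mvn_logpdf_chol(resid, chol)
    else:
        for d in range(traj.n_dims):
            chol = chol_with_jitter(add_localization_noise(base, sig[:, d]))
            total += mvn_logpdf_chol(resid[:, d], chol)
    return total


def ensemble_joint_covariance(model: EnsembleModel) -> np.ndarray:
    """Joint covariance of K stacked trajectories sharing a substrate.

    Diagonal blocks are Σ_k(t_k, t_k) + Σ_R(t_k, t_k) + diag(σ_k²); every
    off-diagonal block is the substrate kernel Σ_R across the two tracks'
    observation times.  In the D_R → 0 limit the off-diagonal blocks vanish
    and the joint density factorizes into per-particle likelihoods.
    """
    if model.n_particles < 2:
        raise EnsembleSizeError("need >= 2 trajectories")
    trajs = model.trajectories
    offs = model.anchor_offsets
    sub = model.substrate_params
    sizes = [tr.n_points for tr in trajs]
    ntot = sum(sizes)
    cov = np.zeros((ntot, ntot))
    starts = np.concatenate([[0], np.cumsum(sizes)])
    for i, tri in enumerate(trajs):
        si, ei = starts[i], starts[i + 1]
        pi = model.particle_params[i]
        own = fbm_covariance(tri.times, tri.times, pi.D_alpha, pi.alpha)
        own = add_localization_noise(own, np.mean(tri.loc_errors, axis=1))
        cov[si:ei, si:ei] = own
        for j, trj in enumerate(trajs):
            sj, ej = starts[j], starts[j + 1]
            block = fbm_increment_covariance(
                tri.times + offs[i], offs[i],
                trj.times + offs[j], offs[j],
                sub.D_alpha, sub.alpha,
            )
            cov[si:ei, sj:ej] += block
    return cov


def ensemble_log_likelihood(model: EnsembleModel) -> float:
    """Exact joint log-density of the stacked, mean-subtracted trajectories.

    Dimensions are independent and share the joint covariance, so a single
    Cholesky factorization serves all of them.
    """
    cov = ensemble_joint_covariance(model)
    resid = np.vstack([
        tr.positions - np.broadcast_to(
            p.mu if p.mu.size == tr.n_dims else np.full(tr.n_dims, float(p.mu[0])),
            (tr.n_dims,),
        )[None, :]
        for tr, p in zip(model.trajectories, model.particle_params)
    ])
    chol = chol_with_jitter(cov)
    return mvn_logpdf_chol(resid, chol)
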