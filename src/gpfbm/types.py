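"""Core containers for trajectory-based diffusion inference.

A :class:`Trajectory` holds one particle's observed time series together
with per-point localization errors.  :class:`DiffusionParams` holds the
fractional-Brownian-motion parameters (apparent diffusion coefficient
``D_alpha``, anomalous exponent ``alpha``, constant mean offsets ``mu``).
:class:`EnsembleModel` couples two or more trajectories from the same cell
through a shared substrate motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ParameterDomainError(ValueError):
    """A diffusion parameter lies outside its physical domain."""


class TrajectoryError(ValueError):
    """A trajectory violates its invariants (times, shapes, finiteness)."""


class EnsembleSizeError(ValueError):
    """An ensemble operation was requested with fewer than two particles."""


@dataclass(frozen=True)
class DiffusionParams:
    """FBM parameters for one particle (or the substrate).

    Parameters
    ----------
    D_alpha : float
        Apparent diffusion coefficient, units length²·time^(−α); must be > 0.
    alpha : float
        Anomalous exponent in (0, 2); α=1 is ordinary Brownian motion.
    mu : ndarray, shape (n_dims,)
        Constant per-dimension mean offset, length units. The substrate's
        mean is fixed at zero for identifiability.
    """

    D_alpha: float
    alpha: float
    mu: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "mu", mu)
        if not np.isfinite(self.D_alpha) or self.D_alpha <= 0:
            raise ParameterDomainError(f"D_alpha must be > 0, got {self.D_alpha}")
        if not np.isfinite(self.alpha) or not 0 < self.alpha < 2:
            raise ParameterDomainError(f"alpha must lie in (0, 2), got {self.alpha}")
        if not np.all(np.isfinite(mu)):
            raise ParameterDomainError("mu must be finite")

    def with_mu(self, mu) -> "DiffusionParams":
        return replace(self, mu=np.atleast_1d(np.asarray(mu, dtype=float)))


@dataclass(frozen=True)
class Trajectory:
    """One particle's observed time series.

    ``times`` are strictly increasing (seconds); ``positions`` is (N, n_dims)
    in length units (px or μm); ``loc_errors`` is (N, n_dims) of per-point
    localization standard deviations (0 where unknown).
    """

    times: np.ndarray
    positions: np.ndarray
    loc_errors: np.ndarray | None = None
    track_id: str = "0"
    group_id: str = "0"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        x = np.asarray(self.positions, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if self.loc_errors is None:
            s = np.zeros_like(x)
        else:
            s = np.asarray(self.loc_errors, dtype=float)
            if s.ndim == 0:
                s = np.full_like(x, float(s))
            elif s.ndim == 1:
                if s.shape[0] == x.shape[0]:
                    s = np.repeat(s[:, None], x.shape[1], axis=1)
                else:
                    raise TrajectoryError("loc_errors length does not match times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", x)
        object.__setattr__(self, "loc_errors", s)
        if t.size < 1:
            raise TrajectoryError("trajectory needs at least one point")
        if x.shape[0] != t.size or s.shape != x.shape:
            raise TrajectoryError(
                f"inconsistent shapes: times {t.shape}, positions {x.shape}, "
                f"loc_errors {s.shape}"
            )
        if x.shape[1] not in (1, 2, 3):
            raise TrajectoryError(f"n_dims must be 1, 2 or 3, got {x.shape[1]}")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise TrajectoryError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x)) and np.all(np.isfinite(s))):
            raise TrajectoryError("times/positions/loc_errors must be finite")
        if np.any(s < 0):
            raise TrajectoryError("loc_errors must be >= 0")

    @property
    def n_points(self) -> int:
        return self.times.size

    @property
    def n_dims(self) -> int:
        return self.positions.shape[1]

    def anchored(self) -> "Trajectory":
        """Re-reference the track to its first observation.

        Returns a trajectory of displacements ``r(t_i) − r(t_0)`` at times
        ``t_i − t_0`` for i ≥ 1; the first point is consumed as the anchor,
        which pins the latent path at the origin (B(0)=0) and avoids a
        singular covariance row at t=0.
        """
        if self.n_points < 2:
            raise TrajectoryError("cannot anchor a trajectory with fewer than 2 points")
        return Trajectory(
            times=self.times[1:] - self.times[0],
            positions=self.positions[1:] - self.positions[0],
            loc_errors=self.loc_errors[1:],
            track_id=self.track_id,
            group_id=self.group_id,
        )

    @property
    def anchor_time(self) -> float:
        return float(self.times[0])

    @property
    def anchor_position(self) -> np.ndarray:
        return self.positions[0]


@dataclass(frozen=True)
class EnsembleModel:
    """Two or more same-cell trajectories sharing a substrate motion.

    ``trajectories`` are expected in *anchored* form (times > 0 relative to a
    common origin where every latent path is pinned at zero).
    ``anchor_offsets`` give each track's anchor time on the common absolute
    clock (all zero when tracks start on the same frame).
    """

    trajectories: tuple
    particle_params: tuple
    substrate_params: DiffusionParams
    anchor_offsets: tuple | None = None

    def __post_init__(self):
        trajs = tuple(self.trajectories)
        pars = tuple(self.particle_params)
        object.__setattr__(self, "trajectories", trajs)
        object.__setattr__(self, "particle_params", pars)
        if len(trajs) < 2:
            raise EnsembleSizeError("an ensemble needs at least 2 trajectories")
        if len(pars) != len(trajs):
            raise ValueError("one DiffusionParams per trajectory required")
        offs = self.anchor_offsets
        offs = tuple(0.0 for _ in trajs) if offs is None else tuple(float(o) for o in offs)
        if len(offs) != len(trajs):
            raise ValueError("one anchor offset per trajectory required")
        object.__setattr__(self, "anchor_offsets", offs)
        ndims = {tr.n_dims for tr in trajs}
        if len(ndims) != 1:
            raise ValueError("all trajectories must share n_dims")
        if np.any(self.substrate_params.mu != 0):
            raise ValueError("substrate mean is fixed at 0 (identifiability)")

    @property
    def n_particles(self) -> int:
        return len(self.trajectories)

    @property
    def n_dims(self) -> int:
        return self.trajectories[0].n_dims
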