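"""Exact FBM trajectory simulation with measurement corruption.

Paths are drawn exactly from the multivariate normal defined by the FBM
kernel on the sample grid (Cholesky sampling; at desk scale, N≈250, there is
no need for circulant embedding).  Measurement corruption adds i.i.d.
Gaussian localization noise to every point and removes a uniformly random
subset of non-anchor points (occlusion).  Substrate-coupled ensembles are
built as r_i(t) = a_i(t) + R(t) with independent FBM draws for each particle
and the substrate.

Random streams for path, noise and occlusion are split from the spec seed so
each corruption stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .kernels import chol_with_jitter, fbm_covariance
from .types import DiffusionParams, EnsembleModel, EnsembleSizeError, Trajectory

__all__ = [
    "SimulationSpec",
    "GroundTruthRecord",
    "simulate_fbm",
    "corrupt",
    "simulate_ensemble",
    "benchmark_dataset",
    "BENCHMARK_RANGES",
]

#: Uniform sampling ranges of the single-trajectory benchmark:
#: apparent diffusion coefficient, anomalous exponent, frame interval,
#: localization noise s.d., occlusion fraction.
BENCHMARK_RANGES = {
    "D_alpha": (0.01, 1.5),
    "alpha": (0.01, 1.9),
    "dt": (0.1, 1.0),
    "sigma": (0.001, 0.25),
    "occlusion": (0.0, 0.8),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated track.

    ``n_points`` counts rows including the anchor at t=0, so a 250-point
    track has 249 sampled increments.
    """

    n_points: int = 250
    dt: float = 0.5
    D_alpha: float = 0.5
    alpha: float = 1.0
    sigma: float = 0.0
    occlusion_rate: float = 0.0
    n_dims: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0 < self.alpha < 2:
            raise ValueError("alpha must lie in (0, 2)")
        if self.D_alpha <= 0:
            raise ValueError("D_alpha must be > 0 (degenerate D=0 rejected)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.occlusion_rate < 1:
            raise ValueError("occlusion_rate must lie in [0, 1)")
        if self.n_dims not in (1, 2, 3):
            raise ValueError("n_dims must be 1, 2 or 3")


@dataclass
class GroundTruthRecord:
    """Everything needed to score an estimator on one simulated instance."""

    particle_params: list
    substrate_params: DiffusionParams | None
    clean: list
    observed: list
    substrate_path: Trajectory | None = None
    spec: dict = field(default_factory=dict)
    seed: int = 0


def _spawn(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def simulate_fbm(spec: SimulationSpec, rng: np.random.Generator | None = None) -> Trajectory:
    """Draw one clean FBM track exactly from its finite-dimensional law.

    Positions at times {dt, 2dt, …} are a multivariate-normal draw with the
    FBM kernel; a t=0 anchor row at the origin is prepended.  Dimensions are
    independent draws sharing (D_α, α).  Deterministic given the spec seed.
    """
    if rng is None:
        rng = np.random.default_rng(_spawn(spec.seed, 1)[0])
    times = spec.dt * np.arange(1, spec.n_points)
    cov = fbm_covariance(times, times, spec.D_alpha, spec.alpha)
    c, _ = chol_with_jitter(cov)
    z = rng.standard_normal((spec.n_points - 1, spec.n_dims))
    x = np.tril(c) @ z
    times = np.concatenate([[0.0], times])
    x = np.vstack([np.zeros((1, spec.n_dims)), x])
    return Trajectory(times=times, positions=x, loc_errors=np.zeros_like(x))


def corrupt(
    traj: Trajectory,
    sigma: float,
    occlusion_rate: float,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Add localization noise and remove occluded points.

    Adds i.i.d. N(0, σ²) to every coordinate and removes
    ``round(o·(N−1))`` non-anchor points uniformly without replacement; the
    anchor (first point) is always retained.  σ is recorded in loc_errors.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0 <= occlusion_rate <= 0.8:
        raise ValueError("occlusion_rate must lie in [0, 0.8]")
    if rng is None:
        rng = np.random.default_rng(_spawn(seed, 1)[0])
    noise_rng, occ_rng = (np.random.default_rng(s) for s in rng.spawn(2))
    x = traj.positions.copy()
    if sigma > 0:
        x = x + sigma * noise_rng.standard_normal(x.shape)
    n = traj.n_points
    n_drop = int(round(occlusion_rate * (n - 1)))
    keep = np.ones(n, dtype=bool)
    if n_drop > 0:
        drop = occ_rng.choice(np.arange(1, n), size=n_drop, replace=False)
        keep[drop] = False
    return Trajectory(
        times=traj.times[keep],
        positions=x[keep],
        loc_errors=np.full((int(keep.sum()), traj.n_dims), sigma),
        track_id=traj.track_id,
        group_id=traj.group_id,
    )


def simulate_ensemble(
    specs: list[SimulationSpec],
    substrate_spec: SimulationSpec,
    seed: int = 0,
) -> tuple[EnsembleModel, GroundTruthRecord]:
    """Simulate K particles riding a common FBM substrate.

    Each observed track is r_i(t) = a_i(t) + R(t) on the shared time grid,
    corrupted per particle after summation.  Returns the (anchored) observed
    ensemble together with the ground truth (clean paths, substrate path,
    generating parameters).
    """
    if len(specs) < 2:
        raise EnsembleSizeError("need >= 2 particle specs")
    grids = {(s.n_points, s.dt) for s in specs}
    if len(grids) != 1:
        raise ValueError("particles must share the time grid before occlusion")
    # len+2 streams: one per particle, the last for the substrate (one spare
    # keeps room for a future noise-only stream without reshuffling draws)
    streams = _spawn(seed, len(specs) + 2)
    sub_clean = simulate_fbm(substrate_spec, rng=np.random.default_rng(streams[-1]))
    clean, observed = [], []
    for k, sp in enumerate(specs):
        rng = np.random.default_rng(streams[k])
        a = simulate_fbm(sp, rng=rng)
        r = Trajectory(
            times=a.times,
            positions=a.positions + sub_clean.positions,
            loc_errors=np.zeros_like(a.positions),
            track_id=str(k),
            group_id="0",
        )
        obs = corrupt(r, sp.sigma, sp.occlusion_rate, rng=rng)
        clean.append(a)
        observed.append(obs)
    model = EnsembleModel(
        trajectories=tuple(tr.anchored() for tr in observed),
        particle_params=tuple(
            DiffusionParams(sp.D_alpha, sp.alpha, np.zeros(sp.n_dims)) for sp in specs
        ),
        substrate_params=DiffusionParams(
            substrate_spec.D_alpha, substrate_spec.alpha, np.zeros(substrate_spec.n_dims)
        ),
    )
    record = GroundTruthRecord(
        particle_params=list(model.particle_params),
        substrate_params=model.substrate_params,
        clean=clean,
        observed=observed,
        substrate_path=sub_clean,
        spec={"particles": [asdict(s) for s in specs], "substrate": asdict(substrate_spec)},
        seed=seed,
    )
    return model, record


def benchmark_dataset(
    n_traj: int,
    ranges: dict | None = None,
    seed: int = 0,
    n_points: int = 250,
) -> list[GroundTruthRecord]:
    """Reproducible single-trajectory benchmark with uniform parameter draws.

    Each record draws (D_α, α, dt, σ, occlusion) uniformly from ``ranges``
    (defaults to :data:`BENCHMARK_RANGES`), simulates a 250-point track and
    corrupts it; the generating parameters are stored as ground truth.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    ranges = dict(BENCHMARK_RANGES if ranges is None else ranges)
    for key, (lo, hi) in ranges.items():
        if not hi > lo:
            raise ValueError(f"empty range for {key}: ({lo}, {hi})")
    records = []
    for child in _spawn(seed, n_traj):
        rng = np.random.default_rng(child)
        draw = {k: rng.uniform(*ranges[k]) for k in
                ("D_alpha", "alpha", "dt", "sigma", "occlusion")}
        spec = SimulationSpec(
            n_points=n_points,
            dt=draw["dt"],
            D_alpha=draw["D_alpha"],
            alpha=draw["alpha"],
            sigma=draw["sigma"],
            occlusion_rate=draw["occlusion"],
        )
        clean = simulate_fbm(spec, rng=rng)
        obs = corrupt(clean, spec.sigma, spec.occlusion_rate, rng=rng)
        records.append(
            GroundTruthRecord(
                particle_params=[DiffusionParams(spec.D_alpha, spec.alpha, np.zeros(2))],
                substrate_params=None,
                clean=[clean],
                observed=[obs],
                spec=asdict(spec),
                seed=int(child.entropy) & 0x7FFFFFFF,
            )
        )
    return records


def write_ground_truth(records: list[GroundTruthRecord], path) -> None:
    """Serialize generating parameters (not the paths) to JSON."""
    out = []
    for rec in records:
        out.append(
            {
                "particles": [
                    {"D_alpha": p.D_alpha, "alpha": p.alpha, "mu": p.mu.tolist()}
                    for p in rec.particle_params
                ],
                "substrate": None
                if rec.substrate_params is None
                else {
                    "D_alpha": rec.substrate_params.D_alpha,
                    "alpha": rec.substrate_params.alpha,
                },
                "spec": rec.spec,
                "seed": rec.seed,
            }
        )
    Path(path).write_text(json.dumps(out, indent=1))
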