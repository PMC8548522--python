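import numpy as np
import pytest

from gpfbm import SimulationSpec, Trajectory, corrupt, simulate_fbm


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def brownian_track():
    """Noiseless 250-point Brownian track (D=1, α=1, dt=0.5)."""
    return simulate_fbm(SimulationSpec(n_points=250, dt=0.5, D_alpha=1.0,
                                       alpha=1.0, seed=7))


@pytest.fixture
def noisy_subdiffusive_track():
    """Sub-diffusive track with 10% occlusion and σ=0.1 noise."""
    spec = SimulationSpec(n_points=250, dt=0.5, D_alpha=0.8, alpha=0.6,
                          sigma=0.1, occlusion_rate=0.1, seed=11)
    clean = simulate_fbm(spec)
    return corrupt(clean, spec.sigma, spec.occlusion_rate, seed=11)


def random_trajectory(rng, n_points=8, n_dims=2, with_noise=True):
    """Small random (not necessarily FBM) trajectory for oracle checks."""
    times = np.cumsum(rng.uniform(0.2, 1.0, size=n_points))
    pos = rng.normal(0.0, 2.0, size=(n_points, n_dims))
    sig = rng.uniform(0.0, 0.3, size=(n_points, n_dims)) if with_noise else None
    return Trajectory(times=times, positions=pos, loc_errors=sig)
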