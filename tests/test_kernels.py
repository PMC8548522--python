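"""Kernel construction and exact Gaussian likelihood evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import cholesky

from gpfbm import (
    DiffusionParams,
    EnsembleModel,
    EnsembleSizeError,
    ParameterDomainError,
    Trajectory,
    add_localization_noise,
    ensemble_joint_covariance,
    ensemble_log_likelihood,
    fbm_covariance,
    log_likelihood,
)

from conftest import random_trajectory


def dense_mvn_logpdf(x, mean, cov):
    """Brute-force multivariate-normal log-density via explicit inverse/det."""
    x = np.asarray(x, dtype=float)
    r = x - mean
    inv = np.linalg.inv(cov)
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return float(-0.5 * r @ inv @ r - 0.5 * logdet - 0.5 * x.size * np.log(2 * np.pi))


class TestFbmCovariance:
    @pytest.mark.parametrize(
        "t, s, D, alpha, expected",
        [
            (1.0, 1.0, 0.5, 1.0, 1.0),          # 0.5·(1+1−0)
            (2.7, 0.0, 1.3, 0.8, 0.0),          # pinned at the origin
            (3.0, 1.0, 1.0, 1.0, 2.0),          # Brownian 2D·min(t,s)
        ],
    )
    def test_pointwise_values(self, t, s, D, alpha, expected):
        assert fbm_covariance([t], [s], D, alpha)[0, 0] == pytest.approx(expected)

    def test_brownian_limit_is_two_D_min(self, rng):
        t = np.sort(rng.uniform(0.1, 10, size=12))
        cov = fbm_covariance(t, t, 0.7, 1.0)
        expected = 2 * 0.7 * np.minimum.outer(t, t)
        np.testing.assert_allclose(cov, expected, rtol=1e-12)

    @given(
        alpha=st.floats(0.05, 1.95),
        D=st.floats(0.01, 5.0),
        dt=st.floats(0.05, 2.0),
        t0=st.floats(0.0, 20.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_stationary_increment_variance(self, alpha, D, dt, t0):
        """Var[x(t+Δ) − x(t)] from the kernel equals 2DΔ^α for all t ≥ 0."""
        t = np.array([t0, t0 + dt])
        cov = fbm_covariance(t, t, D, alpha)
        var_inc = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        assert var_inc == pytest.approx(2 * D * dt**alpha, rel=1e-9, abs=1e-12)

    @given(
        alpha=st.floats(0.05, 1.95),
        times=st.lists(st.floats(0.05, 50.0), min_size=2, max_size=15, unique=True),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_positive_definite_after_jitter(self, alpha, times):
        t = np.sort(np.asarray(times))
        cov = fbm_covariance(t, t, 1.0, alpha)
        eps = 1e-10 * np.max(np.diag(cov))
        cholesky(cov + eps * np.eye(t.size))  # raises if not PD

    @pytest.mark.parametrize("D, alpha", [(-1.0, 1.0), (0.0, 1.0), (1.0, 0.0),
                                          (1.0, 2.0), (1.0, 2.5)])
    def test_domain_errors(self, D, alpha):
        with pytest.raises(ParameterDomainError):
            fbm_covariance([1.0], [1.0], D, alpha)


class TestLocalizationNoise:
    def test_adds_squared_sigmas_to_diagonal(self):
        out = add_localization_noise(np.zeros((2, 2)), [1.0, 2.0])
        np.testing.assert_allclose(out, np.diag([1.0, 4.0]))

    def test_zero_sigma_is_identity(self, rng):
        cov = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(add_localization_noise(cov, np.zeros(4)), cov)

    def test_off_diagonals_unchanged(self):
        cov = fbm_covariance([1.0, 2.0], [1.0, 2.0], 1.0, 1.0)
        out = add_localization_noise(cov, [0.1, 0.1])
        np.testing.assert_allclose(np.diag(out), np.diag(cov) + 0.01)
        assert out[0, 1] == cov[0, 1]

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            add_localization_noise(np.zeros((3, 3)), [1.0, 2.0])


class TestLogLikelihood:
    def test_single_observation_closed_form(self):
        """At t=1 with 2Dt^α=1 the density is a standard normal at 0."""
        tr = Trajectory(times=[1.0], positions=[0.0])
        ll = log_likelihood(tr, DiffusionParams(0.5, 1.0, np.zeros(1)))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-8)

    def test_matches_dense_oracle(self, rng):
        """Exact agreement with an independently assembled dense MVN density."""
        for _ in range(25):
            n = int(rng.integers(2, 11))
            tr = random_trajectory(rng, n_points=n, n_dims=2)
            D = float(rng.uniform(0.05, 2.0))
            alpha = float(rng.uniform(0.1, 1.9))
            mu = rng.normal(size=2)
            ll = log_likelihood(tr, DiffusionParams(D, alpha, mu))
            expected = 0.0
            for d in range(2):
                cov = np.empty((n, n))
                for i in range(n):
                    for j in range(n):
                        ti, tj = tr.times[i], tr.times[j]
                        cov[i, j] = D * (abs(ti) ** alpha + abs(tj) ** alpha
                                         - abs(ti - tj) ** alpha)
                    cov[i, i] += tr.loc_errors[i, d] ** 2
                # the stabilizing jitter is part of the likelihood's covariance
                cov += 1e-10 * max(np.max(np.diag(cov)), 1.0) * np.eye(n)
                expected += dense_mvn_logpdf(tr.positions[:, d], mu[d], cov)
            assert ll == pytest.approx(expected, abs=1e-7)

    def test_translation_invariance(self, rng):
        tr = random_trajectory(rng, n_points=9)
        p = DiffusionParams(0.5, 0.8, np.array([0.3, -0.2]))
        shifted = Trajectory(times=tr.times, positions=tr.positions + 5.0,
                             loc_errors=tr.loc_errors)
        assert log_likelihood(tr, p) == pytest.approx(
            log_likelihood(shifted, p.with_mu(p.mu + 5.0)), rel=1e-12
        )

    def test_per_dimension_loc_errors(self, rng):
        """Dimensions with different σ factor independently but sum correctly."""
        tr = random_trajectory(rng, n_points=6, with_noise=False)
        sig = np.column_stack([np.full(6, 0.1), np.full(6, 0.4)])
        tr2 = Trajectory(times=tr.times, positions=tr.positions, loc_errors=sig)
        p = DiffusionParams(1.0, 1.0, np.zeros(2))
        per_dim = sum(
            log_likelihood(
                Trajectory(times=tr.times, positions=tr.positions[:, d],
                           loc_errors=sig[:, d]),
                DiffusionParams(1.0, 1.0, np.zeros(1)),
            )
            for d in range(2)
        )
        assert log_likelihood(tr2, p) == pytest.approx(per_dim, rel=1e-10)


def _two_particle_model(times, D=0.5, alpha=1.0, D_R=0.5, alpha_R=1.0, sigma=0.0):
    trajs = tuple(
        Trajectory(times=times, positions=np.zeros((len(times), 1)),
                   loc_errors=np.full((len(times), 1), sigma))
        for _ in range(2)
    )
    pars = tuple(DiffusionParams(D, alpha, np.zeros(1)) for _ in range(2))
    return EnsembleModel(trajectories=trajs, particle_params=pars,
                         substrate_params=DiffusionParams(D_R, alpha_R, np.zeros(1)))


class TestEnsembleCovariance:
    def test_two_particles_single_time(self):
        model = _two_particle_model([1.0])
        np.testing.assert_allclose(
            ensemble_joint_covariance(model), [[2.0, 1.0], [1.0, 2.0]]
        )

    def test_substrate_limit_factorizes(self, rng):
        """As D_R → 0 the joint likelihood splits into per-particle terms."""
        times = np.array([0.5, 1.0, 2.0])
        pos = rng.normal(size=(2, 3, 1))
        trajs = tuple(
            Trajectory(times=times, positions=pos[k],
                       loc_errors=np.full((3, 1), 0.05))
            for k in range(2)
        )
        pars = (DiffusionParams(0.4, 0.7, np.zeros(1)),
                DiffusionParams(1.1, 1.2, np.zeros(1)))
        model = EnsembleModel(trajectories=trajs, particle_params=pars,
                              substrate_params=DiffusionParams(1e-14, 1.0, np.zeros(1)))
        joint = ensemble_log_likelihood(model)
        independent = sum(log_likelihood(tr, p) for tr, p in zip(trajs, pars))
        assert joint == pytest.approx(independent, abs=1e-8)

    def test_matches_independent_block_assembly(self, rng):
        """Joint density equals a dense oracle built from blkdiag + rank pattern."""
        times = np.array([0.4, 1.1, 2.3])
        n = times.size
        D1, a1, D2, a2, DR, aR = 0.6, 0.8, 1.2, 1.1, 0.4, 1.4
        pos = rng.normal(size=(2, n, 1))
        sig = 0.1
        trajs = tuple(
            Trajectory(times=times, positions=pos[k],
                       loc_errors=np.full((n, 1), sig))
            for k in range(2)
        )
        model = EnsembleModel(
            trajectories=trajs,
            particle_params=(DiffusionParams(D1, a1, np.zeros(1)),
                             DiffusionParams(D2, a2, np.zeros(1))),
            substrate_params=DiffusionParams(DR, aR, np.zeros(1)),
        )
        # oracle: Cov(r) for r_i = a_i + R with independent FBMs, assembled
        # entry-by-entry from the kernel definition
        def k(ti, tj, D, a):
            return D * (abs(ti) ** a + abs(tj) ** a - abs(ti - tj) ** a)

        cov = np.zeros((2 * n, 2 * n))
        for p in range(2):
            for q in range(2):
                for i in range(n):
                    for j in range(n):
                        v = k(times[i], times[j], DR, aR)
                        if p == q:
                            v += k(times[i], times[j],
                                   (D1, D2)[p], (a1, a2)[p])
                            if i == j:
                                v += sig**2
                        cov[p * n + i, q * n + j] = v
        stacked = np.concatenate([pos[0][:, 0], pos[1][:, 0]])
        expected = dense_mvn_logpdf(stacked, 0.0, cov)
        assert ensemble_log_likelihood(model) == pytest.approx(expected, abs=1e-8)

    def test_correlated_pairs_favor_substrate(self):
        """A shared simulated substrate raises the joint likelihood at the
        generating substrate parameters relative to a near-zero substrate."""
        from gpfbm import SimulationSpec, simulate_ensemble

        specs = [SimulationSpec(n_points=40, dt=0.5, D_alpha=0.3, alpha=0.7)
                 for _ in range(2)]
        sub = SimulationSpec(n_points=40, dt=0.5, D_alpha=0.8, alpha=1.2)
        model, rec = simulate_ensemble(specs, sub, seed=5)
        at_truth = ensemble_log_likelihood(model)
        no_sub = EnsembleModel(
            trajectories=model.trajectories,
            particle_params=model.particle_params,
            substrate_params=DiffusionParams(1e-12, 1.2, np.zeros(2)),
        )
        assert at_truth > ensemble_log_likelihood(no_sub)

    def test_requires_two_particles(self):
        tr = Trajectory(times=[1.0], positions=[0.0])
        with pytest.raises(EnsembleSizeError):
            EnsembleModel(trajectories=(tr,),
                          particle_params=(DiffusionParams(1, 1, np.zeros(1)),),
                          substrate_params=DiffusionParams(1, 1, np.zeros(1)))
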