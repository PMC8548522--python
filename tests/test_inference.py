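"""MAP fitting, posterior sampling, ensemble correction, GP interpolation."""

import numpy as np
import pytest

from gpfbm import (
    DiffusionParams,
    EnsembleModel,
    SimulationSpec,
    Trajectory,
    corrupt,
    fit_ensemble,
    fit_map,
    infer_substrate_path,
    interpolate,
    sample_posterior,
    simulate_ensemble,
    simulate_fbm,
)


class TestFitMap:
    def test_deterministic(self, noisy_subdiffusive_track):
        a = fit_map(noisy_subdiffusive_track)
        b = fit_map(noisy_subdiffusive_track)
        assert a.params.D_alpha == b.params.D_alpha
        assert a.params.alpha == b.params.alpha

    def test_recovers_brownian_parameters(self, brownian_track):
        res = fit_map(brownian_track)
        assert res.params.D_alpha == pytest.approx(1.0, rel=0.35)
        assert res.params.alpha == pytest.approx(1.0, abs=0.15)
        assert res.converged

    def test_alpha_bounded_below_two(self):
        spec = SimulationSpec(n_points=120, dt=0.5, D_alpha=0.5, alpha=1.8, seed=21)
        res = fit_map(simulate_fbm(spec))
        assert 0 < res.params.alpha < 2

    def test_translation_invariance(self, noisy_subdiffusive_track):
        tr = noisy_subdiffusive_track
        shifted = Trajectory(times=tr.times, positions=tr.positions + 17.0,
                             loc_errors=tr.loc_errors)
        a, b = fit_map(tr), fit_map(shifted)
        assert a.params.D_alpha == pytest.approx(b.params.D_alpha, rel=1e-6)
        assert a.params.alpha == pytest.approx(b.params.alpha, abs=1e-6)

    def test_time_rescaling_consistency(self, brownian_track):
        """Multiplying all times by c multiplies D̂ by c^(−α̂)."""
        tr = brownian_track
        c = 3.0
        scaled = Trajectory(times=tr.times * c, positions=tr.positions)
        a, b = fit_map(tr), fit_map(scaled)
        assert b.params.alpha == pytest.approx(a.params.alpha, abs=1e-3)
        assert b.params.D_alpha == pytest.approx(
            a.params.D_alpha * c ** (-a.params.alpha), rel=1e-2
        )

    def test_too_short_track_rejected(self):
        tr = Trajectory(times=[0.0, 1.0, 2.0], positions=np.zeros((3, 2)))
        with pytest.raises(ValueError, match="displacements"):
            fit_map(tr)


class TestSamplePosterior:
    @pytest.fixture(scope="class")
    def track_and_chain(self):
        spec = SimulationSpec(n_points=100, dt=0.5, D_alpha=0.6, alpha=0.9,
                              sigma=0.05, seed=13)
        tr = corrupt(simulate_fbm(spec), 0.05, 0.0, seed=13)
        chain = sample_posterior(tr, n_samples=1500, burn_in=600, seed=3)
        return tr, chain

    def test_seed_reproducibility(self, track_and_chain):
        tr, chain = track_and_chain
        again = sample_posterior(tr, n_samples=1500, burn_in=600, seed=3)
        np.testing.assert_array_equal(chain.samples, again.samples)

    def test_acceptance_rate_in_healthy_band(self, track_and_chain):
        _, chain = track_and_chain
        assert 0.1 < chain.acceptance_rate < 0.6

    def test_posterior_mode_near_map(self, track_and_chain):
        tr, chain = track_and_chain
        res = fit_map(tr)
        med = chain.quantiles()["alpha"][0.5]
        assert med == pytest.approx(res.params.alpha, abs=0.1)
        medD = chain.quantiles()["D_alpha"][0.5]
        assert medD == pytest.approx(res.params.D_alpha, rel=0.25)

    def test_chain_mean_stabilizes(self, track_and_chain):
        """Split-chain check: the two halves agree on the posterior mean."""
        _, chain = track_and_chain
        half = chain.samples.shape[0] // 2
        a = chain.samples[:half, 1]
        b = chain.samples[half:, 1]
        pooled_sd = np.std(chain.samples[:, 1])
        assert abs(a.mean() - b.mean()) < 0.5 * pooled_sd


class TestFitEnsemble:
    def test_negligible_substrate_matches_independent_fits(self):
        specs = [SimulationSpec(n_points=100, dt=0.5, D_alpha=0.5, alpha=0.8,
                                sigma=0.05) for _ in range(2)]
        sub = SimulationSpec(n_points=100, dt=0.5, D_alpha=1e-6, alpha=1.0)
        _, rec = simulate_ensemble(specs, sub, seed=17)
        ef = fit_ensemble(rec.observed)
        for cor, unc in zip(ef.particle_params, ef.uncorrected):
            assert cor.D_alpha == pytest.approx(unc.params.D_alpha, rel=0.15)
            assert cor.alpha == pytest.approx(unc.params.alpha, abs=0.1)

    def test_substrate_correction_improves_estimates(self):
        """With a strong substrate the joint fit beats the independent fits."""
        err_c, err_u = [], []
        for seed in range(6):
            specs = [SimulationSpec(n_points=150, dt=0.5, D_alpha=0.4,
                                    alpha=0.5, sigma=0.1, occlusion_rate=0.1)
                     for _ in range(2)]
            sub = SimulationSpec(n_points=150, dt=0.5, D_alpha=0.8, alpha=1.4)
            _, rec = simulate_ensemble(specs, sub, seed=100 + seed)
            ef = fit_ensemble(rec.observed)
            for k in range(2):
                err_c.append(abs(ef.particle_params[k].alpha - 0.5))
                err_u.append(abs(ef.uncorrected[k].params.alpha - 0.5))
        assert np.median(err_c) < np.median(err_u)

    def test_non_overlapping_tracks_fall_back(self):
        t1 = Trajectory(times=np.arange(20.0), positions=np.cumsum(
            np.random.default_rng(0).normal(size=(20, 2)), axis=0))
        t2 = Trajectory(times=np.arange(30.0, 50.0), positions=np.cumsum(
            np.random.default_rng(1).normal(size=(20, 2)), axis=0))
        with pytest.warns(UserWarning, match="overlap"):
            ef = fit_ensemble([t1, t2])
        assert ef.independent_fallback

    def test_particle_count_bounds(self):
        tr = Trajectory(times=np.arange(10.0),
                        positions=np.zeros((10, 2)))
        with pytest.raises(ValueError):
            fit_ensemble([tr])


class TestSubstratePath:
    @pytest.fixture(scope="class")
    def fitted_ensemble(self):
        specs = [SimulationSpec(n_points=100, dt=0.5, D_alpha=0.3, alpha=0.6,
                                sigma=0.05) for _ in range(2)]
        sub = SimulationSpec(n_points=100, dt=0.5, D_alpha=0.8, alpha=1.3)
        _, rec = simulate_ensemble(specs, sub, seed=23)
        ef = fit_ensemble(rec.observed)
        return ef, rec

    def _true_R_on(self, rec, grid):
        R = rec.substrate_path
        anch = R.positions - R.positions[0]
        return np.column_stack([
            np.interp(grid, R.times - R.times[0], anch[:, d])
            for d in range(anch.shape[1])
        ])

    def test_sign_convention_minimizes_error(self, fitted_ensemble):
        """The conditional mean must track the true substrate path, not its
        mirror image — resolves the sign of the precision-form expression."""
        ef, rec = fitted_ensemble
        path = infer_substrate_path(ef.model)
        truth = self._true_R_on(rec, path.query_times)
        mse_plus = np.mean((path.mean - truth) ** 2)
        mse_minus = np.mean((-path.mean - truth) ** 2)
        assert mse_plus < mse_minus

    def test_recovery_correlates_with_truth(self, fitted_ensemble):
        ef, rec = fitted_ensemble
        path = infer_substrate_path(ef.model)
        truth = self._true_R_on(rec, path.query_times)
        r = np.corrcoef(path.mean[:, 0], truth[:, 0])[0, 1]
        assert r > 0.8

    def test_duplicated_quiet_particles_track_shared_path(self):
        """Two near-identical tracks with tiny particle diffusion pin ⟨R⟩
        onto the shared observed trajectory."""
        rng = np.random.default_rng(5)
        times = 0.5 * np.arange(1, 51)
        shared = np.cumsum(rng.normal(0, 0.5, size=(50, 2)), axis=0)
        trajs = [
            Trajectory(times=times, positions=shared + rng.normal(0, 0.01, (50, 2)),
                       loc_errors=np.full((50, 2), 0.01))
            for _ in range(2)
        ]
        model = EnsembleModel(
            trajectories=tuple(trajs),
            particle_params=tuple(DiffusionParams(1e-4, 1.0, np.zeros(2))
                                  for _ in range(2)),
            substrate_params=DiffusionParams(0.5, 1.0, np.zeros(2)),
        )
        path = infer_substrate_path(model, query_times=times)
        assert np.max(np.abs(path.mean - shared)) < 0.1


class TestInterpolate:
    def test_noiseless_observed_times_reproduced_exactly(self):
        tr = simulate_fbm(SimulationSpec(n_points=40, dt=0.5, D_alpha=0.7,
                                         alpha=0.9, seed=31))
        params = DiffusionParams(0.7, 0.9, np.zeros(2))
        path = interpolate(tr, params, tr.times[5:10])
        np.testing.assert_allclose(path.mean, tr.positions[5:10], atol=1e-4)
        assert np.all(path.upper - path.lower < 1e-3)

    def test_anchor_returned_exactly(self):
        tr = simulate_fbm(SimulationSpec(n_points=20, dt=0.5, seed=32))
        params = DiffusionParams(0.5, 1.0, np.array([0.3, -0.1]))
        path = interpolate(tr, params, [tr.times[0]])
        np.testing.assert_allclose(path.mean[0], tr.positions[0], atol=1e-12)
        assert np.all(path.upper[0] - path.lower[0] < 1e-6)

    def test_band_ordering_and_midpoint_uncertainty(self):
        tr = simulate_fbm(SimulationSpec(n_points=20, dt=1.0, seed=33))
        params = DiffusionParams(0.5, 1.0, np.zeros(2))
        q = np.linspace(0.0, 19.0, 77)
        path = interpolate(tr, params, q)
        assert np.all(path.lower <= path.mean + 1e-12)
        assert np.all(path.mean <= path.upper + 1e-12)
        mid = interpolate(tr, params, [2.5])
        assert np.all(mid.upper[0] - mid.lower[0] > 1e-3)  # real uncertainty

    def test_query_before_anchor_rejected(self):
        tr = Trajectory(times=[2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
                        positions=np.zeros((7, 2)))
        with pytest.raises(ValueError, match="anchor"):
            interpolate(tr, DiffusionParams(1.0, 1.0, np.zeros(2)), [1.0])
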