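"""Benchmark pipelines: estimator comparison, substrate correction, coverage.

These drive the simulation studies: draw ground-truthed synthetic tracks,
run the GP estimator against the MSD and DDB baselines (or the corrected
against the uncorrected ensemble fit), and score relative errors
(est − true)/true.  Results come back as tidy DataFrames so the same code
serves the test suite, the command line and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import baselines
from .inference import fit_ensemble, fit_map, interpolate, sample_posterior
from .simulate import SimulationSpec, benchmark_dataset, corrupt, simulate_ensemble, simulate_fbm

__all__ = [
    "single_particle_benchmark",
    "substrate_benchmark",
    "particle_count_trend",
    "interpolation_coverage",
    "posterior_coverage",
    "median_abs_relative_errors",
]

#: Parameter ranges of the substrate-correction study: particle D and α,
#: substrate D_R and α_R, at fixed dt=0.5, σ=0.1, occlusion 0.1.
SUBSTRATE_RANGES = {
    "D": (0.1, 1.1),
    "alpha": (0.3, 1.0),
    "D_R": (0.1, 1.1),
    "alpha_R": (0.7, 1.7),
}


def _rel(est, true):
    return (est - true) / true


def single_particle_benchmark(
    n_traj: int, seed: int = 0, n_points: int = 250, ranges: dict | None = None
) -> pd.DataFrame:
    """GP vs MSD vs DDB on ground-truthed single tracks.

    One row per (trajectory, method) with signed relative errors for D and α.
    MSD retries without noise subtraction when the corrected curve leaves
    fewer than 3 usable lags; records where a baseline still fails carry NaN
    for that method only.
    """
    records = benchmark_dataset(n_traj, ranges=ranges, seed=seed, n_points=n_points)
    rows = []
    for i, rec in enumerate(records):
        true = rec.particle_params[0]
        obs = rec.observed[0]
        # effective localization scale for the baselines: per-coordinate noise
        # σ adds 2σ² to each coordinate displacement, i.e. σ_eff = √2·σ in the
        # 2-D noise-floor conventions ⟨r²⟩ = 4Dt^α + 2σ_eff² and
        # Rayleigh scale² = 2Dt^α + σ_eff²
        sigma_mean = float(np.sqrt(2.0) * np.mean(obs.loc_errors))
        gp = fit_map(obs)
        rows.append({"record": i, "method": "gp",
                     "err_D": _rel(gp.params.D_alpha, true.D_alpha),
                     "err_alpha": _rel(gp.params.alpha, true.alpha)})
        try:
            curve = baselines.msd_curve(obs)
            try:
                msd = baselines.fit_msd(curve, sigma_mean)
            except baselines.EstimationFailure:
                msd = baselines.fit_msd(curve, 0.0)
            rows.append({"record": i, "method": "msd",
                         "err_D": _rel(msd.D_alpha, true.D_alpha),
                         "err_alpha": _rel(msd.alpha, true.alpha)})
        except baselines.EstimationFailure:
            rows.append({"record": i, "method": "msd",
                         "err_D": np.nan, "err_alpha": np.nan})
        try:
            ddb = baselines.fit_ddb(obs, sigma_mean)
            rows.append({"record": i, "method": "ddb",
                         "err_D": _rel(ddb.D_alpha, true.D_alpha),
                         "err_alpha": _rel(ddb.alpha, true.alpha)})
        except baselines.EstimationFailure:
            rows.append({"record": i, "method": "ddb",
                         "err_D": np.nan, "err_alpha": np.nan})
    return pd.DataFrame(rows)


def median_abs_relative_errors(df: pd.DataFrame) -> pd.DataFrame:
    """Median |relative error| per method for D and α."""
    out = df.copy()
    out["err_D"] = out["err_D"].abs()
    out["err_alpha"] = out["err_alpha"].abs()
    return out.groupby("method")[["err_D", "err_alpha"]].median()


def _draw_substrate_specs(rng, n_particles, n_points, dt=0.5, sigma=0.1, occl=0.1):
    specs = [
        SimulationSpec(
            n_points=n_points, dt=dt,
            D_alpha=rng.uniform(*SUBSTRATE_RANGES["D"]),
            alpha=rng.uniform(*SUBSTRATE_RANGES["alpha"]),
            sigma=sigma, occlusion_rate=occl,
        )
        for _ in range(n_particles)
    ]
    sub = SimulationSpec(
        n_points=n_points, dt=dt,
        D_alpha=rng.uniform(*SUBSTRATE_RANGES["D_R"]),
        alpha=rng.uniform(*SUBSTRATE_RANGES["alpha_R"]),
    )
    return specs, sub


def substrate_benchmark(
    n_pairs: int, seed: int = 0, n_points: int = 250, n_particles: int = 2
) -> pd.DataFrame:
    """Corrected vs uncorrected estimation on substrate-coupled ensembles.

    One row per particle with signed relative errors of the joint
    (substrate-corrected) and independent (uncorrected) fits, plus the
    substrate-parameter errors on the first row of each ensemble.
    """
    rows = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_pairs)):
        rng = np.random.default_rng(child)
        specs, sub = _draw_substrate_specs(rng, n_particles, n_points)
        _, rec = simulate_ensemble(specs, sub, seed=int(child.generate_state(1)[0]) & 0x7FFFFFFF)
        fit = fit_ensemble(rec.observed)
        for k, sp in enumerate(specs):
            cor, unc = fit.particle_params[k], fit.uncorrected[k].params
            rows.append({
                "ensemble": i, "particle": k,
                "err_D_corrected": _rel(cor.D_alpha, sp.D_alpha),
                "err_alpha_corrected": _rel(cor.alpha, sp.alpha),
                "err_D_uncorrected": _rel(unc.D_alpha, sp.D_alpha),
                "err_alpha_uncorrected": _rel(unc.alpha, sp.alpha),
                "err_D_substrate": _rel(fit.substrate_params.D_alpha, sub.D_alpha)
                if k == 0 else np.nan,
                "err_alpha_substrate": _rel(fit.substrate_params.alpha, sub.alpha)
                if k == 0 else np.nan,
            })
    return pd.DataFrame(rows)


def particle_count_trend(
    n_ensembles: int, counts=(2, 3, 4, 5), seed: int = 0, n_points: int = 100
) -> pd.DataFrame:
    """Median |relative error| of particle parameters vs particles per cell.

    The same substrate draw and the same first two particles are shared
    across particle counts within one replicate, so restricting to
    ``particle < 2`` gives a fully paired comparison (identical tracks,
    only the number of helper particles changes).
    """
    rows = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_ensembles)):
        rng = np.random.default_rng(child)
        specs, sub = _draw_substrate_specs(rng, max(counts), n_points)
        ens_seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
        for K in counts:
            _, rec = simulate_ensemble(specs[:K], sub, seed=ens_seed)
            fit = fit_ensemble(rec.observed)
            for k in range(K):
                rows.append({
                    "ensemble": i, "n_particles": K, "particle": k,
                    "abs_err_D": abs(_rel(fit.particle_params[k].D_alpha,
                                          specs[k].D_alpha)),
                    "abs_err_alpha": abs(_rel(fit.particle_params[k].alpha,
                                              specs[k].alpha)),
                })
    return pd.DataFrame(rows)


def interpolation_coverage(
    n_tracks: int, seed: int = 0, n_points: int = 150, occlusion: float = 0.1,
    sigma: float = 0.1, use_true_params: bool = False,
) -> dict:
    """Fraction of hidden true positions inside the 95% credible band.

    Simulates tracks, hides a fraction of points, fits each observed track
    (or uses the generating parameters), and checks the pointwise band at
    the hidden times against the clean simulated positions, pooled over
    coordinates.
    """
    inside = 0
    total = 0
    for child in np.random.SeedSequence(seed).spawn(n_tracks):
        rng = np.random.default_rng(child)
        D = rng.uniform(0.1, 1.2)
        alpha = rng.uniform(0.3, 1.5)
        dt = rng.uniform(0.2, 0.8)
        spec = SimulationSpec(n_points=n_points, dt=dt, D_alpha=D, alpha=alpha,
                              sigma=sigma, occlusion_rate=occlusion)
        clean = simulate_fbm(spec, rng=rng)
        obs = corrupt(clean, sigma, occlusion, rng=rng)
        hidden = np.setdiff1d(clean.times, obs.times)
        if hidden.size == 0:
            continue
        if use_true_params:
            from .types import DiffusionParams
            params = DiffusionParams(D, alpha, np.zeros(clean.n_dims))
        else:
            params = fit_map(obs).params
        path = interpolate(obs, params, hidden)
        idx = np.searchsorted(clean.times, hidden)
        truth = clean.positions[idx]
        ok = (truth >= path.lower) & (truth <= path.upper)
        inside += int(ok.sum())
        total += ok.size
    return {"coverage": inside / total, "n_checked": total}


def posterior_coverage(
    n_tracks: int, seed: int = 0, n_points: int = 64,
    n_samples: int = 1500, burn_in: int = 500,
) -> dict:
    """Coverage of 95% credible intervals for (D, α) over simulated tracks."""
    hits = {"D_alpha": 0, "alpha": 0}
    n = 0
    for child in np.random.SeedSequence(seed).spawn(n_tracks):
        rng = np.random.default_rng(child)
        D = rng.uniform(0.1, 1.2)
        alpha = rng.uniform(0.4, 1.6)
        spec = SimulationSpec(n_points=n_points, dt=0.5, D_alpha=D, alpha=alpha,
                              sigma=0.05, occlusion_rate=0.0)
        clean = simulate_fbm(spec, rng=rng)
        obs = corrupt(clean, spec.sigma, 0.0, rng=rng)
        chain = sample_posterior(obs, n_samples=n_samples, burn_in=burn_in,
                                 seed=int(child.generate_state(1)[0]) & 0x7FFFFFFF)
        truth = {"D_alpha": D, "alpha": alpha}
        for name in hits:
            lo, hi = chain.credible_interval(name)
            hits[name] += int(lo <= truth[name] <= hi)
        n += 1
    return {name: hits[name] / n for name in hits} | {"n": n}
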