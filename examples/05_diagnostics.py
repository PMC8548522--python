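"""Model-adequacy checks: velocity autocorrelation and self-similarity.

FBM predicts a characteristic negative velocity-autocorrelation dip at one
frame lag for α<1, and lag-n displacements that collapse onto a single
Gaussian after rescaling by (n·dt)^(α/2).  The variance decomposition splits
estimate variability into within-cell and between-cell parts.
"""

import numpy as np

from gpfbm import (
    SimulationSpec, empirical_vacf, self_similarity_check, simulate_fbm,
    theoretical_vacf, variance_decomposition,
)

alpha = 0.6
tracks = [simulate_fbm(SimulationSpec(n_points=60, dt=1.0, D_alpha=0.5,
                                      alpha=alpha, seed=s)) for s in range(200)]

curve = empirical_vacf(tracks, max_lags=5)
theory = theoretical_vacf(alpha, curve.taus, curve.epsilon)
print("lag  empirical  FBM-theory")
for t, v, th in zip(curve.taus, curve.values, theory):
    print(f"{t:4.0f}  {v:9.3f}  {th:10.3f}")

rep = self_similarity_check(tracks, [1, 2, 4, 8], alpha_hat=alpha)
print(f"\nself-similarity collapse KS distance: {rep.collapse_ks:.3f} "
      f"(small = one α rescales all lags)")
print(f"per-lag KS normality distances: {np.round(rep.ks_normality, 3)}")

rng = np.random.default_rng(0)
groups = {c: rng.normal(0, 0.5) + rng.normal(0, 1.0, 8) for c in range(20)}
vd = variance_decomposition(groups)
print(f"\nvariance decomposition: intra {100 * vd.intra_fraction:.0f}% / "
      f"inter {100 * vd.inter_fraction:.0f}% of total {vd.total:.2f}")
print("The anti-persistent dip at lag 1 and the distributional collapse are"
      " the signatures that justify the FBM model for these tracks.")
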