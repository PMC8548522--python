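"""Sub-pixel spot localization and two-camera channel alignment.

A synthetic spot is rendered from the rotated-Gaussian model, perturbed with
noise and refit; the reported localization error is the posterior standard
deviation of the center.  A synthetic bead field is shifted between two
"cameras" and the affine alignment recovered by likelihood maximization.
"""

import numpy as np

from gpfbm import (
    AffineAlignment, SpotModel, apply_alignment, estimate_alignment,
    refine_spot, render_spot,
)

truth = SpotModel(5.6, 4.3, 1.4, 1.8, 0.2, 100.0, 10.0)
patch = render_spot((11, 11), truth)
noisy = patch + np.random.default_rng(1).normal(0, 8.0, patch.shape)
fit = refine_spot(noisy, (5, 5), seed=1)
print(f"true center   ({truth.mu_x:.3f}, {truth.mu_y:.3f})")
print(f"fitted center ({fit.mu_x:.3f}, {fit.mu_y:.3f}) "
      f"± ({fit.loc_error[0]:.3f}, {fit.loc_error[1]:.3f}) px")
print("The ± values feed the diffusion likelihood as per-point localization"
      " errors.")

rng = np.random.default_rng(2)
beads = np.full((48, 48), 5.0)
for _ in range(12):
    beads += render_spot((48, 48), SpotModel(
        mu_x=rng.uniform(8, 40), mu_y=rng.uniform(8, 40),
        L_x=1.8, L_y=1.8, theta=0.0, I_o=rng.uniform(50, 120), B_G=0.0))
mover = AffineAlignment(d_x=-2.4, d_y=1.3, W=48, H=48, c_x=24, c_y=24)
ch2 = apply_alignment(beads, mover)  # camera 2 sees content moved by (2.4, −1.3)
al = estimate_alignment([beads], [ch2])
print(f"\nrecovered channel offset: ({al.d_x:.2f}, {al.d_y:.2f}) px "
      f"(true (2.40, -1.30)), rotation {np.rad2deg(al.theta):.3f} deg")
print("Applying the fitted 3x3 matrix to channel-2 detections registers both"
      " channels to sub-pixel accuracy.")
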