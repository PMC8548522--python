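"""Sub-pixel spot refinement and two-channel affine alignment.

A tracked spot is modeled as a rotated 2-D Gaussian on a constant
background,

    S(x, y) = I₀ exp(−½ vᵀ M⁻¹ v) + B_G,   v = (x−μx, y−μy),
    M = [[Lx², θ Lx Ly], [θ Lx Ly, Ly²]],

with −1 < θ < 1 a correlation-style rotation parameter (distinct from the
alignment rotation *angle* below).  The seven parameters are fitted to an
image patch by Nelder-Mead on a Gaussian-noise likelihood; a short
Metropolis–Hastings run around the optimum gives the posterior standard
deviation of the center, reported as the localization error that feeds the
diffusion likelihood.

Channel registration composes scaling, translation and rotation about a
center point into a single 3×3 matrix Ω and maximizes an image-difference
likelihood over (s_x, s_y, d_x, d_y, θ).

Coordinate convention: pixel centers at integer coordinates, origin
top-left, x = column, y = row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from skimage.transform import AffineTransform, warp

__all__ = [
    "SpotModel",
    "AffineAlignment",
    "render_spot",
    "refine_spot",
    "compose_alignment",
    "estimate_alignment",
    "apply_alignment",
]


@dataclass(frozen=True)
class SpotModel:
    """Rotated 2-D Gaussian spot parameters (pixels / intensity units)."""

    mu_x: float
    mu_y: float
    L_x: float
    L_y: float
    theta: float          # correlation-style rotation, in (−1, 1)
    I_o: float
    B_G: float
    loc_error: tuple = (0.0, 0.0)
    flagged: bool = False

    def __post_init__(self):
        if self.L_x <= 0 or self.L_y <= 0:
            raise ValueError("spot sizes L_x, L_y must be > 0")
        if not -1 < self.theta < 1:
            raise ValueError("theta must lie in (−1, 1)")
        if self.I_o <= 0:
            raise ValueError("spot signal I_o must be > 0")
        if self.B_G < 0:
            raise ValueError("background B_G must be >= 0")


def render_spot(shape: tuple, spot: SpotModel) -> np.ndarray:
    """Evaluate the spot model on a (H, W) pixel grid."""
    H, W = shape
    y, x = np.mgrid[0:H, 0:W].astype(float)
    vx = x - spot.mu_x
    vy = y - spot.mu_y
    det = (spot.L_x * spot.L_y) ** 2 * (1 - spot.theta**2)
    # inverse of [[Lx², θLxLy], [θLxLy, Ly²]]
    a = spot.L_y**2 / det
    b = -spot.theta * spot.L_x * spot.L_y / det
    c = spot.L_x**2 / det
    q = a * vx**2 + 2 * b * vx * vy + c * vy**2
    return spot.I_o * np.exp(-0.5 * q) + spot.B_G


def _spot_from_vector(p) -> SpotModel:
    mux, muy, lLx, lLy, ttheta, lIo, lBG = p
    return SpotModel(
        mu_x=float(mux), mu_y=float(muy),
        L_x=float(np.exp(lLx)), L_y=float(np.exp(lLy)),
        theta=float(np.tanh(ttheta)),
        I_o=float(np.exp(lIo)), B_G=float(np.exp(lBG)),
    )


def _spot_neg_logpost(p, patch):
    model = render_spot(patch.shape, _spot_from_vector(p))
    ssq = float(np.sum((patch - model) ** 2))
    # Gaussian residuals with the noise variance marginalized out
    return 0.5 * patch.size * np.log(max(ssq, 1e-300))


def refine_spot(
    patch: np.ndarray,
    initial_center: tuple,
    mh_samples: int = 1200,
    mh_burn: int = 400,
    seed: int = 0,
) -> SpotModel:
    """Fit the 7-parameter spot model to a patch and estimate its precision.

    Nelder-Mead maximizes the marginalized Gaussian-noise likelihood from a
    centroid-based start; a short adaptive MH run around the optimum yields
    the posterior standard deviations of (μx, μy), reported as ``loc_error``.
    Flat patches and fits escaping the patch are returned flagged.
    """
    patch = np.asarray(patch, dtype=float)
    H, W = patch.shape
    if H < 7 or W < 7:
        raise ValueError("patch must be at least 7×7 pixels")
    x0, y0 = initial_center
    if not (0 <= x0 < W and 0 <= y0 < H):
        raise ValueError("initial_center must lie inside the patch")
    if np.ptp(patch) == 0:
        return SpotModel(x0, y0, 1.0, 1.0, 0.0, 1.0, 0.0,
                         loc_error=(np.inf, np.inf), flagged=True)
    bg0 = max(float(np.percentile(patch, 20)), 1e-6)
    amp0 = max(float(patch.max() - bg0), 1e-6)
    p0 = np.array([x0, y0, np.log(1.5), np.log(1.5), 0.0,
                   np.log(amp0), np.log(bg0)])
    best = None
    for off in (np.zeros(7), np.array([0.5, 0.5, 0.3, 0.3, 0.0, 0.3, 0.0])):
        res = minimize(_spot_neg_logpost, p0 + off, args=(patch,),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 3000})
        if best is None or res.fun < best.fun:
            best = res
    p = best.x
    flagged = not (1 <= p[0] <= W - 2 and 1 <= p[1] <= H - 2)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scales = np.full(7, 0.02)
    theta, lp = p.copy(), -_spot_neg_logpost(p, patch)
    keep = np.empty((mh_samples, 2))
    acc = np.zeros(7)
    nwin = 0
    for it in range(mh_burn + mh_samples):
        for j in range(7):
            prop = theta.copy()
            prop[j] += scales[j] * rng.standard_normal()
            lp_prop = -_spot_neg_logpost(prop, patch)
            if np.log(rng.uniform()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                acc[j] += 1
        nwin += 1
        if it < mh_burn and nwin == 50:
            scales *= np.exp(np.clip(acc / nwin - 0.3, -0.5, 0.5))
            scales = np.clip(scales, 1e-5, 1.0)
            acc[:] = 0
            nwin = 0
        if it >= mh_burn:
            keep[it - mh_burn] = theta[:2]
    loc = (float(np.std(keep[:, 0])), float(np.std(keep[:, 1])))
    model = _spot_from_vector(p)
    return SpotModel(model.mu_x, model.mu_y, model.L_x, model.L_y, model.theta,
                     model.I_o, model.B_G, loc_error=loc, flagged=flagged)


@dataclass(frozen=True)
class AffineAlignment:
    """Channel-registration parameters: scale, translation, rotation about c."""

    s_x: float = 1.0
    s_y: float = 1.0
    d_x: float = 0.0
    d_y: float = 0.0
    theta: float = 0.0    # radians
    c_x: float = 0.0
    c_y: float = 0.0
    W: int = 0
    H: int = 0

    def __post_init__(self):
        if self.s_x <= 0 or self.s_y <= 0:
            raise ValueError("scale factors must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        return compose_alignment(self)


def compose_alignment(params: AffineAlignment) -> np.ndarray:
    """Exact product (scaling)·(translation)·(rotation)·(re-centering).

    Identity when s=1, d=0, θ=0 for every rotation center and image size.
    """
    sx, sy, W, H = params.s_x, params.s_y, params.W, params.H
    dx, dy, cx, cy, th = params.d_x, params.d_y, params.c_x, params.c_y, params.theta
    S = np.array([[sx, 0, (1 - sx) * W / 2], [0, sy, (1 - sy) * H / 2], [0, 0, 1.0]])
    T = np.array([[1, 0, dx + cx], [0, 1, dy + cy], [0, 0, 1.0]])
    R = np.array([[np.cos(th), np.sin(th), 0], [-np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    C = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    return S @ T @ R @ C


def apply_alignment(image: np.ndarray, alignment: AffineAlignment) -> np.ndarray:
    """Resample an image under Ω with bilinear interpolation.

    Output pixel (x, y) takes the value of the input at Ω·(x, y, 1);
    out-of-bounds pixels are filled with the image's border median.
    """
    image = np.asarray(image, dtype=float)
    border = np.concatenate([image[0], image[-1], image[:, 0], image[:, -1]])
    fill = float(np.median(border))
    tf = AffineTransform(matrix=compose_alignment(alignment))
    return warp(image, tf, order=1, cval=fill, mode="constant",
                preserve_range=True)


def _alignment_neg_loglik(p, frames1, frames2, W, H):
    sx, sy, dx, dy, th = p
    if sx <= 0.2 or sy <= 0.2:
        return 1e12
    al = AffineAlignment(s_x=sx, s_y=sy, d_x=dx, d_y=dy, theta=th,
                         c_x=W / 2, c_y=H / 2, W=W, H=H)
    total = 0.0
    for f1, f2 in zip(frames1, frames2):
        moved = apply_alignment(f2, al)
        total += float(np.sum((moved - f1) ** 2))
    return 0.5 * W * H * np.log(max(total, 1e-300))


def estimate_alignment(
    frames_ch1,
    frames_ch2,
    normalize: bool = False,
) -> AffineAlignment:
    """Estimate the affine map aligning channel 2 onto channel 1.

    Maximizes the image-difference likelihood summed over the provided frame
    pairs over (s_x, s_y, d_x, d_y, θ), with the rotation center fixed at the
    image center (the likelihood is degenerate in (c, d) jointly).
    ``normalize=True`` divides each frame by its median first.  Structureless
    (constant) inputs raise a ValueError.
    """
    f1 = [np.asarray(f, dtype=float) for f in np.atleast_3d(frames_ch1).reshape(
        (-1,) + np.asarray(frames_ch1).shape[-2:])]
    f2 = [np.asarray(f, dtype=float) for f in np.atleast_3d(frames_ch2).reshape(
        (-1,) + np.asarray(frames_ch2).shape[-2:])]
    if len(f1) != len(f2) or not f1:
        raise ValueError("need equal-size, non-empty frame sets")
    if all(np.ptp(f) == 0 for f in f1) or all(np.ptp(f) == 0 for f in f2):
        raise ValueError("structureless images: alignment is unidentifiable")
    if normalize:
        f1 = [f / max(np.median(f), 1e-12) for f in f1]
        f2 = [f / max(np.median(f), 1e-12) for f in f2]
    H, W = f1[0].shape
    p0 = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
    res = minimize(
        _alignment_neg_loglik, p0, args=(f1, f2, W, H), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000,
                 "initial_simplex": p0 + np.vstack([np.zeros(5),
                                                    np.diag([0.02, 0.02, 2.0, 2.0, 0.02])])},
    )
    sx, sy, dx, dy, th = res.x
    return AffineAlignment(s_x=float(sx), s_y=float(sy), d_x=float(dx),
                           d_y=float(dy), theta=float(th),
                           c_x=W / 2, c_y=H / 2, W=W, H=H)
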