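"""Sparse non-negative regression inverting the observation model.

The estimation problem is

    min_{F, rho, alpha, b, a, phi >= 0}  L_sparsity
    subject to                           L_reconstruction <= omega

solved in penalized (Lagrangian) form  L_reconstruction + lam * L_sparsity
by block projected gradient descent, with the multiplier ``lam`` adjusted by
bisection until the solution's reconstruction loss lands just below omega.

Block subproblems in a, b and alpha are quadratic with diagonal curvature
and are minimized exactly (the ideal diagonal-step projected gradient
update); the F block uses a projected gradient step of size
1 / (2 sigma_max(G)^2), a valid inverse-Lipschitz step because the
normalized blur kernel has spectral norm <= 1; phi rows use an SVD-based
Lipschitz bound; the rho block (the only non-quadratic one) backtracks.
Every update is therefore monotone in the penalized objective.

The overall scale of (F, alpha, phi) is not identifiable — rescaling
(F, alpha, phi) -> (4F, alpha/2, phi/2) leaves both losses unchanged — so
fitted parameters are reported in a canonical normalization: alpha sums
to 1 and phi has unit diagonal (``normalize_scale``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import (
    Codebook,
    ImageStack,
    ModelParameters,
    NoiseThreshold,
    PointSpreadFunction,
    ValidationError,
)
from .core import compute_gain_tensor, phase_codebook

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "fit",
    "estimate_step_sizes",
    "select_noise_threshold",
    "normalize_scale",
]


@dataclass
class FitConfig:
    """Optimization settings for :func:`fit`."""

    max_iters: int = 100
    inner_iters_per_block: int = 4
    tol_rel_objective: float = 1e-6
    unexplained_fraction_target: float = 0.1
    lagrange_bisection_iters: int = 8
    seed: int = 0
    learn_phi: bool = True
    learn_rho: bool = True

    def __post_init__(self):
        if self.max_iters < 1 or self.inner_iters_per_block < 1:
            raise ValidationError("iteration counts must be positive")
        if self.tol_rel_objective <= 0:
            raise ValidationError("tol_rel_objective must be positive")
        if not 0 < self.unexplained_fraction_target < 1:
            raise ValidationError("unexplained_fraction_target must be in (0, 1)")
        if self.lagrange_bisection_iters < 1:
            raise ValidationError("lagrange_bisection_iters must be positive")


@dataclass
class FitResult:
    """Fitted parameters plus the optimization trace."""

    params: ModelParameters
    omega: NoiseThreshold
    trajectory: list  # per outer iteration: (reconstruction_loss, sparsity_loss)
    converged: bool
    lam: float = 0.0

    @property
    def reconstruction_loss(self) -> float:
        return self.trajectory[-1][0] if self.trajectory else np.nan

    @property
    def sparsity_loss(self) -> float:
        return self.trajectory[-1][1] if self.trajectory else np.nan


def select_noise_threshold(
    X: ImageStack,
    codebook: Codebook | None = None,
    psf: PointSpreadFunction | None = None,
    config: FitConfig | None = None,
) -> NoiseThreshold:
    """Set omega to a declared fraction of the centered total sum of squares.

    The centering removes the per-(round, channel) mean over voxels, so a
    constant stack yields omega = 0.  ``codebook`` and ``psf`` are accepted
    for interface symmetry with :func:`fit` but do not enter the rule.
    """
    config = config or FitConfig()
    flat = X.flat
    centered = flat - flat.mean(axis=2, keepdims=True)
    tss = float(np.sum(centered * centered))
    return NoiseThreshold(config.unexplained_fraction_target * tss)


def normalize_scale(params: ModelParameters) -> ModelParameters:
    """Map parameters to the canonical scale.

    Each row of phi is divided by its diagonal value and the corresponding
    column of alpha multiplied by it; then alpha is divided by its sum and F
    multiplied by it.  The forward model is unchanged to roundoff, and any
    two parameter sets related by the (cF, alpha/s, phi/t) ambiguity map to
    the same canonical point.
    """
    d = np.diag(params.phi).copy()
    if np.any(d <= 0):
        raise ValidationError("phi must have a positive diagonal to normalize")
    alpha = params.alpha * d[None, :]
    phi = params.phi / d[:, None]
    s = alpha.sum()
    if s <= 0:
        raise ValidationError("alpha must have a positive sum to normalize")
    return ModelParameters(
        F=params.F * s,
        a=params.a.copy(),
        b=params.b.copy(),
        alpha=alpha / s,
        phi=np.clip(phi, 0.0, 1.0),
        rho=params.rho.copy(),
    )


# ----------------------------------------------------------------------
# internal state for the block solver


class _Problem:
    """Caches the quantities the block updates share."""

    def __init__(self, X: ImageStack, codebook: Codebook, psf: PointSpreadFunction):
        self.X = X.flat  # (R, C, M)
        self.codebook = codebook
        self.psf = psf
        self.spatial_shape = X.spatial_shape
        self.R, self.C, self.M = self.X.shape
        self.J = codebook.J

    def blur(self, F: np.ndarray) -> np.ndarray:
        return self.psf.apply_to_density(F, self.spatial_shape)

    def blur_stack(self, T: np.ndarray) -> np.ndarray:
        """Apply the (self-adjoint) kernel to each (r, c) frame of (R,C,M)."""
        out = np.empty_like(T)
        for r in range(self.R):
            for c in range(self.C):
                out[r, c] = self.psf.apply(T[r, c].reshape(self.spatial_shape)).ravel()
        return out

    def phased(self, rho: np.ndarray) -> np.ndarray:
        return phase_codebook(self.codebook, rho).Z


def _recon(prob: _Problem, p: ModelParameters, KF: np.ndarray, G: np.ndarray) -> np.ndarray:
    return p.a[None, None, :] + p.b[:, :, None] + np.einsum("mj,rcj->rcm", KF, G)


def _losses(prob, p, KF, G, lam):
    recon = _recon(prob, p, KF, G)
    resid = prob.X - recon
    lrec = float(np.sum(resid * resid))
    lsp = float(p.F.sum(axis=0) @ G.sum(axis=(0, 1)))
    return lrec, lsp, lrec + lam * lsp, resid


def _fit_penalized(
    prob: _Problem,
    lam: float,
    params0: ModelParameters,
    config: FitConfig,
):
    """Monotone block descent on L_rec + lam * L_sp from params0."""
    p = params0.copy()
    R, C, M, J = prob.R, prob.C, prob.M, prob.J

    Z = prob.phased(p.rho)
    phiZ = np.einsum("cd,rdj->rcj", p.phi, Z)
    G = p.alpha[:, :, None] * phiZ
    KF = prob.blur(p.F)

    trajectory = []
    converged = False
    lrec, lsp, obj, resid = _losses(prob, p, KF, G, lam)
    obj0 = obj

    for _ in range(config.max_iters):
        # --- F block: projected gradient, step 1/(2 smax(G)^2) ---------
        gsum = G.sum(axis=(0, 1))
        smax = np.linalg.svd(G.reshape(R * C, J), compute_uv=False)[0]
        if smax > 0:
            step = 1.0 / (2.0 * smax * smax)
            for _ in range(config.inner_iters_per_block):
                recon = _recon(prob, p, KF, G)
                kres = prob.blur_stack(prob.X - recon)
                gradF = -2.0 * np.einsum("rcm,rcj->mj", kres, G) + lam * gsum[None, :]
                p.F = np.maximum(p.F - step * gradF, 0.0)
                KF = prob.blur(p.F)

        # --- a block: exact projected minimizer ------------------------
        mix = np.einsum("mj,rcj->rcm", KF, G)
        p.a = np.maximum(
            (prob.X - p.b[:, :, None] - mix).sum(axis=(0, 1)) / (R * C), 0.0
        )
        # --- b block ----------------------------------------------------
        p.b = np.maximum((prob.X - p.a[None, None, :] - mix).sum(axis=2) / M, 0.0)

        # --- alpha block: exact per-entry minimizer ---------------------
        u = np.einsum("mj,rcj->rcm", KF, phiZ)  # d recon / d alpha[r,c]
        uu = np.einsum("rcm,rcm->rc", u, u)
        xa = prob.X - p.a[None, None, :] - p.b[:, :, None]
        num = np.einsum("rcm,rcm->rc", xa, u) - 0.5 * lam * np.einsum(
            "j,rcj->rc", p.F.sum(axis=0), phiZ
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha_new = np.where(uu > 0, num / np.maximum(uu, 1e-300), p.alpha)
        p.alpha = np.maximum(alpha_new, 0.0)
        G = p.alpha[:, :, None] * phiZ

        # --- phi block: one projected gradient step per row -------------
        if config.learn_phi:
            vv = np.einsum("mj,rcj->rcm", KF, Z)  # (R, c', M)
            resid = xa - np.einsum("mj,rcj->rcm", KF, G)
            fsum = p.F.sum(axis=0)
            # D_c[(r,m), c'] = alpha[r,c] vv[r,c',m]; rows of phi are independent
            for c in range(C):
                Dc = p.alpha[:, c][:, None, None] * vv  # (R, C, M) over c'
                rc = resid[:, c, :]  # (R, M)
                grad = -2.0 * np.einsum("rm,rdm->d", rc, Dc)
                grad += lam * np.einsum("j,rdj->d", fsum, p.alpha[:, c][:, None, None] * Z)
                Dmat = np.moveaxis(Dc, 1, 0).reshape(C, -1)
                smax_c = np.linalg.norm(Dmat @ Dmat.T, 2)
                if smax_c > 0:
                    p.phi[c] = np.clip(p.phi[c] - grad / (2.0 * smax_c), 0.0, 1.0)
            phiZ = np.einsum("cd,rdj->rcj", p.phi, Z)
            G = p.alpha[:, :, None] * phiZ

        # --- rho block: backtracked projected gradient ------------------
        if config.learn_rho and R > 1:
            lrec_c, lsp_c, obj_c, resid = _losses(prob, p, KF, G, lam)
            grad_rho = _rho_gradient(prob, p, KF, Z, resid, lam)
            gnorm = float(np.abs(grad_rho).max())
            if gnorm > 0:
                step = 0.5 / gnorm  # initial trial step; backtrack to descent
                rho_old = p.rho.copy()
                for _ in range(25):
                    p.rho = np.clip(rho_old - step * grad_rho, 0.0, 1.0)
                    Z_t = prob.phased(p.rho)
                    phiZ_t = np.einsum("cd,rdj->rcj", p.phi, Z_t)
                    G_t = p.alpha[:, :, None] * phiZ_t
                    _, _, obj_t, _ = _losses(prob, p, KF, G_t, lam)
                    if obj_t <= obj_c:
                        Z, phiZ, G = Z_t, phiZ_t, G_t
                        break
                    step *= 0.5
                else:
                    p.rho = rho_old

        _check_boxes(p)
        lrec, lsp, obj_new, resid = _losses(prob, p, KF, G, lam)
        trajectory.append((lrec, lsp))
        if obj_new > obj * (1 + 1e-9) + 1e-12 * obj0:
            logger.warning("objective increased (%.3e -> %.3e)", obj, obj_new)
        rel = abs(obj - obj_new) / max(obj, 1e-300)
        obj = obj_new
        if rel <= config.tol_rel_objective:
            converged = True
            break

    return p, trajectory, converged


def _check_boxes(p: ModelParameters) -> None:
    """Verify every block stayed inside its box after projection."""
    for name in ("F", "a", "b", "alpha"):
        v = getattr(p, name)
        if v.min() < 0:
            raise AssertionError(f"projection failed: {name} went negative")
    for name in ("phi", "rho"):
        v = getattr(p, name)
        if v.min() < 0 or v.max() > 1:
            raise AssertionError(f"projection failed: {name} left [0, 1]")


def _rho_gradient(prob, p, KF, Z, resid, lam):
    """d(L_rec + lam L_sp)/d rho via the unrolled phasing recursion.

    W[r] = dZ[r]/drho (per channel) obeys W[0] = 0,
    W[r] = rho * W[r-1] + Z[r-1].
    """
    R, C, J = Z.shape
    W = np.zeros_like(Z)
    for r in range(1, R):
        W[r] = p.rho[:, None] * W[r - 1] + Z[r - 1]
    # dG[r,ct,j]/drho_c = alpha[r,ct] phi[ct,c] W[r,c,j]
    # dL_rec/drho_c = -2 sum resid[r,ct,m] KF[m,j] alpha[r,ct] phi[ct,c] W[r,c,j]
    t = np.einsum("rtm,mj->rtj", resid, KF)  # (R, C~, J)
    core = np.einsum("rtj,rt->rtj", t, p.alpha)
    g_rec = -2.0 * np.einsum("rtj,tc,rcj->c", core, p.phi, W)
    fsum = p.F.sum(axis=0)
    g_sp = np.einsum("j,rt,tc,rcj->c", fsum, p.alpha, p.phi, W)
    return g_rec + lam * g_sp


# ----------------------------------------------------------------------
# public fit with Lagrange-multiplier bisection


def fit(
    X: ImageStack,
    codebook: Codebook,
    psf: PointSpreadFunction,
    config: FitConfig | None = None,
    params_init: ModelParameters | None = None,
    lam: float | None = None,
) -> FitResult:
    """Estimate all model parameters from an observed stack.

    The constrained problem (minimize the sparsity penalty subject to
    L_reconstruction <= omega) is solved through its penalized form with
    the multiplier chosen by bisection so the reconstruction loss lands
    within ~5% of omega.  Passing ``lam`` skips the bisection and solves
    the penalized problem at that multiplier directly.
    """
    config = config or FitConfig()
    if np.any(np.isnan(X.data)):
        raise ValidationError("stack contains NaN values")
    if codebook.R != X.R or codebook.C != X.C:
        raise ValidationError("codebook (R, C) does not match the stack")

    omega = select_noise_threshold(X, codebook, psf, config)
    prob = _Problem(X, codebook, psf)

    if not np.any(X.data):
        warnings.warn("all-zero stack: returning zero parameters")
        p = ModelParameters.zeros(prob.M, prob.J, prob.R, prob.C)
        return FitResult(params=p, omega=omega, trajectory=[(0.0, 0.0)],
                         converged=True, lam=0.0)

    p0 = params_init.copy() if params_init is not None else _default_init(prob)

    if lam is not None:
        p, traj, conv = _fit_penalized(prob, lam, p0, config)
        lrec = traj[-1][0] if traj else np.inf
        return FitResult(params=normalize_scale(p), omega=omega, trajectory=traj,
                         converged=conv and lrec <= omega.omega * (1 + 1e-6), lam=lam)

    # feasibility anchor: unpenalized non-negative least squares
    p_lo, traj_lo, conv_lo = _fit_penalized(prob, 0.0, p0, config)
    lrec_lo = traj_lo[-1][0]
    if lrec_lo > omega.omega:
        logger.warning(
            "could not reach the noise threshold (L_rec=%.3g > omega=%.3g)",
            lrec_lo, omega.omega,
        )
        return FitResult(params=normalize_scale(p_lo), omega=omega,
                         trajectory=traj_lo, converged=False, lam=0.0)

    lam_hi = _lambda_upper_bound(prob, p0)
    lam_lo, best = 0.0, (p_lo, traj_lo, conv_lo, 0.0)
    for _ in range(config.lagrange_bisection_iters):
        lam_mid = 0.5 * (lam_lo + lam_hi)
        p_mid, traj_mid, conv_mid = _fit_penalized(prob, lam_mid, best[0], config)
        lrec_mid = traj_mid[-1][0]
        if lrec_mid <= omega.omega:
            lam_lo, best = lam_mid, (p_mid, traj_mid, conv_mid, lam_mid)
            if lrec_mid >= 0.95 * omega.omega:
                break
        else:
            lam_hi = lam_mid

    p_fin, traj_fin, conv_fin, lam_fin = best
    lrec_fin = traj_fin[-1][0]
    return FitResult(
        params=normalize_scale(p_fin),
        omega=omega,
        trajectory=traj_fin,
        converged=conv_fin and lrec_fin <= omega.omega * (1 + 1e-6),
        lam=lam_fin,
    )


def _default_init(prob: _Problem) -> ModelParameters:
    """Deterministic feasible start: F = 0, background from per-voxel minima."""
    a = prob.X.min(axis=(0, 1))
    b = np.maximum((prob.X - a[None, None, :]).min(axis=2), 0.0)
    return ModelParameters(
        F=np.zeros((prob.M, prob.J)),
        a=a,
        b=b,
        alpha=np.full((prob.R, prob.C), 1.0 / (prob.R * prob.C)),
        phi=np.eye(prob.C),
        rho=np.zeros(prob.C),
    )


def _lambda_upper_bound(prob: _Problem, p0: ModelParameters) -> float:
    """A multiplier above which the very first F step stays at zero."""
    Z = prob.phased(p0.rho)
    G = compute_gain_tensor(Z, np.ones((prob.R, prob.C)), p0.phi)
    resid0 = prob.X - p0.a[None, None, :] - p0.b[:, :, None]
    kres = prob.blur_stack(resid0)
    drive = 2.0 * np.einsum("rcm,rcj->mj", kres, G)
    gsum = G.sum(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gsum[None, :] > 0, drive / gsum[None, :], 0.0)
    return max(float(ratio.max()), 1e-12) * 2.0


# ----------------------------------------------------------------------
# step-size estimation contract


def estimate_step_sizes(
    X: ImageStack,
    codebook: Codebook,
    psf: PointSpreadFunction,
    params: ModelParameters | None = None,
    n_iter: int = 30,
    seed: int = 0,
) -> dict[str, float]:
    """Per-block step sizes 1 / L from power-iterated Lipschitz bounds.

    For each parameter block the reconstruction is linear (for rho,
    linearized) in that block; the gradient's Lipschitz constant is twice
    the squared operator norm, estimated by power iteration on the block's
    normal operator and inflated by 0.1% so the result is an upper bound at
    convergence.  Step sizes depend only on the operator, not on X, so
    rescaling the data leaves them unchanged.

    The reference point defaults to unit alpha, identity phi, zero rho and
    unit density (the neutral parameterization).
    """
    if n_iter < 10:
        raise ValidationError("power iteration needs at least 10 iterations")
    if not np.any(codebook.B):
        raise ValidationError("codebook is all-zero; operators are degenerate")
    R, C, M, J = X.R, X.C, X.M, codebook.J
    if params is None:
        params = ModelParameters(
            F=np.ones((M, J)), a=np.zeros(M), b=np.zeros((R, C)),
            alpha=np.ones((R, C)), phi=np.eye(C), rho=np.zeros(C),
        )
    prob = _Problem(X, codebook, psf)
    Z = prob.phased(params.rho)
    phiZ = np.einsum("cd,rdj->rcj", params.phi, Z)
    G = params.alpha[:, :, None] * phiZ
    KF = prob.blur(params.F)
    rng = np.random.default_rng(seed)

    def power(mat, rmat, shape):
        v = rng.standard_normal(shape)
        v /= np.linalg.norm(v)
        lam_est = 0.0
        for _ in range(n_iter):
            w = rmat(mat(v))
            lam_est = float(np.linalg.norm(w.ravel()))
            if lam_est == 0:
                return 0.0
            v = w / lam_est
        return lam_est

    ops = {
        "F": (
            lambda v: np.einsum("mj,rcj->rcm", prob.blur(v), G),
            lambda T: np.einsum("rcm,rcj->mj", prob.blur_stack(T), G),
            (M, J),
        ),
        "a": (
            lambda v: np.broadcast_to(v[None, None, :], (R, C, M)).copy(),
            lambda T: T.sum(axis=(0, 1)),
            (M,),
        ),
        "b": (
            lambda v: np.broadcast_to(v[:, :, None], (R, C, M)).copy(),
            lambda T: T.sum(axis=2),
            (R, C),
        ),
        "alpha": (
            lambda v: v[:, :, None] * np.einsum("mj,rcj->rcm", KF, phiZ),
            lambda T: np.einsum("rcm,rcm->rc", T, np.einsum("mj,rcj->rcm", KF, phiZ)),
            (R, C),
        ),
        "phi": (
            lambda v: params.alpha[:, :, None]
            * np.einsum("cd,rdm->rcm", v, np.einsum("mj,rdj->rdm", KF, Z)),
            lambda T: np.einsum(
                "rcm,rc,rdm->cd", T, params.alpha, np.einsum("mj,rdj->rdm", KF, Z)
            ),
            (C, C),
        ),
    }
    if R > 1:
        W = np.zeros_like(Z)
        for r in range(1, R):
            W[r] = params.rho[:, None] * W[r - 1] + Z[r - 1]
        cols = np.einsum("rt,tc,rcj,mj->crtm", params.alpha, params.phi, W, KF)
        ops["rho"] = (
            lambda v: np.einsum("c,crtm->rtm", v, cols),
            lambda T: np.einsum("rtm,crtm->c", T, cols),
            (C,),
        )

    steps = {}
    for name, (mat, rmat, shape) in ops.items():
        lam_est = power(mat, rmat, shape)
        L = 2.0 * lam_est * 1.001
        steps[name] = 1.0 / L if L > 0 else 1.0
    return steps
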