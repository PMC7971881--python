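"""Forward observation model and its two losses.

The model for the observed intensity at voxel m, round r, channel c is

    X[m,r,c] ~ a[m] + b[r,c] + sum_j (K * F[:,j])[m] G[r,c,j]

with G[r,c,j] = alpha[r,c] sum_c' phi[c,c'] Z[r,c',j] and the phased
codebook Z[r,c,j] = rho[c] Z[r-1,c,j] + B[r,c,j].  Estimation minimizes a
linear sparsity penalty on the summed density subject to the squared
reconstruction error staying below a noise threshold.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    Codebook,
    ImageStack,
    ModelParameters,
    PhasedCodebook,
    PointSpreadFunction,
    ValidationError,
)

__all__ = [
    "phase_codebook",
    "compute_gain_tensor",
    "forward_model",
    "reconstruction_loss",
    "sparsity_loss",
]


def phase_codebook(codebook: Codebook, rho: np.ndarray) -> PhasedCodebook:
    """Apply the round-phasing recursion Z[r] = rho * Z[r-1] + B[r].

    There is no ghost signal before round 1, so Z at r=0 (0-based) equals B
    at r=0.  With rho = 0 the recursion collapses to Z = B.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (codebook.C,):
        raise ValidationError("rho must have one entry per channel")
    bad = np.flatnonzero((rho < 0) | (rho > 1))
    if bad.size:
        raise ValidationError(
            f"rho must lie in [0, 1]; violated at channel(s) {bad.tolist()}"
        )
    B = codebook.B
    Z = np.empty_like(B)
    Z[0] = B[0]
    for r in range(1, codebook.R):
        Z[r] = rho[:, None] * Z[r - 1] + B[r]
    return PhasedCodebook(Z=Z)


def compute_gain_tensor(Z: np.ndarray, alpha: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """G[r,c,j] = alpha[r,c] * sum_c' phi[c,c'] Z[r,c',j]."""
    Z = np.asarray(Z, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    phi = np.asarray(phi, dtype=float)
    R, C, J = Z.shape
    if alpha.shape != (R, C) or phi.shape != (C, C):
        raise ValidationError(
            f"shape mismatch: Z {Z.shape}, alpha {alpha.shape}, phi {phi.shape}"
        )
    return alpha[:, :, None] * np.einsum("cd,rdj->rcj", phi, Z)


def gain_tensor(params: ModelParameters, codebook: Codebook) -> np.ndarray:
    """Convenience: phase the codebook with params.rho and form G."""
    Z = phase_codebook(codebook, params.rho).Z
    return compute_gain_tensor(Z, params.alpha, params.phi)


def forward_model(
    params: ModelParameters,
    psf: PointSpreadFunction,
    codebook: Codebook,
    spatial_shape: tuple[int, ...],
) -> ImageStack:
    """Render the model's predicted stack ('reconstruction')."""
    if codebook.J != params.J:
        raise ValidationError(
            f"codebook has {codebook.J} barcodes but F has {params.J} columns"
        )
    if int(np.prod(spatial_shape)) != params.M:
        raise ValidationError("spatial_shape does not match F's row count")
    G = gain_tensor(params, codebook)
    KF = psf.apply_to_density(params.F, spatial_shape)
    flat = (
        params.a[None, None, :]
        + params.b[:, :, None]
        + np.einsum("mj,rcj->rcm", KF, G)
    )
    return ImageStack(flat.reshape(params.R, params.C, *spatial_shape))


def reconstruction_loss(X: ImageStack, reconstruction: ImageStack) -> float:
    """Total squared error between observed and reconstructed stacks."""
    if X.data.shape != reconstruction.data.shape:
        raise ValidationError(
            f"shape mismatch: {X.data.shape} vs {reconstruction.data.shape}"
        )
    d = X.data - reconstruction.data
    return float(np.sum(d * d))


def sparsity_loss(params: ModelParameters, Z: np.ndarray) -> float:
    """Linear penalty on the total summed density.

    sum_{m,r,c,c',j} alpha[r,c] F[m,j] phi[c,c'] Z[r,c',j]
      = sum_j (sum_m F[m,j]) (sum_{r,c} G[r,c,j]).
    """
    G = compute_gain_tensor(Z, params.alpha, params.phi)
    return float(params.F.sum(axis=0) @ G.sum(axis=(0, 1)))
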