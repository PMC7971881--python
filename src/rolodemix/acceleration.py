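"""Acceleration strategies: coarse-to-fine, barcode sparsification, patches.

Large stacks are processed per spatial patch (with a halo wide enough to
absorb PSF spill-over); within each patch a cheap fit on block-mean
downsampled data prunes barcodes that are absent there and initializes the
full-resolution fit.  Patch cores tile the grid exactly, so stitched
results are independent of patch execution order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .containers import (
    Codebook,
    ImageStack,
    ModelParameters,
    PointSpreadFunction,
    ValidationError,
)
from .inference import FitConfig, FitResult, fit, normalize_scale, select_noise_threshold

__all__ = [
    "PatchGrid",
    "downsample_stack",
    "upsample_density",
    "sparsify_barcodes",
    "fit_accelerated",
]

#: Iteration budgets for the two stages of a coarse-to-fine fit.
COARSE_ITERS = 20
FINE_ITERS = 10


@dataclass
class PatchGrid:
    """Disjoint core boxes covering the grid, each padded by a halo."""

    spatial_shape: tuple[int, ...]
    patch_size: tuple[int, ...]
    halo: int = 0

    def __post_init__(self):
        self.spatial_shape = tuple(int(n) for n in self.spatial_shape)
        if np.isscalar(self.patch_size):
            self.patch_size = (int(self.patch_size),) * len(self.spatial_shape)
        else:
            self.patch_size = tuple(int(p) for p in self.patch_size)
        if len(self.patch_size) != len(self.spatial_shape):
            raise ValidationError("patch_size must give one size per spatial dim")
        if any(p < 1 for p in self.patch_size) or self.halo < 0:
            raise ValidationError("patch sizes must be positive and halo >= 0")

    @property
    def patches(self) -> list[tuple[tuple[slice, ...], tuple[slice, ...]]]:
        """List of (core box, padded box) slice tuples."""
        ranges = [
            [(lo, min(lo + p, n)) for lo in range(0, n, p)]
            for n, p in zip(self.spatial_shape, self.patch_size)
        ]
        out = []
        import itertools

        for combo in itertools.product(*ranges):
            core = tuple(slice(lo, hi) for lo, hi in combo)
            padded = tuple(
                slice(max(lo - self.halo, 0), min(hi + self.halo, n))
                for (lo, hi), n in zip(combo, self.spatial_shape)
            )
            out.append((core, padded))
        return out


def downsample_stack(X: ImageStack, factor: int) -> ImageStack:
    """Block-mean pooling over ``factor``-per-side spatial blocks.

    Partial edge blocks are averaged over the voxels they actually contain;
    rounds and channels are untouched.
    """
    if factor < 1:
        raise ValidationError("factor must be a positive integer")
    if factor == 1:
        return ImageStack(X.data.copy())
    spatial = X.spatial_shape
    if all(factor > n for n in spatial):
        raise ValidationError("factor exceeds every spatial dimension")
    data = X.data
    counts = np.ones(spatial)
    for axis, n in enumerate(spatial):
        stack_axis = axis + 2
        nb = -(-n // factor)
        pad = nb * factor - n
        if pad:
            padding = [(0, 0)] * data.ndim
            padding[stack_axis] = (0, pad)
            data = np.pad(data, padding)
            cpad = [(0, 0)] * counts.ndim
            cpad[axis] = (0, pad)
            counts = np.pad(counts, cpad)
        shape = data.shape[:stack_axis] + (nb, factor) + data.shape[stack_axis + 1:]
        data = data.reshape(shape).sum(axis=stack_axis + 1)
        cshape = counts.shape[:axis] + (nb, factor) + counts.shape[axis + 1:]
        counts = counts.reshape(cshape).sum(axis=axis + 1)
    return ImageStack(data / counts[None, None])


def upsample_density(
    F_coarse: np.ndarray,
    factor: int,
    fine_shape: tuple[int, ...],
    coarse_shape: tuple[int, ...],
) -> np.ndarray:
    """Nearest-neighbor replication preserving total summed density.

    Each coarse value is copied into its factor-block and divided by the
    block's actual voxel count (factor^d in the interior, fewer at edges).
    """
    if factor < 1:
        raise ValidationError("factor must be a positive integer")
    exp_coarse = tuple(-(-n // factor) for n in fine_shape)
    if tuple(coarse_shape) != exp_coarse:
        raise ValidationError(
            f"coarse shape {coarse_shape} inconsistent with fine {fine_shape} "
            f"at factor {factor}"
        )
    if F_coarse.shape[0] != int(np.prod(coarse_shape)):
        raise ValidationError("F_coarse rows do not match coarse_shape")
    if factor == 1:
        return F_coarse.copy()
    J = F_coarse.shape[1]
    out = np.empty((int(np.prod(fine_shape)), J))
    # per-block fine-voxel count (factor^d in the interior, fewer at edges)
    idx = np.meshgrid(*[np.arange(n) // factor for n in fine_shape], indexing="ij")
    flat_block = tuple(i.ravel() for i in idx)
    counts = np.zeros(exp_coarse)
    np.add.at(counts, flat_block, 1.0)
    for j in range(J):
        vals = F_coarse[:, j].reshape(exp_coarse)
        out[:, j] = (vals / counts)[flat_block]
    return out


def sparsify_barcodes(
    F_coarse: np.ndarray, codebook: Codebook, tol: float = np.finfo(float).eps
) -> np.ndarray:
    """Indices of barcodes worth keeping at the fine scale.

    Keeps every barcode whose maximum coarse density exceeds ``tol``;
    unused barcodes are always retained, since they calibrate the
    spot-calling threshold.
    """
    if tol < 0:
        raise ValidationError("tol must be non-negative")
    keep = F_coarse.max(axis=0) > tol
    keep |= codebook.unused_mask
    return np.flatnonzero(keep)


def fit_accelerated(
    X: ImageStack,
    codebook: Codebook,
    psf: PointSpreadFunction,
    config: FitConfig | None = None,
    patch_grid: PatchGrid | None = None,
    factor: int = 2,
    tol: float = np.finfo(float).eps,
    coarse_iters: int = COARSE_ITERS,
    fine_iters: int = FINE_ITERS,
) -> FitResult:
    """Patch-parallelizable coarse-to-fine fit.

    Per padded patch: fit on ``factor``-downsampled data, drop barcodes
    with no coarse density, then fit the full-resolution patch restricted
    to the retained barcodes, initialized from the upsampled coarse
    density.  Core regions are stitched back (each voxel's result comes
    from exactly one patch), so results do not depend on patch order.

    With ``factor=1`` the coarse stage is the identity problem and is
    skipped; a single full-grid patch then reduces exactly to :func:`fit`.
    """
    config = config or FitConfig()
    if patch_grid is None:
        patch_grid = PatchGrid(
            spatial_shape=X.spatial_shape,
            patch_size=X.spatial_shape,
            halo=psf.halo(len(X.spatial_shape)),
        )
    if tuple(patch_grid.spatial_shape) != tuple(X.spatial_shape):
        raise ValidationError("patch grid does not match the stack's spatial shape")

    patches = patch_grid.patches
    if factor == 1 and len(patches) == 1:
        return fit(X, codebook, psf, config)

    spatial = X.spatial_shape
    F_full = np.zeros((X.M, codebook.J))
    a_full = np.zeros(X.M)
    b_acc = np.zeros((X.R, X.C))
    alpha_acc = np.zeros((X.R, X.C))
    phi_acc = np.zeros((X.C, X.C))
    rho_acc = np.zeros(X.C)
    traj_last: list = []
    converged = True
    omega = select_noise_threshold(X, codebook, psf, config)

    lin = np.arange(X.M).reshape(spatial)
    # process in a canonical order so scalar accumulations are bitwise
    # independent of the order patches were listed (or computed) in
    patches = sorted(patches, key=lambda cp: tuple(s.start for s in cp[0]))
    for core, padded in patches:
        try:
            sub = ImageStack(X.data[(slice(None), slice(None)) + padded])
            res = _fit_patch(
                sub, codebook, psf, config, factor, tol, coarse_iters, fine_iters
            )
        except Exception as exc:  # annotate with patch identity
            raise RuntimeError(f"patch {core} failed: {exc}") from exc
        converged &= res.converged
        traj_last = res.trajectory
        # keep only the core region of this patch
        pad_shape = sub.spatial_shape
        core_in_pad = tuple(
            slice(c.start - p.start, c.stop - p.start)
            for c, p in zip(core, padded)
        )
        pad_lin = np.arange(int(np.prod(pad_shape))).reshape(pad_shape)
        core_rows_pad = pad_lin[core_in_pad].ravel()
        core_rows_full = lin[core].ravel()
        F_full[core_rows_full] = res.params.F[core_rows_pad]
        a_full[core_rows_full] = res.params.a[core_rows_pad]
        w = core_rows_full.size
        b_acc += w * res.params.b
        alpha_acc += w * res.params.alpha
        phi_acc += w * res.params.phi
        rho_acc += w * res.params.rho

    n = X.M
    params = ModelParameters(
        F=F_full, a=a_full, b=b_acc / n,
        alpha=np.maximum(alpha_acc / n, 1e-300),
        phi=np.clip(phi_acc / n, 0.0, 1.0),
        rho=np.clip(rho_acc / n, 0.0, 1.0),
    )
    return FitResult(
        params=normalize_scale(params),
        omega=omega,
        trajectory=traj_last,
        converged=converged,
    )


def _fit_patch(sub, codebook, psf, config, factor, tol, coarse_iters, fine_iters):
    """Coarse fit -> sparsify -> restricted warm-started fine fit."""
    if factor == 1:
        return fit(sub, codebook, psf, config)
    coarse = downsample_stack(sub, factor)
    coarse_cfg = dataclasses.replace(config, max_iters=coarse_iters)
    res_c = fit(coarse, codebook, psf.scaled(factor), coarse_cfg)
    keep = sparsify_barcodes(res_c.params.F, codebook, tol)
    sub_cb = codebook.subset(keep)
    F0 = upsample_density(
        res_c.params.F[:, keep], factor, sub.spatial_shape, coarse.spatial_shape
    )
    p0 = ModelParameters(
        F=F0,
        a=res_c.params.a[
            _upsample_rows(coarse.spatial_shape, sub.spatial_shape, factor)
        ],
        b=res_c.params.b.copy(),
        alpha=res_c.params.alpha.copy(),
        phi=res_c.params.phi.copy(),
        rho=res_c.params.rho.copy(),
    )
    fine_cfg = dataclasses.replace(config, max_iters=fine_iters)
    res_f = fit(sub, sub_cb, psf, fine_cfg, params_init=p0)
    F_full = np.zeros((sub.M, codebook.J))
    F_full[:, keep] = res_f.params.F
    params = ModelParameters(
        F=F_full, a=res_f.params.a, b=res_f.params.b,
        alpha=res_f.params.alpha, phi=res_f.params.phi, rho=res_f.params.rho,
    )
    return FitResult(
        params=params, omega=res_f.omega,
        trajectory=res_f.trajectory, converged=res_f.converged, lam=res_f.lam,
    )


def _upsample_rows(coarse_shape, fine_shape, factor):
    """Row indices mapping each fine voxel to its coarse block."""
    idx = np.meshgrid(*[np.arange(n) // factor for n in fine_shape], indexing="ij")
    coarse_lin = np.ravel_multi_index(
        tuple(i.ravel() for i in idx), coarse_shape
    )
    return coarse_lin
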