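"""Core data containers for barcoded in-situ sequencing demixing.

The observation model describes a registered, background-subtracted
fluorescence image stack ``X`` indexed by imaging round *r*, color channel
*c* and voxel *m*.  Rolonies (rolling-circle-amplified transcripts) of
barcode *j* contribute signal according to a binary codebook ``B``, blurred
by a point-spread function ``K`` and modulated by per-round/per-channel
gains, channel cross-talk and round-to-round phasing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageStack",
    "Codebook",
    "ModelParameters",
    "PointSpreadFunction",
    "PhasedCodebook",
    "NoiseThreshold",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")
    return arr


@dataclass
class ImageStack:
    """Observed (or reconstructed) intensities, shape ``(R, C, *spatial)``.

    Voxel index *m* is the row-major, 0-based linearization of the spatial
    grid (2-D or 3-D).
    """

    data: np.ndarray

    def __post_init__(self):
        self.data = _as_float_array(self.data, "stack data")
        if self.data.ndim not in (4, 5):
            raise ValidationError(
                f"stack must be (R, C, y, x) or (R, C, z, y, x); got ndim={self.data.ndim}"
            )
        if np.any(self.data < 0):
            raise ValidationError("stack intensities must be non-negative")

    @property
    def R(self) -> int:
        return self.data.shape[0]

    @property
    def C(self) -> int:
        return self.data.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[2:]

    @property
    def M(self) -> int:
        return int(np.prod(self.spatial_shape))

    @property
    def flat(self) -> np.ndarray:
        """View of the data as ``(R, C, M)``."""
        return self.data.reshape(self.R, self.C, self.M)


@dataclass
class Codebook:
    """Binary codebook ``B`` of shape ``(R, C, J)`` with gene labels.

    ``unused_mask`` marks barcodes deliberately absent from the experiment;
    their fitted densities calibrate the spot-calling threshold.
    """

    B: np.ndarray
    gene_names: list[str]
    unused_mask: np.ndarray | None = None

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 3:
            raise ValidationError("codebook B must have shape (R, C, J)")
        if not np.isin(self.B, (0.0, 1.0)).all():
            raise ValidationError("codebook entries must be 0 or 1")
        if np.any(self.B.sum(axis=(0, 1)) == 0):
            raise ValidationError("every barcode needs at least one active (round, channel)")
        self.gene_names = list(self.gene_names)
        if len(self.gene_names) != self.J:
            raise ValidationError(
                f"{len(self.gene_names)} gene names for {self.J} barcodes"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValidationError("duplicate gene names in codebook")
        if self.unused_mask is None:
            self.unused_mask = np.zeros(self.J, dtype=bool)
        else:
            self.unused_mask = np.asarray(self.unused_mask, dtype=bool)
            if self.unused_mask.shape != (self.J,):
                raise ValidationError("unused_mask length must equal J")

    @property
    def R(self) -> int:
        return self.B.shape[0]

    @property
    def C(self) -> int:
        return self.B.shape[1]

    @property
    def J(self) -> int:
        return self.B.shape[2]

    @property
    def one_hot_per_round(self) -> bool:
        """True when every (round, barcode) slice activates exactly one channel."""
        return bool(np.all(self.B.sum(axis=1) == 1))

    @property
    def used_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.unused_mask)

    @property
    def unused_indices(self) -> np.ndarray:
        return np.flatnonzero(self.unused_mask)

    def subset(self, indices) -> "Codebook":
        indices = np.asarray(indices, dtype=int)
        return Codebook(
            B=self.B[:, :, indices],
            gene_names=[self.gene_names[i] for i in indices],
            unused_mask=self.unused_mask[indices],
        )


@dataclass
class ModelParameters:
    """All free parameters of the observation model.

    F     : (M, J) rolony density, >= 0
    a     : (M,)   per-voxel background, >= 0
    b     : (R, C) per-round per-channel offset, >= 0
    alpha : (R, C) per-round per-channel scale, >= 0
    phi   : (C, C) channel wavelength-response (cross-talk), entries in [0, 1]
    rho   : (C,)   per-channel phasing factor, entries in [0, 1]
    """

    F: np.ndarray
    a: np.ndarray
    b: np.ndarray
    alpha: np.ndarray
    phi: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        for name in ("F", "a", "b", "alpha", "phi", "rho"):
            setattr(self, name, _as_float_array(getattr(self, name), name))
        if self.F.ndim != 2:
            raise ValidationError("F must have shape (M, J)")
        R, C = self.b.shape
        if self.alpha.shape != (R, C):
            raise ValidationError("alpha and b must share shape (R, C)")
        if self.phi.shape != (C, C):
            raise ValidationError("phi must have shape (C, C)")
        if self.rho.shape != (C,):
            raise ValidationError("rho must have shape (C,)")
        for name in ("F", "a", "b", "alpha"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{name} must be non-negative")
        for name in ("phi", "rho"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValidationError(f"{name} entries must lie in [0, 1]")

    @property
    def M(self) -> int:
        return self.F.shape[0]

    @property
    def J(self) -> int:
        return self.F.shape[1]

    @property
    def R(self) -> int:
        return self.b.shape[0]

    @property
    def C(self) -> int:
        return self.b.shape[1]

    def copy(self) -> "ModelParameters":
        return ModelParameters(**{
            f.name: getattr(self, f.name).copy() for f in dataclasses.fields(self)
        })

    @classmethod
    def zeros(cls, M: int, J: int, R: int, C: int) -> "ModelParameters":
        return cls(
            F=np.zeros((M, J)),
            a=np.zeros(M),
            b=np.zeros((R, C)),
            alpha=np.full((R, C), 1.0 / (R * C)),
            phi=np.eye(C),
            rho=np.zeros(C),
        )


@dataclass
class PointSpreadFunction:
    """Isotropic (per-axis) Gaussian blur, truncated and sum-normalized.

    ``sigma`` is given in voxels, one value per spatial dimension (a scalar
    broadcasts).  ``sigma = 0`` is the identity kernel.  The kernel is
    applied by separable convolution with reflective boundary handling, so
    the induced operator is symmetric (self-adjoint) and has spectral norm
    at most 1.
    """

    sigma: tuple[float, ...] | float = 1.0
    truncation_radius: float = 4.0

    def __post_init__(self):
        if np.isscalar(self.sigma):
            self.sigma = (float(self.sigma),)
        else:
            self.sigma = tuple(float(s) for s in self.sigma)
        if any(s < 0 for s in self.sigma):
            raise ValidationError("psf sigma must be non-negative")
        if self.truncation_radius <= 0:
            raise ValidationError("truncation_radius must be positive")

    def sigmas_for(self, ndim: int) -> tuple[float, ...]:
        if len(self.sigma) == 1:
            return self.sigma * ndim
        if len(self.sigma) != ndim:
            raise ValidationError(
                f"psf has {len(self.sigma)} sigmas for a {ndim}-D grid"
            )
        return self.sigma

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Convolve a spatial image with the kernel."""
        sig = self.sigmas_for(image.ndim)
        if all(s == 0 for s in sig):
            return np.array(image, dtype=float)
        return ndimage.gaussian_filter(
            np.asarray(image, dtype=float), sigma=sig,
            mode="reflect", truncate=self.truncation_radius,
        )

    def apply_to_density(self, F: np.ndarray, spatial_shape: tuple[int, ...]) -> np.ndarray:
        """Blur each column of an (M, J) density matrix; returns K*F, (M, J)."""
        M = int(np.prod(spatial_shape))
        if F.shape[0] != M:
            raise ValidationError("density rows do not match the spatial grid")
        out = np.empty_like(F, dtype=float)
        for j in range(F.shape[1]):
            out[:, j] = self.apply(F[:, j].reshape(spatial_shape)).ravel()
        return out

    def scaled(self, factor: float) -> "PointSpreadFunction":
        """PSF expressed on a grid coarsened by ``factor``."""
        return PointSpreadFunction(
            sigma=tuple(s / factor for s in self.sigma),
            truncation_radius=self.truncation_radius,
        )

    def halo(self, ndim: int = 2) -> int:
        """Voxel radius beyond which the truncated kernel is identically zero."""
        sig = self.sigmas_for(ndim)
        return int(np.ceil(self.truncation_radius * max(sig))) if max(sig) > 0 else 0


@dataclass
class PhasedCodebook:
    """Phased barcodes ``Z`` and scaled color-mixed barcodes ``G``.

    ``Z[r,c,j]`` is the probe concentration expected at round *r* from a
    barcode-*j* rolony once incomplete stripping (phasing) is accounted for;
    ``G[r,c,j] = alpha[r,c] * sum_c' phi[c,c'] Z[r,c',j]`` is the total
    fluorescence expected in (round, channel) per unit density.
    """

    Z: np.ndarray
    G: np.ndarray | None = None


@dataclass
class NoiseThreshold:
    """Tolerated total squared reconstruction error (omega)."""

    omega: float = 0.0

    def __post_init__(self):
        self.omega = float(self.omega)
        if self.omega < 0:
            raise ValidationError("omega must be non-negative")
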