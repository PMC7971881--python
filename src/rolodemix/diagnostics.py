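"""Model-checking diagnostics.

The *cleaned image* for a barcode j* is the data with every modeled
component subtracted except j*'s own contribution:

    X(j*)[m,r,c] = X[m,r,c] - a[m] - b[r,c] - sum_{j != j*} (K*F_j)[m] G[r,c,j]

Under the model this tensor is approximately rank one: the outer product of
the blurred density (K*F_{j*}) with the gain vector G_{j*}.  The rank-one
structure is checked by SVD in a small window around each called spot; the
squared correlation between the window and its best rank-one approximation
is the spot's quality score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    Codebook,
    ImageStack,
    ModelParameters,
    PointSpreadFunction,
    ValidationError,
)
from .core import gain_tensor

__all__ = [
    "CleanedImage",
    "SpotQuality",
    "cleaned_image",
    "rank_one_diagnostic",
    "residual_summary",
    "quality_histogram",
]


@dataclass
class CleanedImage:
    """Counterfactual stack keeping only one barcode's contribution.

    Entries may be negative: the subtraction is residual-style.
    """

    data: np.ndarray  # (R, C, *spatial)
    barcode_index: int


@dataclass
class SpotQuality:
    """Rank-one SVD summary of a cleaned-image window around one spot."""

    barcode_index: int
    voxel: tuple[int, ...]
    r_squared: float
    spatial_vector: np.ndarray
    temporal_vector: np.ndarray  # length R*C


def cleaned_image(
    X: ImageStack,
    params: ModelParameters,
    psf: PointSpreadFunction,
    codebook: Codebook,
    j_star: int,
) -> CleanedImage:
    """Subtract background, offsets and all other barcodes' contributions."""
    if not 0 <= j_star < codebook.J:
        raise ValidationError(f"j_star={j_star} outside 0..{codebook.J - 1}")
    G = gain_tensor(params, codebook)
    F_others = params.F.copy()
    F_others[:, j_star] = 0.0
    KF = psf.apply_to_density(F_others, X.spatial_shape)
    others = np.einsum("mj,rcj->rcm", KF, G)
    flat = X.flat - params.a[None, None, :] - params.b[:, :, None] - others
    return CleanedImage(
        data=flat.reshape(X.data.shape), barcode_index=int(j_star)
    )


def _window_slices(center, width, shape):
    slices = []
    for c, n in zip(center, shape):
        lo = c - width // 2
        hi = lo + width
        if lo < 0 or hi > n:
            raise ValidationError(
                f"window of width {width} at {tuple(center)} exceeds grid {shape}"
            )
        slices.append(slice(lo, hi))
    return tuple(slices)


def rank_one_diagnostic(
    cleaned: CleanedImage,
    voxel: tuple[int, ...],
    window: int = 10,
) -> SpotQuality:
    """SVD check of the rank-one structure around one spot.

    The windowed cleaned image is reshaped to (voxels, R*C) and decomposed;
    R^2 is the squared Pearson correlation between the window and the top
    rank-one approximation.  Signs are fixed so the temporal vector's
    largest-magnitude entry is positive.  An all-zero window scores 0.
    """
    data = cleaned.data
    R, C = data.shape[:2]
    spatial = data.shape[2:]
    sl = _window_slices(voxel, window, spatial)
    win = data[(slice(None), slice(None)) + sl]  # (R, C, *window)
    nvox = int(np.prod(win.shape[2:]))
    mat = win.reshape(R * C, nvox).T  # (voxels, R*C)
    if not np.any(mat):
        return SpotQuality(
            barcode_index=cleaned.barcode_index, voxel=tuple(voxel),
            r_squared=0.0, spatial_vector=np.zeros(nvox),
            temporal_vector=np.zeros(R * C),
        )
    U, S, Vt = np.linalg.svd(mat, full_matrices=False)
    spatial_vec = U[:, 0] * S[0]
    temporal_vec = Vt[0]
    k = int(np.argmax(np.abs(temporal_vec)))
    if temporal_vec[k] < 0:
        temporal_vec = -temporal_vec
        spatial_vec = -spatial_vec
    approx = np.outer(spatial_vec, temporal_vec)
    va, vb = mat.ravel(), approx.ravel()
    va_c, vb_c = va - va.mean(), vb - vb.mean()
    denom = np.linalg.norm(va_c) * np.linalg.norm(vb_c)
    r2 = float((va_c @ vb_c) ** 2 / denom**2) if denom > 0 else 0.0
    return SpotQuality(
        barcode_index=cleaned.barcode_index,
        voxel=tuple(voxel),
        r_squared=min(max(r2, 0.0), 1.0),
        spatial_vector=spatial_vec,
        temporal_vector=temporal_vec,
    )


def residual_summary(X: ImageStack, reconstruction: ImageStack) -> float:
    """Percentage of variance left unexplained by the reconstruction.

    100 * sum((X - reconstruction)^2) / sum((X - mean(X))^2).  Undefined
    (NaN, with a warning) for a constant stack.
    """
    if X.data.shape != reconstruction.data.shape:
        raise ValidationError("stack and reconstruction shapes differ")
    num = float(np.sum((X.data - reconstruction.data) ** 2))
    den = float(np.sum((X.data - X.data.mean()) ** 2))
    if den == 0.0:
        import warnings

        warnings.warn("constant stack: percentage unexplained is undefined")
        return float("nan")
    return 100.0 * num / den


def quality_histogram(qualities: list[SpotQuality], n_bins: int = 20):
    """Bin spot R^2 values over [0, 1].

    Returns ``(counts, bin_edges, table)`` where ``table`` is a pandas
    DataFrame with one row per spot.
    """
    import pandas as pd

    r2 = np.array([q.r_squared for q in qualities], dtype=float)
    counts, edges = np.histogram(r2, bins=n_bins, range=(0.0, 1.0))
    table = pd.DataFrame(
        {
            "barcode_index": [q.barcode_index for q in qualities],
            "voxel": [q.voxel for q in qualities],
            "r_squared": r2,
        }
    )
    return counts, edges, table
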