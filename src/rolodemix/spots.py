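"""Spot calling on fitted rolony-density images.

Rolonies are read off the per-barcode density images as local maxima.  The
detection threshold is calibrated with *unused barcodes*: valid codes
absent from the experiment, whose fitted densities can only be noise.  The
threshold is the smallest value that excludes every blob found in the
unused-barcode images.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import Codebook, ValidationError

__all__ = [
    "augment_codebook",
    "find_local_maxima",
    "select_threshold_from_unused",
    "call_spots",
]

#: Columns of a spot table (coordinate columns depend on dimensionality).
SPOT_COLUMNS = ("gene", "barcode_index", "density", "passes_threshold")


def augment_codebook(
    codebook: Codebook,
    n_unused: int = 2,
    min_round_diff: int = 3,
    seed: int = 0,
) -> Codebook:
    """Append unused barcodes for threshold calibration.

    Candidates are enumerated over all one-hot-per-round codes; a uniformly
    random subset is kept such that every appended barcode differs from
    every other barcode (original and appended) in at least
    ``min_round_diff`` rounds.
    """
    if n_unused < 0 or min_round_diff < 1:
        raise ValidationError("n_unused must be >= 0 and min_round_diff >= 1")
    if n_unused == 0:
        return codebook
    if codebook.J > 0 and not codebook.one_hot_per_round:
        raise ValidationError("augmentation requires a one-hot-per-round codebook")
    R, C = codebook.R, codebook.C
    if min_round_diff > R:
        raise ValidationError(
            f"barcodes with {R} rounds cannot differ in {min_round_diff} rounds"
        )
    # active-channel representation: one channel index per round
    existing = [tuple(int(np.argmax(codebook.B[r, :, j])) for r in range(R))
                for j in range(codebook.J)]
    rng = np.random.default_rng(seed)
    candidates = np.array(list(itertools.product(range(C), repeat=R)), dtype=int)
    rng.shuffle(candidates)

    def round_diff(u, v):
        return int(np.sum(np.asarray(u) != np.asarray(v)))

    chosen: list[tuple[int, ...]] = []
    for cand in map(tuple, candidates):
        others = existing + chosen
        if all(round_diff(cand, o) >= min_round_diff for o in others):
            chosen.append(cand)
            if len(chosen) == n_unused:
                break
    if len(chosen) < n_unused:
        raise ValidationError(
            f"only {len(chosen)} of {n_unused} unused barcodes satisfy the "
            f"min_round_diff={min_round_diff} constraint"
        )
    B_new = np.zeros((R, C, codebook.J + n_unused))
    B_new[:, :, : codebook.J] = codebook.B
    for k, code in enumerate(chosen):
        for r, c in enumerate(code):
            B_new[r, c, codebook.J + k] = 1.0
    names = codebook.gene_names + [f"unused_{k}" for k in range(n_unused)]
    mask = np.concatenate([codebook.unused_mask, np.ones(n_unused, dtype=bool)])
    return Codebook(B=B_new, gene_names=names, unused_mask=mask)


def find_local_maxima(
    density_image: np.ndarray, footprint_radius: int = 1
) -> list[tuple[tuple[int, ...], float]]:
    """Strictly positive local maxima of a per-barcode density image.

    A voxel qualifies when its value is >= every value in the surrounding
    (2r+1)-per-side box.  Plateau ties keep only the lexicographically
    smallest coordinate within each tied neighborhood, so output is
    deterministic.  Returned sorted by coordinate.
    """
    img = np.asarray(density_image, dtype=float)
    if np.any(img < 0):
        raise ValidationError("density image must be non-negative")
    if footprint_radius < 1:
        raise ValidationError("footprint_radius must be a positive integer")
    size = 2 * int(footprint_radius) + 1
    mx = ndimage.maximum_filter(img, size=size, mode="constant", cval=0.0)
    cand = sorted(map(tuple, np.argwhere((img >= mx) & (img > 0))))
    kept = []
    for i, coord in enumerate(cand):
        # plateau tie-break: suppressed by any lexicographically smaller
        # equal-valued candidate inside the footprint
        dominated = any(
            img[other] == img[coord]
            and all(abs(a - b) <= footprint_radius for a, b in zip(coord, other))
            for other in cand[:i]
        )
        if not dominated:
            kept.append((coord, float(img[coord])))
    return kept


def select_threshold_from_unused(
    F: np.ndarray,
    codebook: Codebook,
    spatial_shape: tuple[int, ...],
    footprint_radius: int = 1,
) -> float:
    """Smallest threshold excluding every blob in the unused barcodes.

    Returns the maximum local-maximum value across unused-barcode density
    images, nudged up by one representable increment so a strict
    ``density > threshold`` test rejects all of them; 0 when the unused
    densities are identically zero.
    """
    unused = codebook.unused_indices
    if unused.size == 0:
        raise ValidationError(
            "no unused barcodes in the codebook; run augment_codebook first "
            "or supply a manual threshold"
        )
    peak = 0.0
    for j in unused:
        for _, value in find_local_maxima(F[:, j].reshape(spatial_shape), footprint_radius):
            peak = max(peak, value)
    return float(np.nextafter(peak, np.inf)) if peak > 0 else 0.0


def call_spots(
    F: np.ndarray,
    codebook: Codebook,
    spatial_shape: tuple[int, ...],
    threshold: float = 0.0,
    footprint_radius: int = 1,
    psf=None,
) -> pd.DataFrame:
    """Local maxima of every non-unused barcode image, as a spot table.

    One row per (barcode, voxel) local maximum with columns gene,
    barcode_index, one 0-based coordinate column per spatial dimension
    (z, y, x as applicable), density and passes_threshold
    (density > threshold).  Rows are ordered by (barcode, voxel).  Passing
    ``psf`` runs detection on the blurred densities K*F instead
    (visualization-style smoothing); default is the deconvolved F.
    """
    ndim = len(spatial_shape)
    coord_names = ("z", "y", "x")[-ndim:]
    Fd = psf.apply_to_density(F, spatial_shape) if psf is not None else F
    rows = []
    for j in range(codebook.J):
        if codebook.unused_mask[j]:
            continue
        img = Fd[:, j].reshape(spatial_shape)
        for coord, value in find_local_maxima(img, footprint_radius):
            rows.append(
                {
                    "gene": codebook.gene_names[j],
                    "barcode_index": j,
                    **dict(zip(coord_names, coord)),
                    "density": value,
                    "passes_threshold": bool(value > threshold),
                }
            )
    columns = ["gene", "barcode_index", *coord_names, "density", "passes_threshold"]
    table = pd.DataFrame(rows, columns=columns)
    table["barcode_index"] = table["barcode_index"].astype(int)
    for c in coord_names:
        table[c] = table[c].astype(int)
    table["passes_threshold"] = table["passes_threshold"].astype(bool)
    return table
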