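"""Readers and writers for stacks, codebooks, parameters and outputs.

Formats
-------
stack        HDF5 file with a dataset ``data`` of shape (R, C, y, x) or
             (R, C, z, y, x); or a directory of per-frame TIFFs named
             ``r{round}_c{channel}.tif`` (0-based, round-major).
codebook     CSV; wide dialect ``gene,round1..roundR`` with 0-based active
             channel indices (one-hot-per-round), or long dialect
             ``gene,round,channel`` for general binary codebooks.  An
             optional ``unused`` column (0/1) marks unused barcodes.
spots        CSV with gene, barcode_index, one 0-based coordinate column
             per spatial dimension, density, passes_threshold.
diagnostics  HDF5 with per-spot records and the fitted parameters.

All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import Codebook, ImageStack, ModelParameters, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_stack",
    "write_stack",
    "read_codebook",
    "write_codebook",
    "read_params",
    "write_params",
    "write_outputs",
    "load_config",
]


def _atomic_path(path: Path):
    """Temp file in the target directory, to be os.replace'd into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    return Path(tmp)


def read_stack(path) -> ImageStack:
    """Read an image stack from HDF5 or a TIFF frame directory.

    Negative intensities are clamped to zero; the number of clamped
    entries is logged as a warning.
    """
    path = Path(path)
    if path.is_dir():
        data = _read_tiff_dir(path)
    else:
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise ValidationError(f"{path} has no 'data' dataset")
            data = f["data"][...].astype(float)
        if data.ndim not in (4, 5):
            raise ValidationError(
                f"stack dataset must be 4-D or 5-D; got {data.ndim}-D"
            )
    n_neg = int(np.sum(data < 0))
    if n_neg:
        logger.warning("clamped %d negative intensities to zero", n_neg)
        data = np.maximum(data, 0.0)
    return ImageStack(data)


def _read_tiff_dir(path: Path) -> np.ndarray:
    frames = sorted(path.glob("r*_c*.tif"))
    if not frames:
        raise ValidationError(f"no r{{round}}_c{{channel}}.tif frames in {path}")
    coords = []
    for p in frames:
        stem = p.stem  # r{r}_c{c}
        try:
            rpart, cpart = stem.split("_")
            coords.append((int(rpart[1:]), int(cpart[1:])))
        except (ValueError, IndexError):
            raise ValidationError(f"unrecognized frame name {p.name}")
    R = max(r for r, _ in coords) + 1
    C = max(c for _, c in coords) + 1
    grid = {}
    shape = None
    for (r, c), p in zip(coords, frames):
        img = tifffile.imread(p).astype(float)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValidationError(
                f"frame {p.name} has shape {img.shape}, expected {shape}"
            )
        grid[(r, c)] = img
    missing = [(r, c) for r in range(R) for c in range(C) if (r, c) not in grid]
    if missing:
        r, c = missing[0]
        raise ValidationError(f"missing frame r{r}_c{c}.tif")
    data = np.stack(
        [np.stack([grid[(r, c)] for c in range(C)]) for r in range(R)]
    )
    return data


def write_stack(X: ImageStack, path) -> None:
    path = Path(path)
    tmp = _atomic_path(path)
    try:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("data", data=X.data)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def read_codebook(path, n_channels: int | None = None) -> Codebook:
    """Read a codebook CSV in wide or long dialect."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "gene" not in cols:
        raise ValidationError("codebook CSV needs a 'gene' column")
    unused_col = df.pop("unused") if "unused" in cols else None
    if {"round", "channel"} <= set(df.columns):
        return _codebook_from_long(df, n_channels, unused_col)
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate gene name: {dup!r}")
    return _codebook_from_wide(df, n_channels, unused_col)


def _codebook_from_wide(df, n_channels, unused_col):
    round_cols = [c for c in df.columns if c.startswith("round")]
    if not round_cols:
        raise ValidationError("wide codebook needs round1..roundR columns")
    round_cols = sorted(round_cols, key=lambda c: int(c.replace("round", "")))
    R = len(round_cols)
    vals = df[round_cols].to_numpy()
    if np.isnan(vals).any():
        raise ValidationError("ragged or missing entries in codebook")
    vals = vals.astype(int)
    C = n_channels if n_channels is not None else int(vals.max()) + 1
    if vals.max() >= C or vals.min() < 0:
        raise ValidationError(
            f"channel index {vals.max()} out of range for {C} channels"
        )
    J = len(df)
    B = np.zeros((R, C, J))
    for j in range(J):
        for r in range(R):
            B[r, vals[j, r], j] = 1.0
    mask = unused_col.to_numpy().astype(bool) if unused_col is not None else None
    return Codebook(B=B, gene_names=df["gene"].tolist(), unused_mask=mask)


def _codebook_from_long(df, n_channels, unused_col):
    genes = list(dict.fromkeys(df["gene"]))
    R = int(df["round"].max()) + 1
    C = n_channels if n_channels is not None else int(df["channel"].max()) + 1
    if df["channel"].max() >= C or df["channel"].min() < 0:
        raise ValidationError(
            f"channel index {int(df['channel'].max())} out of range for {C} channels"
        )
    B = np.zeros((R, C, len(genes)))
    jmap = {g: j for j, g in enumerate(genes)}
    for _, row in df.iterrows():
        B[int(row["round"]), int(row["channel"]), jmap[row["gene"]]] = 1.0
    mask = None
    if unused_col is not None:
        per_gene = {}
        for g, u in zip(df["gene"], unused_col):
            per_gene[g] = bool(u)
        mask = np.array([per_gene[g] for g in genes])
    return Codebook(B=B, gene_names=genes, unused_mask=mask)


def write_codebook(codebook: Codebook, path) -> None:
    """Write in the dialect matching the codebook's structure."""
    path = Path(path)
    tmp = _atomic_path(path)
    try:
        if codebook.one_hot_per_round:
            rows = {
                "gene": codebook.gene_names,
                **{
                    f"round{r + 1}": np.argmax(codebook.B[r], axis=0)
                    for r in range(codebook.R)
                },
                "unused": codebook.unused_mask.astype(int),
            }
            pd.DataFrame(rows).to_csv(tmp, index=False)
        else:
            recs = []
            for j, g in enumerate(codebook.gene_names):
                for r, c in zip(*np.nonzero(codebook.B[:, :, j])):
                    recs.append(
                        {"gene": g, "round": r, "channel": c,
                         "unused": int(codebook.unused_mask[j])}
                    )
            pd.DataFrame(recs).to_csv(tmp, index=False)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


_PARAM_NAMES = ("F", "a", "b", "alpha", "phi", "rho")


def write_params(params: ModelParameters, path, spatial_shape=None) -> None:
    path = Path(path)
    tmp = _atomic_path(path)
    try:
        with h5py.File(tmp, "w") as f:
            for name in _PARAM_NAMES:
                f.create_dataset(name, data=getattr(params, name))
            if spatial_shape is not None:
                f.attrs["spatial_shape"] = tuple(int(n) for n in spatial_shape)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def read_params(path):
    """Returns (ModelParameters, spatial_shape or None)."""
    with h5py.File(path, "r") as f:
        kw = {name: f[name][...] for name in _PARAM_NAMES}
        shape = tuple(f.attrs["spatial_shape"]) if "spatial_shape" in f.attrs else None
    return ModelParameters(**kw), shape


def write_outputs(
    out_dir,
    spots: pd.DataFrame,
    qualities=None,
    params: ModelParameters | None = None,
    spatial_shape=None,
    histogram=None,
) -> dict[str, Path]:
    """Write the three standard outputs into ``out_dir``.

    1. ``spots.csv`` — the spot table;
    2. ``diagnostics.h5`` — per-spot quality records plus fitted parameters;
    3. ``quality_histogram.csv`` / ``.png`` — 20-bin histogram of spot R^2.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise ValidationError(f"output directory {out_dir} is not writable")
    written = {}

    spot_path = out_dir / "spots.csv"
    tmp = _atomic_path(spot_path)
    try:
        spots.to_csv(tmp, index=False)
        os.replace(tmp, spot_path)
    finally:
        tmp.unlink(missing_ok=True)
    written["spots"] = spot_path

    qualities = qualities or []
    diag_path = out_dir / "diagnostics.h5"
    tmp = _atomic_path(diag_path)
    try:
        with h5py.File(tmp, "w") as f:
            g = f.create_group("spots")
            g.create_dataset(
                "barcode_index", data=np.array([q.barcode_index for q in qualities], int)
            )
            voxels = (
                np.array([q.voxel for q in qualities], int)
                if qualities
                else np.zeros((0, 2), int)
            )
            g.create_dataset("voxel", data=voxels)
            g.create_dataset(
                "r_squared", data=np.array([q.r_squared for q in qualities])
            )
            if qualities:
                g.create_dataset(
                    "temporal_vector",
                    data=np.stack([q.temporal_vector for q in qualities]),
                )
            if params is not None:
                gp = f.create_group("params")
                for name in _PARAM_NAMES:
                    gp.create_dataset(name, data=getattr(params, name))
                if spatial_shape is not None:
                    gp.attrs["spatial_shape"] = tuple(int(n) for n in spatial_shape)
        os.replace(tmp, diag_path)
    finally:
        tmp.unlink(missing_ok=True)
    written["diagnostics"] = diag_path

    from .diagnostics import quality_histogram as _qh

    counts, edges, _ = _qh(qualities) if histogram is None else histogram
    hist_df = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    hist_path = out_dir / "quality_histogram.csv"
    tmp = _atomic_path(hist_path)
    try:
        hist_df.to_csv(tmp, index=False)
        os.replace(tmp, hist_path)
    finally:
        tmp.unlink(missing_ok=True)
    written["histogram"] = hist_path

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
               edgecolor="white")
        ax.set_xlabel("spot quality $R^2$")
        ax.set_ylabel("number of spots")
        fig.tight_layout()
        png_path = out_dir / "quality_histogram.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        written["histogram_png"] = png_path
    except Exception as exc:  # plotting failure must not discard results
        logger.warning("histogram plot failed: %s", exc)

    return written


def load_config(path) -> dict:
    """Flat key-value YAML configuration."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a mapping")
    return cfg
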