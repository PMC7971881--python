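"""Model / Results interface over the demixing machinery.

``DemixingModel`` is constructed from an observed stack and a codebook;
``fit()`` (or ``fit_accelerated()``) returns a ``DemixingResults`` carrying
the estimated parameters, the optimization trace and diagnostics, with
spot calling, cleaned-image quality scoring and plotting as methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import acceleration as _accel
from . import diagnostics as _diag
from . import inference as _inf
from . import spots as _spots
from .containers import Codebook, ImageStack, ModelParameters, PointSpreadFunction
from .core import forward_model

__all__ = ["DemixingModel", "DemixingResults"]


class DemixingModel:
    """Generative observation model of a barcoded image stack.

    Parameters
    ----------
    stack : ImageStack or ndarray, shape (R, C, *spatial)
        Registered, background-subtracted intensities.
    codebook : Codebook
        Binary barcode patterns; augment with unused barcodes (see
        ``augment_codebook``) if threshold calibration is wanted.
    psf : PointSpreadFunction or float
        Gaussian blur width in voxels.
    """

    def __init__(self, stack, codebook: Codebook, psf=1.0):
        self.stack = stack if isinstance(stack, ImageStack) else ImageStack(np.asarray(stack))
        self.codebook = codebook
        self.psf = psf if isinstance(psf, PointSpreadFunction) else PointSpreadFunction(sigma=psf)

    @classmethod
    def from_arrays(cls, data, B, gene_names=None, unused_mask=None, psf=1.0):
        B = np.asarray(B)
        names = gene_names or [f"gene_{j}" for j in range(B.shape[2])]
        return cls(ImageStack(np.asarray(data)), Codebook(B, names, unused_mask), psf)

    def fit(self, config: _inf.FitConfig | None = None, **kwargs) -> "DemixingResults":
        """Solve the constrained sparse non-negative regression."""
        if config is None and kwargs:
            config = _inf.FitConfig(**kwargs)
        res = _inf.fit(self.stack, self.codebook, self.psf, config)
        return DemixingResults(self, res)

    def fit_accelerated(
        self,
        config: _inf.FitConfig | None = None,
        patch_grid: _accel.PatchGrid | None = None,
        factor: int = 2,
        **kwargs,
    ) -> "DemixingResults":
        """Coarse-to-fine, barcode-sparsified, patch-parallel fit."""
        res = _accel.fit_accelerated(
            self.stack, self.codebook, self.psf, config,
            patch_grid=patch_grid, factor=factor, **kwargs,
        )
        return DemixingResults(self, res)


class DemixingResults:
    """Estimates, diagnostics and downstream calls from a fitted model."""

    def __init__(self, model: DemixingModel, fit_result: _inf.FitResult):
        self.model = model
        self.fit_result = fit_result

    # -- estimates ------------------------------------------------------
    @property
    def params(self) -> ModelParameters:
        return self.fit_result.params

    @property
    def density(self) -> np.ndarray:
        """Rolony density F, shape (M, J)."""
        return self.params.F

    def density_image(self, j: int) -> np.ndarray:
        return self.params.F[:, j].reshape(self.model.stack.spatial_shape)

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def omega(self) -> float:
        return self.fit_result.omega.omega

    @property
    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fit_result.trajectory,
            columns=["reconstruction_loss", "sparsity_loss"],
        )

    # -- reconstruction-level diagnostics -------------------------------
    def reconstruction(self) -> ImageStack:
        return forward_model(
            self.params, self.model.psf, self.model.codebook,
            self.model.stack.spatial_shape,
        )

    def percent_unexplained(self) -> float:
        return _diag.residual_summary(self.model.stack, self.reconstruction())

    def cleaned_image(self, j_star: int) -> _diag.CleanedImage:
        return _diag.cleaned_image(
            self.model.stack, self.params, self.model.psf,
            self.model.codebook, j_star,
        )

    # -- spot calling ---------------------------------------------------
    def threshold_from_unused(self, footprint_radius: int = 1) -> float:
        return _spots.select_threshold_from_unused(
            self.params.F, self.model.codebook,
            self.model.stack.spatial_shape, footprint_radius,
        )

    def call_spots(
        self, threshold: float | None = None, footprint_radius: int = 1
    ) -> pd.DataFrame:
        """Spot table; threshold defaults to the unused-barcode rule."""
        if threshold is None:
            threshold = self.threshold_from_unused(footprint_radius)
        return _spots.call_spots(
            self.params.F, self.model.codebook,
            self.model.stack.spatial_shape, threshold, footprint_radius,
        )

    def spot_qualities(
        self, spot_table: pd.DataFrame | None = None, window: int = 10
    ) -> list[_diag.SpotQuality]:
        """Rank-one SVD quality for each passing spot (clipped to the grid)."""
        if spot_table is None:
            spot_table = self.call_spots()
        shape = self.model.stack.spatial_shape
        coord_names = [c for c in ("z", "y", "x") if c in spot_table.columns]
        out = []
        cleaned_cache: dict[int, _diag.CleanedImage] = {}
        for _, row in spot_table[spot_table["passes_threshold"]].iterrows():
            j = int(row["barcode_index"])
            if j not in cleaned_cache:
                cleaned_cache[j] = self.cleaned_image(j)
            voxel = tuple(
                int(np.clip(row[c], window // 2, n - (window - window // 2)))
                for c, n in zip(coord_names, shape)
            )
            out.append(_diag.rank_one_diagnostic(cleaned_cache[j], voxel, window))
        return out

    def quality_histogram(self, qualities=None, n_bins: int = 20):
        if qualities is None:
            qualities = self.spot_qualities()
        return _diag.quality_histogram(qualities, n_bins)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        lrec = self.fit_result.reconstruction_loss
        lsp = self.fit_result.sparsity_loss
        p = self.params
        n_active = int(np.sum(p.F > 0))
        lines = [
            "Barcode demixing fit",
            "=" * 52,
            f"rounds x channels          {p.R} x {p.C}",
            f"voxels, barcodes           {p.M}, {p.J}",
            f"converged                  {self.converged}",
            f"outer iterations           {len(self.fit_result.trajectory)}",
            f"reconstruction loss        {lrec:.6g}",
            f"noise threshold (omega)    {self.omega:.6g}",
            f"sparsity penalty           {lsp:.6g}",
            f"nonzero density entries    {n_active}",
            f"alpha (normalized) range   [{p.alpha.min():.4f}, {p.alpha.max():.4f}]",
            f"phi off-diagonal max       {np.max(p.phi - np.diag(np.diag(p.phi))):.4f}"
            if p.C > 1 else "phi off-diagonal max       n/a",
            f"rho (phasing) max          {p.rho.max():.4f}",
        ]
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------
    def plot_quality_histogram(self, ax=None, qualities=None):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        counts, edges, _ = self.quality_histogram(qualities)
        if ax is None:
            _, ax = plt.subplots()
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
               edgecolor="white")
        ax.set_xlabel("spot quality $R^2$")
        ax.set_ylabel("number of spots")
        return ax

    def plot_density(self, j: int, ax=None, blurred: bool = False):
        import matplotlib.pyplot as plt

        img = self.density_image(j)
        if blurred:
            img = self.model.psf.apply(img)
        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(img, cmap="magma")
        ax.set_title(self.model.codebook.gene_names[j])
        return ax
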