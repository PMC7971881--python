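"""Synthetic data generation and detection-accuracy evaluation.

The generator places rolonies at random voxels, renders them through the
forward observation model (optionally deleting a rolony's signal in a few
rounds to emulate 'dropout'), and adds zero-truncated Gaussian noise.  A
hybrid mode injects synthetic rolonies into an existing background stack.
The evaluation harness matches called spots to ground truth by greedy
nearest-neighbor pairing and sweeps the detection threshold into ROC
curves, in two flavors: barcode-strict and detection-only ('total hit
rate', which forgives barcode mis-identification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    Codebook,
    ImageStack,
    ModelParameters,
    PointSpreadFunction,
    ValidationError,
)
from .core import forward_model, gain_tensor
from .spots import call_spots

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_codebook",
    "default_true_params",
    "simulate_truth",
    "render_stack",
    "inject_spots",
    "match_spots",
    "MatchResult",
    "roc_curve",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a modest single-plane experiment: 7 rounds, 4
    channels, a 100x100 field, 30 rolonies, a one-voxel Gaussian PSF and
    no dropout.  The noise s.d. is set so that noise accounts for a few
    percent of the stack's total variance, matching the signal-dominated
    character of registered, background-subtracted rolony data; per-peak
    signal-to-noise is then far above the detectability limit.
    """

    R: int = 7
    C: int = 4
    J: int = 10
    spatial_shape: tuple[int, ...] = (100, 100)
    n_spots: int = 30
    amplitude_low: float = 5.0
    amplitude_high: float = 10.0
    psf_sigma: float = 1.0
    noise_sd: float = 0.01
    dropout_fraction: float = 0.0
    dropout_rounds: int = 1
    seed: int = 0

    def __post_init__(self):
        self.spatial_shape = tuple(int(n) for n in self.spatial_shape)
        if self.amplitude_low <= 0 or self.amplitude_high < self.amplitude_low:
            raise ValidationError("need 0 < amplitude_low <= amplitude_high")
        if self.noise_sd < 0 or not 0 <= self.dropout_fraction <= 1:
            raise ValidationError("noise_sd >= 0 and dropout_fraction in [0, 1]")
        if not 0 < self.dropout_rounds < self.R:
            raise ValidationError("dropout_rounds must be in 1..R-1")

    @property
    def M(self) -> int:
        return int(np.prod(self.spatial_shape))

    @property
    def psf(self) -> PointSpreadFunction:
        return PointSpreadFunction(sigma=self.psf_sigma)


@dataclass
class SimTruth:
    """Ground-truth rolonies: voxel, barcode, amplitude, dropped rounds."""

    table: pd.DataFrame  # columns: voxel (tuple), barcode_index, amplitude, dropped_rounds
    spatial_shape: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.table)

    @property
    def coordinates(self) -> np.ndarray:
        if len(self.table) == 0:
            return np.zeros((0, len(self.spatial_shape)), dtype=int)
        return np.array([list(v) for v in self.table["voxel"]], dtype=int)


def default_codebook(config: SimConfig) -> Codebook:
    """A random one-hot-per-round, channel-balanced codebook.

    Within every round the J barcodes are spread over the C channels as
    evenly as possible (as real codebook designs do), so that when J >= C
    every (round, channel) frame receives signal from some barcode and the
    per-frame gain stays identifiable.
    """
    rng = np.random.default_rng(config.seed)
    R, C, J = config.R, config.C, config.J
    for _ in range(1000):
        cols = []
        for _ in range(R):
            pool = np.tile(np.arange(C), -(-J // C))[:J]
            rng.shuffle(pool)
            cols.append(pool)
        codes = np.stack(cols, axis=0)  # (R, J) active channel per round
        if len({tuple(codes[:, j]) for j in range(J)}) == J:
            break
    else:  # pragma: no cover - essentially impossible for J < C**R
        raise ValidationError("could not draw J distinct barcodes")
    B = np.zeros((R, C, J))
    for j in range(J):
        for r in range(R):
            B[r, codes[r, j], j] = 1.0
    return Codebook(B=B, gene_names=[f"gene_{k}" for k in range(J)])


def default_true_params(
    config: SimConfig, J: int | None = None
) -> ModelParameters:
    """Ground-truth nuisance parameters (F is filled in by the renderer).

    The per-round/per-channel gain ramps from 0.75 to 1.25 so that gain
    recovery is a meaningful check; background and offsets are small and
    constant; no cross-talk or phasing by default.
    """
    J = config.J if J is None else J
    R, C = config.R, config.C
    ramp = np.linspace(0.75, 1.25, R * C).reshape(R, C)
    return ModelParameters(
        F=np.zeros((config.M, J)),
        a=np.full(config.M, 0.05),
        b=np.full((R, C), 0.02),
        alpha=ramp,
        phi=np.eye(C),
        rho=np.zeros(C),
    )


def simulate_truth(config: SimConfig, codebook: Codebook) -> SimTruth:
    """Draw ground-truth rolonies.

    Voxels are distinct and uniform; barcodes are drawn from a uniform
    per-gene frequency vector over the used (non-unused) barcodes;
    amplitudes are uniform on [amplitude_low, amplitude_high].  Exactly
    ``round(dropout_fraction * n_spots)`` rolonies receive
    ``dropout_rounds`` distinct dropped rounds.
    """
    if config.n_spots > config.M:
        raise ValidationError("n_spots exceeds the number of voxels")
    rng = np.random.default_rng(config.seed)
    flat = rng.choice(config.M, size=config.n_spots, replace=False)
    coords = [tuple(int(x) for x in np.unravel_index(f, config.spatial_shape))
              for f in flat]
    used = codebook.used_indices
    barcodes = rng.choice(used, size=config.n_spots, replace=True)
    amplitudes = rng.uniform(
        config.amplitude_low, config.amplitude_high, size=config.n_spots
    )
    n_drop = int(round(config.dropout_fraction * config.n_spots))
    drop_idx = set(
        rng.choice(config.n_spots, size=n_drop, replace=False).tolist()
        if n_drop
        else []
    )
    dropped = [
        tuple(sorted(rng.choice(config.R, size=config.dropout_rounds,
                                replace=False).tolist()))
        if i in drop_idx
        else ()
        for i in range(config.n_spots)
    ]
    table = pd.DataFrame(
        {
            "voxel": coords,
            "barcode_index": barcodes.astype(int),
            "amplitude": amplitudes,
            "dropped_rounds": dropped,
        }
    )
    return SimTruth(table=table, spatial_shape=config.spatial_shape)


def _density_from_truth(truth: SimTruth, J: int) -> np.ndarray:
    M = int(np.prod(truth.spatial_shape))
    F = np.zeros((M, J))
    for _, row in truth.table.iterrows():
        m = int(np.ravel_multi_index(row["voxel"], truth.spatial_shape))
        F[m, row["barcode_index"]] += row["amplitude"]
    return F


def render_stack(
    truth: SimTruth,
    codebook: Codebook,
    params_true: ModelParameters,
    psf: PointSpreadFunction,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImageStack:
    """Render a stack from ground truth through the forward model.

    Each dropped (rolony, round) has that rolony's contribution removed in
    that round only.  Gaussian noise of the given s.d. is added and the
    result truncated at zero to respect the non-negative data contract.
    """
    params = params_true.copy()
    params.F = _density_from_truth(truth, codebook.J)
    stack = forward_model(params, psf, codebook, truth.spatial_shape)
    data = stack.data.copy()
    G = gain_tensor(params, codebook)
    for _, row in truth.table.iterrows():
        if not row["dropped_rounds"]:
            continue
        j = int(row["barcode_index"])
        m = np.ravel_multi_index(row["voxel"], truth.spatial_shape)
        single = np.zeros((params.M, 1))
        single[m, 0] = row["amplitude"]
        blob = psf.apply_to_density(single, truth.spatial_shape)[:, 0]
        for r in row["dropped_rounds"]:
            for c in range(codebook.C):
                data[r, c] -= (blob * G[r, c, j]).reshape(truth.spatial_shape)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return ImageStack(np.maximum(data, 0.0))


def inject_spots(
    background: ImageStack,
    codebook: Codebook,
    psf: PointSpreadFunction,
    n_inject: int,
    scale_intensity: float = 1.0,
    seed: int = 0,
    dropout_fraction: float = 0.0,
    dropout_rounds: int = 1,
) -> tuple[ImageStack, SimTruth]:
    """Hybrid simulation: add synthetic rolonies onto a real background.

    Injected rolonies land at uniformly random voxels with their *peak
    rendered intensity* equal to ``scale_intensity`` times the background
    maximum, and carry uniformly random used barcodes.  A
    ``dropout_fraction`` subset of the injected rolonies can additionally
    lose ``dropout_rounds`` rounds of signal.
    """
    if not 0 < scale_intensity <= 1:
        raise ValidationError("scale_intensity must lie in (0, 1]")
    ref = float(background.data.max())
    if ref <= 0:
        raise ValidationError(
            "background maximum is zero; provide a stack with positive "
            "reference intensity before injecting"
        )
    rng = np.random.default_rng(seed)
    M = background.M
    flat = rng.choice(M, size=n_inject, replace=False) if n_inject else np.array([], int)
    coords = [tuple(int(x) for x in np.unravel_index(f, background.spatial_shape))
              for f in flat]
    used = codebook.used_indices
    barcodes = (rng.choice(used, size=n_inject, replace=True)
                if n_inject else np.array([], int))

    # unit gains for injection rendering
    params = ModelParameters(
        F=np.zeros((M, codebook.J)),
        a=np.zeros(M),
        b=np.zeros((codebook.R, codebook.C)),
        alpha=np.ones((codebook.R, codebook.C)),
        phi=np.eye(codebook.C),
        rho=np.zeros(codebook.C),
    )
    G = gain_tensor(params, codebook)
    mid = tuple(n // 2 for n in background.spatial_shape)
    unit = np.zeros((M, 1))
    unit[np.ravel_multi_index(mid, background.spatial_shape), 0] = 1.0
    kmax = float(psf.apply_to_density(unit, background.spatial_shape).max())
    amplitudes = np.array(
        [scale_intensity * ref / (kmax * G[:, :, j].max()) for j in barcodes]
    )
    n_drop = int(round(dropout_fraction * n_inject))
    drop_idx = set(
        rng.choice(n_inject, size=n_drop, replace=False).tolist() if n_drop else []
    )
    dropped = [
        tuple(sorted(rng.choice(codebook.R, size=dropout_rounds,
                                replace=False).tolist()))
        if i in drop_idx
        else ()
        for i in range(n_inject)
    ]
    table = pd.DataFrame(
        {
            "voxel": coords,
            "barcode_index": np.asarray(barcodes, dtype=int),
            "amplitude": amplitudes,
            "dropped_rounds": dropped,
        }
    )
    truth = SimTruth(table=table, spatial_shape=background.spatial_shape)
    extra = render_stack(truth, codebook, params, psf, noise_sd=0.0)
    return ImageStack(background.data + extra.data), truth


@dataclass
class MatchResult:
    """Greedy nearest-neighbor pairing of called spots to ground truth."""

    pairs: pd.DataFrame  # call_index, truth_index, distance, barcode_correct
    unmatched_calls: list[int]
    unmatched_truth: list[int]
    n_calls: int
    n_truth: int

    @property
    def detection_rate(self) -> float:
        """Fraction of truths matched by any call (total hit rate)."""
        return len(self.pairs) / self.n_truth if self.n_truth else np.nan

    @property
    def correct_rate(self) -> float:
        """Fraction of truths matched with the correct barcode (1 - FNR)."""
        if not self.n_truth:
            return np.nan
        return int(self.pairs["barcode_correct"].sum()) / self.n_truth

    @property
    def fpr(self) -> float:
        """Unmatched calls over total calls."""
        return len(self.unmatched_calls) / self.n_calls if self.n_calls else 0.0


def match_spots(
    called: pd.DataFrame, truth: SimTruth, radius: float = 2.0
) -> MatchResult:
    """Match called spots to true rolonies within a Euclidean radius.

    Candidate pairs are sorted by distance (ties broken by truth then call
    index) and accepted greedily, each spot and truth used at most once.
    A pair is a *detection* regardless of barcode agreement and *correct*
    when the barcodes also agree.
    """
    coord_names = [c for c in ("z", "y", "x") if c in called.columns]
    call_xy = called[coord_names].to_numpy(dtype=float) if len(called) else \
        np.zeros((0, len(truth.spatial_shape)))
    truth_xy = truth.coordinates.astype(float)
    cand = []
    for ti in range(len(truth_xy)):
        d = np.linalg.norm(call_xy - truth_xy[ti], axis=1) if len(call_xy) else []
        for ci, dist in enumerate(d):
            if dist <= radius:
                cand.append((float(dist), ti, ci))
    cand.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    rows = []
    truth_barcodes = truth.table["barcode_index"].to_numpy() if len(truth.table) \
        else np.array([], int)
    call_barcodes = called["barcode_index"].to_numpy() if len(called) else \
        np.array([], int)
    for dist, ti, ci in cand:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        rows.append(
            {
                "call_index": ci,
                "truth_index": ti,
                "distance": dist,
                "barcode_correct": bool(call_barcodes[ci] == truth_barcodes[ti]),
            }
        )
    pairs = pd.DataFrame(
        rows, columns=["call_index", "truth_index", "distance", "barcode_correct"]
    )
    return MatchResult(
        pairs=pairs,
        unmatched_calls=sorted(set(range(len(called))) - used_c),
        unmatched_truth=sorted(set(range(len(truth_xy))) - used_t),
        n_calls=len(called),
        n_truth=len(truth_xy),
    )


def roc_curve(
    F: np.ndarray,
    codebook: Codebook,
    truth: SimTruth,
    radius: float = 2.0,
    thresholds: np.ndarray | None = None,
    footprint_radius: int = 1,
):
    """Sweep the spot-calling threshold into an ROC curve.

    At each threshold, spots are the passing local maxima of the
    per-barcode density images; 1-FNR is matched-correct / |truth| (strict)
    or matched / |truth| (detection-only), FPR is unmatched calls over
    total calls.  AUROC integrates the strict curve by the trapezoid rule
    over FPR, extending the best operating point horizontally to FPR = 1.
    """
    if len(truth) == 0:
        raise ValidationError("ROC evaluation needs a non-empty ground truth")
    spots = call_spots(F, codebook, truth.spatial_shape,
                       threshold=0.0, footprint_radius=footprint_radius)
    if thresholds is None:
        vals = np.sort(spots["density"].to_numpy())
        lo = 0.0
        hi = float(vals.max()) if len(vals) else 1.0
        thresholds = np.unique(np.concatenate([[lo], vals, [hi]]))
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValidationError("thresholds must be sorted ascending")

    points = []
    for thr in thresholds:
        passing = spots[spots["density"] > thr]
        m = match_spots(passing, truth, radius)
        points.append(
            {
                "threshold": float(thr),
                "fpr": m.fpr,
                "tpr_strict": m.correct_rate,
                "tpr_detection": m.detection_rate,
            }
        )
    curve = pd.DataFrame(points)
    auroc = _auroc(curve["fpr"].to_numpy(), curve["tpr_strict"].to_numpy())
    return curve, auroc


def _auroc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    order = np.argsort(fpr, kind="stable")
    x, y = fpr[order], tpr[order]
    # keep, per FPR, the best achievable rate; extend to the [0, 1] span
    xs, ys = [0.0], [y[x == x.min()].max() if len(x) else 0.0]
    for xi, yi in zip(x, y):
        if xi > xs[-1]:
            xs.append(xi)
            ys.append(yi)
        else:
            ys[-1] = max(ys[-1], yi)
    if xs[-1] < 1.0:
        xs.append(1.0)
        ys.append(ys[-1])
    return float(np.trapezoid(ys, xs))
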