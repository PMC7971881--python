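"""Synthetic generator and the spot-matching / ROC evaluation harness."""

import numpy as np
import pandas as pd
import pytest

from rolodemix import (
    ImageStack,
    ModelParameters,
    PointSpreadFunction,
    SimConfig,
    SimTruth,
    ValidationError,
    default_codebook,
    default_true_params,
    forward_model,
    inject_spots,
    match_spots,
    render_stack,
    roc_curve,
    simulate_truth,
)


@pytest.fixture
def sim(rng):
    cfg = SimConfig(R=4, C=3, J=6, spatial_shape=(15, 15), n_spots=8, seed=21)
    return cfg, default_codebook(cfg)


class TestSimulateTruth:
    def test_empty_truth(self, sim):
        cfg, cb = sim
        cfg2 = SimConfig(**{**cfg.__dict__, "n_spots": 0})
        truth = simulate_truth(cfg2, cb)
        assert len(truth) == 0

    def test_deterministic_under_seed(self, sim):
        cfg, cb = sim
        t1 = simulate_truth(cfg, cb)
        t2 = simulate_truth(cfg, cb)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_voxels_distinct_and_in_grid(self, sim):
        cfg, cb = sim
        truth = simulate_truth(cfg, cb)
        coords = truth.coordinates
        assert len({tuple(c) for c in coords}) == len(coords)
        assert (coords >= 0).all()
        assert (coords < np.array(cfg.spatial_shape)).all()

    def test_dropout_count_is_exact(self):
        cfg = SimConfig(R=5, C=3, J=4, spatial_shape=(30, 30), n_spots=200,
                        dropout_fraction=0.5, dropout_rounds=1, seed=2)
        cb = default_codebook(cfg)
        truth = simulate_truth(cfg, cb)
        n_dropped = sum(1 for d in truth.table["dropped_rounds"] if d)
        assert n_dropped == 100

    def test_too_many_spots_rejected(self):
        cfg = SimConfig(R=4, C=3, J=4, spatial_shape=(3, 3), n_spots=5)
        cb = default_codebook(cfg)
        cfg.n_spots = 10
        with pytest.raises(ValidationError):
            simulate_truth(cfg, cb)

    def test_unused_barcodes_never_drawn(self, sim):
        from rolodemix import augment_codebook

        cfg, cb = sim
        aug = augment_codebook(cb, n_unused=2, min_round_diff=2, seed=1)
        truth = simulate_truth(cfg, aug)
        assert not aug.unused_mask[truth.table["barcode_index"]].any()


class TestRenderStack:
    def test_noiseless_no_dropout_equals_forward_model(self, sim):
        cfg, cb = sim
        truth = simulate_truth(cfg, cb)
        pt = default_true_params(cfg)
        X = render_stack(truth, cb, pt, cfg.psf, noise_sd=0.0)
        params = pt.copy()
        F = np.zeros((cfg.M, cfg.J))
        for _, row in truth.table.iterrows():
            F[np.ravel_multi_index(row["voxel"], cfg.spatial_shape),
              row["barcode_index"]] += row["amplitude"]
        params.F = F
        expected = forward_model(params, cfg.psf, cb, cfg.spatial_shape)
        np.testing.assert_allclose(X.data, expected.data, atol=1e-12)

    def test_dropped_round_removes_only_that_contribution(self, sim):
        cfg, cb = sim
        table = pd.DataFrame({
            "voxel": [(7, 7)],
            "barcode_index": [0],
            "amplitude": [5.0],
            "dropped_rounds": [(2,)],
        })
        truth = SimTruth(table=table, spatial_shape=cfg.spatial_shape)
        pt = default_true_params(cfg)
        X_drop = render_stack(truth, cb, pt, cfg.psf, noise_sd=0.0)
        table_nd = table.copy()
        table_nd["dropped_rounds"] = [()]
        X_full = render_stack(
            SimTruth(table=table_nd, spatial_shape=cfg.spatial_shape),
            cb, pt, cfg.psf, noise_sd=0.0,
        )
        background = pt.a.reshape(cfg.spatial_shape)[None, :] + 0  # a only
        # dropped round contains background only
        np.testing.assert_allclose(
            X_drop.data[2],
            (pt.a[None, :] + pt.b[2][:, None]).reshape(cfg.C, *cfg.spatial_shape),
            atol=1e-12,
        )
        # all other rounds identical to the no-dropout render
        for r in range(cfg.R):
            if r != 2:
                np.testing.assert_allclose(X_drop.data[r], X_full.data[r], atol=1e-12)

    def test_empty_truth_gives_background_plus_noise(self, sim):
        cfg, cb = sim
        truth = SimTruth(
            table=pd.DataFrame(
                {"voxel": [], "barcode_index": [], "amplitude": [],
                 "dropped_rounds": []}
            ),
            spatial_shape=cfg.spatial_shape,
        )
        pt = default_true_params(cfg)
        X = render_stack(truth, cb, pt, cfg.psf, noise_sd=0.0)
        expected = pt.a[None, None, :] + pt.b[:, :, None]
        np.testing.assert_allclose(X.flat, expected, atol=1e-12)

    def test_noise_reproducible_and_nonnegative(self, sim):
        cfg, cb = sim
        truth = simulate_truth(cfg, cb)
        pt = default_true_params(cfg)
        X1 = render_stack(truth, cb, pt, cfg.psf, noise_sd=0.5, seed=3)
        X2 = render_stack(truth, cb, pt, cfg.psf, noise_sd=0.5, seed=3)
        np.testing.assert_array_equal(X1.data, X2.data)
        assert (X1.data >= 0).all()


class TestInjectSpots:
    def test_zero_injection_leaves_background(self, sim, rng):
        cfg, cb = sim
        bg = ImageStack(rng.random((cfg.R, cfg.C, 15, 15)))
        out, truth = inject_spots(bg, cb, cfg.psf, n_inject=0)
        np.testing.assert_array_equal(out.data, bg.data)
        assert len(truth) == 0

    def test_injection_only_adds_signal(self, sim, rng):
        cfg, cb = sim
        bg = ImageStack(rng.random((cfg.R, cfg.C, 15, 15)))
        out, truth = inject_spots(bg, cb, cfg.psf, n_inject=5, seed=2)
        assert len(truth) == 5
        assert np.all(out.data >= bg.data - 1e-12)

    def test_peak_amplitude_scales_with_background_max(self, sim):
        cfg, cb = sim
        bg = ImageStack(np.full((cfg.R, cfg.C, 15, 15), 2.0))
        out, truth = inject_spots(bg, cb, cfg.psf, n_inject=1,
                                  scale_intensity=0.5, seed=0)
        added = out.data - bg.data
        assert added.max() == pytest.approx(1.0, rel=1e-6)

    def test_zero_background_rejected(self, sim):
        cfg, cb = sim
        bg = ImageStack(np.zeros((cfg.R, cfg.C, 15, 15)))
        with pytest.raises(ValidationError, match="reference intensity"):
            inject_spots(bg, cb, cfg.psf, n_inject=1)


def spot_table(entries):
    rows = [
        {"gene": f"g{j}", "barcode_index": j, "y": y, "x": x,
         "density": 1.0, "passes_threshold": True}
        for j, y, x in entries
    ]
    return pd.DataFrame(
        rows, columns=["gene", "barcode_index", "y", "x", "density",
                       "passes_threshold"],
    )


def truth_table(entries, shape=(10, 10)):
    return SimTruth(
        table=pd.DataFrame({
            "voxel": [(y, x) for _, y, x in entries],
            "barcode_index": [j for j, _, _ in entries],
            "amplitude": [1.0] * len(entries),
            "dropped_rounds": [()] * len(entries),
        }),
        spatial_shape=shape,
    )


class TestMatchSpots:
    def test_identical_sets_match_perfectly(self):
        entries = [(0, 2, 2), (1, 5, 5), (2, 8, 1)]
        m = match_spots(spot_table(entries), truth_table(entries), radius=2.0)
        assert m.correct_rate == 1.0
        assert m.detection_rate == 1.0
        assert m.fpr == 0.0

    def test_empty_calls_detect_nothing(self):
        m = match_spots(spot_table([]), truth_table([(0, 1, 1)]), radius=2.0)
        assert m.correct_rate == 0.0
        assert m.detection_rate == 0.0

    def test_barcode_swap_counts_as_detection_not_correct(self):
        # 3 truths / 3 calls, one barcode swapped: every rolony is found but
        # only one third carries the right label... here 2 correct, 1 swap
        truths = [(0, 2, 2), (1, 5, 5), (2, 8, 8)]
        calls = [(0, 2, 2), (2, 5, 5), (1, 8, 8)]  # two swapped labels
        m = match_spots(spot_table(calls), truth_table(truths), radius=1.0)
        assert m.detection_rate == 1.0
        assert m.correct_rate == pytest.approx(1 / 3)
        # brute-force oracle: best assignment within radius
        assert len(m.pairs) == 3

    def test_each_spot_used_once(self):
        truths = [(0, 5, 5)]
        calls = [(0, 5, 5), (0, 5, 6)]
        m = match_spots(spot_table(calls), truth_table(truths), radius=2.0)
        assert len(m.pairs) == 1
        assert m.pairs.iloc[0]["call_index"] == 0  # nearest wins
        assert m.unmatched_calls == [1]


class TestRocCurve:
    def perfect_F(self, truth, J, shape):
        F = np.zeros((int(np.prod(shape)), J))
        for _, row in truth.table.iterrows():
            F[np.ravel_multi_index(row["voxel"], shape), row["barcode_index"]] = 1.0
        return F

    def test_perfect_density_reaches_corner(self, sim):
        cfg, cb = sim
        truth = simulate_truth(cfg, cb)
        F = self.perfect_F(truth, cb.J, cfg.spatial_shape)
        curve, auroc = roc_curve(F, cb, truth, radius=1.0)
        assert auroc == pytest.approx(1.0)
        best = curve[(curve.fpr == 0)]["tpr_strict"].max()
        assert best == 1.0

    def test_detection_rate_dominates_strict_rate(self, sim, rng):
        cfg, cb = sim
        truth = simulate_truth(cfg, cb)
        F = rng.random((cfg.M, cb.J)) ** 6
        curve, _ = roc_curve(F, cb, truth, radius=2.0)
        assert (curve.tpr_detection >= curve.tpr_strict - 1e-12).all()

    def test_pure_noise_density_scores_near_chance(self):
        # with random density and many barcodes, the barcode-strict curve
        # carries little signal: mean AUROC over seeds stays far below the
        # performance of a real fit
        cfg = SimConfig(R=4, C=3, J=8, spatial_shape=(12, 12), n_spots=6, seed=0)
        cb = default_codebook(cfg)
        aurocs = []
        for seed in range(100):
            g = np.random.default_rng(seed)
            truth = simulate_truth(
                SimConfig(**{**cfg.__dict__, "seed": seed}), cb
            )
            F = g.random((cfg.M, cb.J)) ** 4
            _, a = roc_curve(F, cb, truth, radius=2.0)
            aurocs.append(a)
        assert np.mean(aurocs) < 0.6

    def test_empty_truth_rejected(self, sim):
        cfg, cb = sim
        truth = truth_table([], shape=cfg.spatial_shape)
        with pytest.raises(ValidationError):
            roc_curve(np.zeros((cfg.M, cb.J)), cb, truth)

    def test_unsorted_thresholds_rejected(self, sim):
        cfg, cb = sim
        truth = simulate_truth(cfg, cb)
        F = self.perfect_F(truth, cb.J, cfg.spatial_shape)
        with pytest.raises(ValidationError):
            roc_curve(F, cb, truth, thresholds=np.array([0.5, 0.1]))
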