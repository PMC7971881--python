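"""Inference: noise threshold, normalization, step sizes, small fits."""

import numpy as np
import pytest

from rolodemix import (
    Codebook,
    FitConfig,
    ImageStack,
    ModelParameters,
    PointSpreadFunction,
    ValidationError,
    estimate_step_sizes,
    fit,
    forward_model,
    normalize_scale,
    select_noise_threshold,
)

from conftest import random_codebook, random_params


class TestNoiseThreshold:
    def test_constant_stack_gives_zero(self):
        X = ImageStack(np.full((2, 2, 5, 5), 3.0))
        assert select_noise_threshold(X).omega == 0.0

    def test_full_fraction_equals_centered_tss(self, rng):
        X = ImageStack(rng.random((3, 2, 4, 4)))
        cfg = FitConfig(unexplained_fraction_target=0.999999)
        flat = X.flat
        tss = ((flat - flat.mean(axis=2, keepdims=True)) ** 2).sum()
        assert select_noise_threshold(X, config=cfg).omega == pytest.approx(
            0.999999 * tss, rel=1e-9
        )

    def test_matches_direct_computation(self, rng):
        X = ImageStack(rng.random((2, 3, 5, 5)))
        expected = 0.0
        for r in range(2):
            for c in range(3):
                frame = X.data[r, c].ravel()
                expected += ((frame - frame.mean()) ** 2).sum()
        assert select_noise_threshold(X).omega == pytest.approx(
            0.1 * expected, rel=1e-12
        )


class TestNormalizeScale:
    def test_idempotent(self, rng):
        p = random_params(rng, M=10, J=2, R=3, C=2)
        once = normalize_scale(p)
        twice = normalize_scale(once)
        for name in ("F", "a", "b", "alpha", "phi", "rho"):
            np.testing.assert_allclose(
                getattr(twice, name), getattr(once, name), rtol=1e-12, atol=1e-15
            )
        assert once.alpha.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(once.phi), 1.0)

    def test_rescaled_models_map_to_same_canonical_point(self, rng):
        # the unobservable (4F, alpha/2, phi/2) transformation
        p = random_params(rng, M=10, J=2, R=3, C=2)
        q = p.copy()
        q.F = p.F * 4
        q.alpha = p.alpha / 2
        q.phi = p.phi / 2
        np_, nq = normalize_scale(p), normalize_scale(q)
        for name in ("F", "alpha", "phi"):
            np.testing.assert_allclose(
                getattr(np_, name), getattr(nq, name), rtol=1e-9
            )

    def test_forward_model_unchanged(self, rng):
        cb = random_codebook(rng, R=3, C=2, J=2)
        p = random_params(rng, M=16, J=2, R=3, C=2)
        psf = PointSpreadFunction(0.8)
        before = forward_model(p, psf, cb, (4, 4)).data
        after = forward_model(normalize_scale(p), psf, cb, (4, 4)).data
        np.testing.assert_allclose(after, before, rtol=1e-9)

    def test_zero_diagonal_rejected(self, rng):
        p = random_params(rng, M=4, J=1, R=2, C=2)
        p.phi[0, 0] = 0.0
        with pytest.raises(ValidationError):
            normalize_scale(p)


class TestStepSizes:
    def test_single_indicator_matches_analytic_lipschitz(self):
        # one barcode active in a single (r, c), unit alpha, identity PSF:
        # the F operator is an indicator, so L = 2 * sigma_max^2 = 2
        B = np.zeros((2, 2, 1))
        B[0, 0, 0] = 1.0
        cb = Codebook(B, ["g"])
        X = ImageStack(np.ones((2, 2, 3, 3)))
        steps = estimate_step_sizes(X, cb, PointSpreadFunction(0.0), n_iter=100)
        assert 1.0 / steps["F"] == pytest.approx(2.0, rel=0.05)

    def test_steps_invariant_to_data_scaling(self, rng):
        cb = random_codebook(rng, R=3, C=2, J=2)
        X = ImageStack(rng.random((3, 2, 4, 4)))
        X10 = ImageStack(X.data * 10)
        psf = PointSpreadFunction(0.7)
        s1 = estimate_step_sizes(X, cb, psf)
        s2 = estimate_step_sizes(X10, cb, psf)
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], rel=1e-9)

    def test_power_iteration_reaches_dense_svd_value(self, rng):
        # identity PSF makes the F operator dense-representable:
        # A[(r,c),(j)] per voxel is block diagonal; compare on one voxel
        cb = random_codebook(rng, R=3, C=2, J=3)
        params = ModelParameters(
            F=np.ones((4, 3)), a=np.zeros(4), b=np.zeros((3, 2)),
            alpha=0.5 + rng.random((3, 2)), phi=np.eye(2), rho=np.zeros(2),
        )
        X = ImageStack(rng.random((3, 2, 2, 2)))
        steps = estimate_step_sizes(
            X, cb, PointSpreadFunction(0.0), params=params, n_iter=300
        )
        from rolodemix.core import gain_tensor

        G = gain_tensor(params, cb).reshape(6, 3)
        smax2 = np.linalg.svd(G, compute_uv=False)[0] ** 2
        est = 1.0 / (2.0 * steps["F"]) / 1.001  # undo the safety inflation
        assert est >= smax2 - 1e-6
        assert est == pytest.approx(smax2, rel=1e-6)

    def test_all_zero_codebook_rejected(self, rng):
        B = np.ones((2, 2, 1))
        cb = Codebook(B, ["g"])
        cb.B = np.zeros_like(cb.B)  # bypass constructor check deliberately
        X = ImageStack(np.ones((2, 2, 3, 3)))
        with pytest.raises(ValidationError):
            estimate_step_sizes(X, cb, PointSpreadFunction(0.0))


class TestFitSmall:
    def test_all_zero_stack_returns_zero_signal(self, rng):
        cb = random_codebook(rng, R=3, C=2, J=2)
        X = ImageStack(np.zeros((3, 2, 5, 5)))
        with pytest.warns(UserWarning, match="all-zero"):
            res = fit(X, cb, PointSpreadFunction(0.0))
        assert np.all(res.params.F == 0)
        assert np.all(res.params.a == 0)
        assert np.all(res.params.b == 0)

    def test_nan_stack_rejected(self, rng):
        cb = random_codebook(rng, R=2, C=2, J=1)
        data = np.ones((2, 2, 3, 3))
        X = ImageStack(data)
        X.data[0, 0, 0, 0] = np.nan  # after construction, to test fit's guard
        with pytest.raises(ValidationError):
            fit(X, cb, PointSpreadFunction(0.0))

    def test_single_rolony_noiseless_recovery(self):
        # render one rolony through the exact model and invert
        R, C, J = 4, 3, 3
        rng = np.random.default_rng(7)
        B = np.zeros((R, C, J))
        for j in range(J):
            for r in range(R):
                B[r, (j + r) % C, j] = 1.0
        cb = Codebook(B, [f"g{j}" for j in range(J)])
        shape = (12, 12)
        true = ModelParameters(
            F=np.zeros((144, J)), a=np.zeros(144), b=np.zeros((R, C)),
            alpha=np.ones((R, C)), phi=np.eye(C), rho=np.zeros(C),
        )
        m0, j0 = 5 * 12 + 7, 1
        true.F[m0, j0] = 2.0
        X = forward_model(true, PointSpreadFunction(0.0), cb, shape)
        res = fit(X, cb, PointSpreadFunction(0.0), FitConfig(max_iters=60))
        F = res.params.F
        assert F.max() > 0
        assert np.unravel_index(F.argmax(), F.shape) == (m0, j0)
        off_support = F.sum() - F[m0, j0]
        assert off_support / F[m0, j0] < 0.05

    def test_two_overlapping_rolonies_demixed(self):
        # two different barcodes within one PSF width, moderate noise
        R, C, J = 5, 3, 4
        rng = np.random.default_rng(11)
        B = np.zeros((R, C, J))
        for j in range(J):
            for r in range(R):
                B[r, (j * 2 + r) % C, j] = 1.0
        cb = Codebook(B, [f"g{j}" for j in range(J)])
        shape = (14, 14)
        M = 196
        true = ModelParameters(
            F=np.zeros((M, J)), a=np.zeros(M), b=np.zeros((R, C)),
            alpha=np.ones((R, C)), phi=np.eye(C), rho=np.zeros(C),
        )
        psf = PointSpreadFunction(1.0)
        pos = [(7, 7, 0), (7, 8, 2)]  # one voxel apart, barcodes 0 and 2
        for y, x, j in pos:
            true.F[y * 14 + x, j] = 5.0
        clean = forward_model(true, psf, cb, shape)
        noisy = ImageStack(
            np.maximum(clean.data + rng.normal(0, 0.01, clean.data.shape), 0)
        )
        res = fit(noisy, cb, psf, FitConfig(max_iters=80))
        F = res.params.F
        top2 = np.argsort(F.ravel())[::-1][:2]
        found = set()
        for idx in top2:
            m, j = divmod(int(idx), J)
            y, x = divmod(m, 14)
            for ty, tx, tj in pos:
                if tj == j and abs(ty - y) <= 1 and abs(tx - x) <= 1:
                    found.add((ty, tx, tj))
        assert found == set(pos)


class TestFitContract:
    def test_penalized_objective_monotone_and_params_nonnegative(self, rng):
        from rolodemix.inference import _Problem, _default_init, _fit_penalized

        cb = random_codebook(rng, R=3, C=2, J=3)
        true = random_params(rng, M=64, J=3, R=3, C=2)
        true.F = np.zeros((64, 3))
        for _ in range(4):
            true.F[rng.integers(64), rng.integers(3)] = 3.0
        psf = PointSpreadFunction(0.8)
        clean = forward_model(true, psf, cb, (8, 8))
        X = ImageStack(np.maximum(
            clean.data + rng.normal(0, 0.01, clean.data.shape), 0
        ))
        prob = _Problem(X, cb, psf)
        p, traj, conv = _fit_penalized(
            prob, 0.05, _default_init(prob), FitConfig(max_iters=40)
        )
        objs = [lr + 0.05 * ls for lr, ls in traj]
        for before, after in zip(objs, objs[1:]):
            assert after <= before * (1 + 1e-9) + 1e-12 * objs[0]
        for name in ("F", "a", "b", "alpha"):
            assert np.all(getattr(p, name) >= 0)
        assert np.all((p.phi >= 0) & (p.phi <= 1))
        assert np.all((p.rho >= 0) & (p.rho <= 1))

    def test_constraint_met_on_convergence(self, rng):
        cb = random_codebook(rng, R=3, C=2, J=2)
        true = random_params(rng, M=100, J=2, R=3, C=2)
        true.F = np.zeros((100, 2))
        true.F[33, 0] = 4.0
        true.F[66, 1] = 5.0
        true.rho = np.zeros(2)
        true.phi = np.eye(2)
        psf = PointSpreadFunction(1.0)
        clean = forward_model(true, psf, cb, (10, 10))
        X = ImageStack(np.maximum(
            clean.data + rng.normal(0, 0.005, clean.data.shape), 0
        ))
        res = fit(X, cb, psf)
        if res.converged:
            assert res.reconstruction_loss <= res.omega.omega * (1 + 1e-6)
        assert res.converged

    def test_fit_canonical_under_data_rescaling(self, rng):
        # multiplying X by c rescales omega by c^2 and F by c, but leaves
        # the normalized alpha/phi and the spot geometry unchanged
        cb = random_codebook(rng, R=4, C=2, J=2)
        true = random_params(rng, M=100, J=2, R=4, C=2)
        true.F = np.zeros((100, 2))
        true.F[22, 0] = 4.0
        true.F[77, 1] = 5.0
        psf = PointSpreadFunction(1.0)
        clean = forward_model(true, psf, cb, (10, 10))
        X = ImageStack(np.maximum(
            clean.data + rng.normal(0, 0.005, clean.data.shape), 0
        ))
        c = 3.7
        res1 = fit(X, cb, psf, FitConfig(max_iters=60))
        res2 = fit(ImageStack(c * X.data), cb, psf, FitConfig(max_iters=60))
        assert res2.omega.omega == pytest.approx(c**2 * res1.omega.omega, rel=1e-9)
        assert np.argmax(res2.params.F) == np.argmax(res1.params.F)
        np.testing.assert_allclose(
            res2.params.alpha, res1.params.alpha, atol=0.02
        )
        np.testing.assert_allclose(
            res2.params.F.max(), c * res1.params.F.max(), rtol=0.05
        )
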