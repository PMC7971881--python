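import numpy as np
import pytest

from rolodemix import Codebook, ImageStack, ModelParameters, PointSpreadFunction


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_codebook(rng, R=3, C=2, J=2, one_hot=True):
    """Small random codebook; one-hot per round unless asked otherwise."""
    B = np.zeros((R, C, J))
    for j in range(J):
        if one_hot:
            for r in range(R):
                B[r, rng.integers(C), j] = 1.0
        else:
            while not B[:, :, j].any():
                B[:, :, j] = (rng.random((R, C)) < 0.4).astype(float)
    return Codebook(B=B, gene_names=[f"g{j}" for j in range(J)])


def random_params(rng, M, J, R, C):
    return ModelParameters(
        F=rng.random((M, J)),
        a=rng.random(M) * 0.1,
        b=rng.random((R, C)) * 0.1,
        alpha=0.5 + rng.random((R, C)),
        phi=np.eye(C) + 0.2 * rng.random((C, C)) * (1 - np.eye(C)),
        rho=rng.random(C) * 0.5,
    )


@pytest.fixture
def small_instance(rng):
    """4x4 grid, R=3, C=2, J=2 — small enough for brute-force oracles."""
    codebook = random_codebook(rng, R=3, C=2, J=2)
    params = random_params(rng, M=16, J=2, R=3, C=2)
    psf = PointSpreadFunction(sigma=0.0)
    return codebook, params, psf, (4, 4)
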