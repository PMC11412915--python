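import numpy as np
import pytest

from ans_scmc import AssociationMatrix, SyntheticSpec, generate


@pytest.fixture
def tiny_A() -> AssociationMatrix:
    """3 microbes x 2 diseases; the hand-computable instance used throughout."""
    return AssociationMatrix(
        np.array([[1, 0], [0, 1], [1, 1]]), ("m1", "m2", "m3"), ("d1", "d2")
    )


@pytest.fixture(scope="session")
def planted():
    """Default planted benchmark instance (60 x 20, rank 5, seed 1)."""
    return generate(SyntheticSpec())


def random_binary(rng: np.random.Generator, n: int, p: int, density: float = 0.3):
    """Random 0/1 matrix with every row nonzero (a valid profile matrix)."""
    X = (rng.random((n, p)) < density).astype(float)
    for i in np.flatnonzero(X.sum(axis=1) == 0):
        X[i, rng.integers(p)] = 1.0
    return X
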