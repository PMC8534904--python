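import numpy as np
import pytest

from pmnmix.matnorm import MatrixNormalParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, d, jitter=None):
    """Random well-conditioned SPD matrix."""
    A = rng.normal(size=(d, d))
    return A @ A.T + (jitter if jitter is not None else d) * np.eye(d)


def random_params(rng, p, q):
    return MatrixNormalParams(
        M=rng.normal(size=(p, q)),
        U=random_spd(rng, p),
        V=random_spd(rng, q),
    )


def vec(X):
    """Column-stacking vectorization, the convention used throughout."""
    return np.asarray(X).flatten(order="F")
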