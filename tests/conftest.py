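"""Shared fixtures for the test suite."""

import os

# Keep BLAS single-threaded: the training GEMMs are skinny and thread
# oversubscription slows them down. Must happen before numpy loads.
for var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(var, "1")

import numpy as np  # noqa: E402
import pytest  # noqa: E402

from dstrf.cnn import CnnModel, CnnSpec  # noqa: E402
from dstrf.stimulus import make_windows  # noqa: E402
from dstrf.synth import generate_stimulus  # noqa: E402


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_stimulus():
    """A 30 s, 32-band correlated stimulus shared across tests."""
    return generate_stimulus(30.0, seed=77)


@pytest.fixture(scope="session")
def small_windows(small_stimulus):
    return make_windows(small_stimulus)


@pytest.fixture(scope="session")
def untrained_cnn():
    """An untrained (random but non-degenerate) CNN for linearization tests."""
    model = CnnModel(CnnSpec(), seed=5)
    return model


@pytest.fixture(scope="session")
def random_windows():
    gen = np.random.default_rng(11)
    return gen.standard_normal((40, 40, 32)) * 0.5 + 0.3
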