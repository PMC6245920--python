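import numpy as np
import pytest

from svmrfe import KernelSpec, LabeledSet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180001)


@pytest.fixture
def gaussian():
    return KernelSpec("gaussian", 2.0)


@pytest.fixture
def linear():
    return KernelSpec("linear", None)


def random_classification(seed: int, n: int = 25, p: int = 4, signal: float = 1.0) -> LabeledSet:
    """Small random binary problem with a planted signal in the first column."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.sign(signal * X[:, 0] + 0.5 * rng.normal(size=n))
    y[y == 0] = 1
    return LabeledSet.from_labels(X, y)


@pytest.fixture
def toy_labeled():
    return random_classification(0)
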