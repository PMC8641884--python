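import numpy as np
import pytest

from dfcselect import generate_case1, generate_case2


@pytest.fixture(scope="session")
def case1():
    return generate_case1(seed=11)


@pytest.fixture(scope="session")
def case2():
    return generate_case2(seed=22)


@pytest.fixture(scope="session")
def small_instance():
    """3 informative-ish features, 150 cells: the solver-oracle workhorse."""
    rng = np.random.default_rng(7)
    n = 150
    y = (rng.random(n) < 0.4).astype(float)
    X = rng.standard_normal((n, 3)) + np.outer(y, [1.0, -0.6, 0.2])
    return X, y
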