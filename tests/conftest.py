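import numpy as np
import pytest

from erpselect.core_model import GroupStructure, TrialSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def groups_2x2():
    """Two sensors with two features each (d = 4)."""
    return GroupStructure.contiguous(2, 2)


@pytest.fixture
def small_trials(rng):
    """20 weakly separable trials on 3 sensors x 2 features."""
    p, r, n = 3, 2, 20
    d = p * r
    y = np.where(rng.random(n) < 0.5, 1, -1)
    y[0], y[1] = 1, -1
    direction = rng.standard_normal(d)
    X = rng.standard_normal((n, d)) + 0.8 * np.outer(y, direction / np.sqrt(d))
    return TrialSet(X, y, p, r)


@pytest.fixture
def recovery_trials(rng):
    """One informative sensor group plus three pure-noise groups."""
    p, r, n = 4, 3, 60
    d = p * r
    y = np.where(rng.random(n) < 0.5, 1, -1)
    y[0], y[1] = 1, -1
    X = 0.3 * rng.standard_normal((n, d))
    signal = np.array([1.0, -0.5, 0.8])
    X[:, :r] += np.outer(y, signal)
    return TrialSet(X, y, p, r)
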