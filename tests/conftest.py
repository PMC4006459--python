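import numpy as np
import pytest

from scanbma import ExpressionTimeSeries, RegressionData


@pytest.fixture
def rng():
    return np.random.default_rng(20140417)


@pytest.fixture
def small_ts(rng):
    """5 genes x 6 times x 3 replicates of smooth random dynamics."""
    values = rng.standard_normal((5, 6, 3)).cumsum(axis=1) * 0.5
    return ExpressionTimeSeries(
        [f"G{i}" for i in range(1, 6)], np.arange(6.0), ["R1", "R2", "R3"], values
    )


def make_regression(rng, n, p, signal_cols=(), coef=1.0, noise=1.0):
    """Random regression instance with optional true signal columns."""
    X = rng.standard_normal((n, p))
    y = noise * rng.standard_normal(n)
    for j in signal_cols:
        y = y + coef * X[:, j]
    return RegressionData(y, X, [f"C{j:02d}" for j in range(p)])
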