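import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_ls_instance(rng, n=None, m=None, heteroskedastic=True):
    """A random least-squares problem with its design and residual pieces."""
    import resindex as rx

    n = int(rng.integers(30, 200)) if n is None else n
    m = int(rng.integers(2, 7)) if m is None else m
    X = rng.standard_normal((n, m))
    X[:, 0] = 1.0
    theta_true = rng.standard_normal(m)
    noise = rng.standard_normal(n)
    if heteroskedastic:
        noise = noise * (0.5 + np.abs(X[:, -1]))
    y = X @ theta_true + noise
    m1 = int(rng.integers(1, m))
    table = rx.ObservationTable(y, X, m0=m - m1, m1=m1)
    return rx.least_squares_problem(table), X, y
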