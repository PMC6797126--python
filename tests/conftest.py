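import numpy as np
import pytest

from tapetraj import adgraph as ad


@pytest.fixture
def fig_tape():
    """Tape of y = cos(x2) - x2*x1 recorded at (1, pi/2)."""
    return ad.record(lambda x: ad.cos(x[1]) - x[1] * x[0], [1.0, np.pi / 2])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tape(rng, n_in=None):
    """A random smooth multi-output tape for property tests.

    Compositions of the supported ops with inputs kept in safe domains
    (positive arguments for log/sqrt).
    """
    if n_in is None:
        n_in = int(rng.integers(1, 5))
    x0 = rng.uniform(0.5, 1.5, size=n_in)

    def fn(x):
        outs = []
        a = x[0]
        for i in range(1, n_in):
            a = a * x[i] + ad.sin(x[i - 1])
        outs.append(a)
        b = 0.0
        for i in range(n_in):
            b = b + ad.exp(0.3 * x[i]) - ad.tanh(x[i] * a * 0.1)
        outs.append(b / n_in)
        outs.append(ad.sqrt(x[0] * x[0] + 1.0) * ad.atan(b * 0.2) + x[-1] ** 3)
        return outs

    return ad.record(fn, x0)
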