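import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def finite_difference(fn, param, h=1e-6):
    """Central finite-difference gradient of scalar fn() w.r.t. param.data."""
    num = np.zeros_like(param.data)
    it = np.nditer(num, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = param.data[i]
        step = h * max(1.0, abs(old))
        param.data[i] = old + step
        lp = float(fn())
        param.data[i] = old - step
        lm = float(fn())
        param.data[i] = old
        num[i] = (lp - lm) / (2 * step)
    return num


def rel_err(a, b):
    a, b = np.asarray(a), np.asarray(b)
    return np.abs(a - b).max() / (np.abs(b).max() + 1e-12)
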