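import numpy as np
import pytest

import bcmring as b


@pytest.fixture(scope="session")
def vm8():
    return b.build_ensemble("von_mises", 8, 8, 0.5)


@pytest.fixture(scope="session")
def vm4():
    return b.build_ensemble("von_mises", 4, 4, 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def scalar_profile_value(kind: str, offset: float, n: int, omega: float) -> float:
    """Independent scalar evaluation of the profile formulas (test oracle)."""
    import math

    if kind == "von_mises":
        return math.exp((math.cos(2.0 * math.pi * offset / n) - 1.0) / omega)
    if kind == "triangular":
        d = abs(offset) % n
        d = min(d, n - d)
        return max(1.0 - d / (omega * n), 0.0)
    raise ValueError(kind)
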