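import itertools

import numpy as np
import pytest

from exoflux import NATURAL_ACETYL, fatty_acid_forward_mid  # noqa: F401  (re-exported for tests)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def acetyl_assignments():
    """All 3**8 assignments of 8 acetyl units to mass classes 0/1/2."""
    return np.array(list(itertools.product(range(3), repeat=8)))


@pytest.fixture(scope="session")
def brute_force_palmitate(acetyl_assignments):
    """Exhaustive-enumeration oracle for the fatty-acid forward model."""

    def _evaluate(x3: np.ndarray, n3: np.ndarray, g: float) -> np.ndarray:
        masses = acetyl_assignments.sum(axis=1)
        px = np.prod(x3[acetyl_assignments], axis=1)
        pn = np.prod(n3[acetyl_assignments], axis=1)
        out = np.zeros(17)
        np.add.at(out, masses, g * px + (1 - g) * pn)
        return out

    return _evaluate
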