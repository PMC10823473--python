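import numpy as np
import pytest

import fisstkit as fk


@pytest.fixture
def harmonic():
    return fk.make_harmonic_cv_system(stiffness=1.0, center=0.0)


@pytest.fixture
def harmonic_oracle(harmonic):
    return fk.oracle_for_system(harmonic, beta=1.0, q_grid=np.linspace(-9.0, 9.0, 36001))


@pytest.fixture
def quartic_well():
    return fk.make_double_well_system(barrier=4.0, well_separation=2.0, form="quartic")


def fd_gradient(func, x, h=1e-6):
    """Central finite differences of a scalar function of an (n,d) array."""
    g = np.zeros_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            xp = x.copy()
            xp[i, j] += h
            xm = x.copy()
            xm[i, j] -= h
            g[i, j] = (func(xp) - func(xm)) / (2 * h)
    return g
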