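import numpy as np
import pytest

from hardiopt import signal_sim as sim
from hardiopt import sphere_math as sm


@pytest.fixture(scope="session")
def scheme_72():
    return sim.generate_gradient_scheme(72, seed=42)

@pytest.fixture(scope="session")
def scheme_60():
    return sim.generate_gradient_scheme(60, seed=7)


@pytest.fixture(scope="session")
def mesh4():
    return sm.tessellate_icosahedron(4)


@pytest.fixture(scope="session")
def mesh5():
    return sm.tessellate_icosahedron(5)


@pytest.fixture(scope="session")
def sphere_quadrature():
    """Gauss-Legendre(theta) x uniform(phi) product rule, exact for SH up
    to high degree: (directions, weights summing to 4 pi)."""
    x, w = np.polynomial.legendre.leggauss(24)
    n_phi = 48
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    theta = np.arccos(x)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    st = np.sin(tt).ravel()
    dirs = np.column_stack(
        [st * np.cos(pp.ravel()), st * np.sin(pp.ravel()), np.cos(tt).ravel()]
    )
    weights = np.repeat(w, n_phi) * (2.0 * np.pi / n_phi)
    return dirs, weights
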