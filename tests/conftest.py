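import numpy as np
import pytest

from ironstrip import (
    KineticConditions,
    OpticalConstants,
    RateLawParams,
    simulate_complex_formation,
)

#: Rate constant used throughout the kinetic tests; with orders (1, 2) and
#: millimolar ferene it gives observed rates of 0.02-0.08 1/s, i.e. colour
#: development on the assay's two-minute timescale.
K_PRIME = 5000.0


@pytest.fixture(scope="session")
def optics():
    return OpticalConstants()


@pytest.fixture(scope="session")
def design_2x2():
    """Noise-free simulated 2x2 kinetic design: 50/100 ug/dL x 2/4 mM."""
    params = RateLawParams(k_prime=K_PRIME, alpha=1.0, beta=2.0)
    return [
        simulate_complex_formation(KineticConditions.from_assay(iron, ferene), params)
        for iron in (50.0, 100.0)
        for ferene in (2.0, 4.0)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
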