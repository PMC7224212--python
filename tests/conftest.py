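import numpy as np
import pytest

from fdelast.phantoms import end_to_end_case


@pytest.fixture(scope="session")
def bilayer_coarse():
    """6x6 mm bilayer at 0.3 mm (20x20 elements): fast inversion fixture."""
    return end_to_end_case("bilayer2d", resolution=0.3)


@pytest.fixture(scope="session")
def bilayer_fine():
    """6x6 mm bilayer at the imaging resolution (0.15 mm, 40x40 elements)."""
    return end_to_end_case("bilayer2d")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
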