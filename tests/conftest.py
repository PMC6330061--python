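import numpy as np
import pytest

from celldose.nuclide import (
    ElectronEmissionSpectrum,
    StoppingRangeTable,
    build_dpk,
    load_spectrum,
    load_stopping_table,
)
from celldose.svalues import KernelMoments


@pytest.fixture(scope="session")
def spectrum():
    return load_spectrum("In-111")


@pytest.fixture(scope="session")
def water():
    return load_stopping_table("water")


@pytest.fixture(scope="session")
def kernel(spectrum, water):
    return build_dpk(spectrum, water)


@pytest.fixture(scope="session")
def moments(kernel):
    return KernelMoments(kernel)


@pytest.fixture(scope="session")
def constant_stopping_table():
    """Toy medium with constant stopping power 1 keV/um (range = E in um)."""
    E = np.geomspace(0.01, 500.0, 60)
    S = np.ones_like(E)
    return StoppingRangeTable(E, S, E.copy())


def make_toy_spectrum(lines):
    return ElectronEmissionSpectrum.from_lines(lines, nuclide_id="toy")


@pytest.fixture
def toy_spectrum_factory():
    return make_toy_spectrum


@pytest.fixture(scope="session")
def small_cluster():
    """A modest MDA-468 cluster shared by assembly-level tests."""
    from celldose.pipeline import cached_assembly

    return cached_assembly("MDA-468", 150, 11)
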