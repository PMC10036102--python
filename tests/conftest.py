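import numpy as np
import pytest

from scattershield.spectrum import Spectrum, table1_beam


@pytest.fixture(scope="session")
def beam():
    """The clinical 80 kVp beam with full added filtration."""
    return table1_beam()


@pytest.fixture(scope="session")
def mono60():
    """A quasi-monoenergetic 60 keV spectrum (one narrow bin)."""
    return Spectrum(np.array([59.95, 60.05]), np.array([1.0]), 1.0)


def mono_spectrum(energy_keV: float) -> Spectrum:
    half = 0.05
    return Spectrum(np.array([energy_keV - half, energy_keV + half]),
                    np.array([1.0]), 1.0)
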