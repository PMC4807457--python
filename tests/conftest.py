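import numpy as np
import pytest

from hhabc.model import MembraneConstants, VoltageDependencyParams


@pytest.fixture(scope="session")
def k_default():
    return VoltageDependencyParams()


@pytest.fixture(scope="session")
def consts():
    return MembraneConstants()


@pytest.fixture(scope="session")
def reference_rate_functions():
    """Hand-coded classic rate curves, independent of the package path."""
    return {
        "alpha_n": lambda V: 0.01 * (V + 10) / (np.exp((V + 10) / 10) - 1),
        "beta_n": lambda V: 0.125 * np.exp(V / 80),
        "alpha_m": lambda V: 0.1 * (V + 25) / (np.exp((V + 25) / 10) - 1),
        "beta_m": lambda V: 4 * np.exp(V / 18),
        "alpha_h": lambda V: 0.07 * np.exp(V / 20),
        "beta_h": lambda V: 1 / (np.exp((V + 30) / 10) + 1),
    }
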