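import numpy as np
import pytest

from growthmon import eis, simulate


@pytest.fixture
def circuit() -> eis.CircuitParameters:
    """Reference circuit with both branch corners in/near the sweep band."""
    return eis.CircuitParameters(
        r_med=100.0, r_cell=1000.0, c_cell=10e-9, r_el=500.0, c_el=100e-9
    )


@pytest.fixture
def frequencies() -> np.ndarray:
    return simulate.default_frequencies(30)


def branch_impedance_oracle(r: float, c: float, f: np.ndarray) -> np.ndarray:
    """Independent oracle: parallel RC evaluated by direct complex division."""
    return 1.0 / (1.0 / r + 1j * 2 * np.pi * f * c)


def circuit_impedance_oracle(p: eis.CircuitParameters, f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    return (
        p.r_med
        + branch_impedance_oracle(p.r_cell, p.c_cell, f)
        + branch_impedance_oracle(p.r_el, p.c_el, f)
    )
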