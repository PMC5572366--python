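import numpy as np
import pytest

from memhnn import CircuitValues, DriveSignal, HNNParams

#: High-precision reference roots of the nonzero-equilibrium problem,
#: frozen from a 40-digit arbitrary-precision solve of the nullcline
#: intersection (k=0.8, a=1).
P1_B026 = np.array([2.1647265848, -0.59653109809, -0.68643512645, 0.9739931342])
P2_B026 = np.array([-1.4751495937, 0.19721449558, 0.45283100498, -0.90055525393])
P1_B0 = np.array([1.764746307, -0.36409250161, -0.54998557796, 0.9430307493])


@pytest.fixture
def p08():
    """Reference network parameters: k=0.8, a=1, b=0.26."""
    return HNNParams(k=0.8, a=1.0, b=0.26)


@pytest.fixture
def table1_circuit():
    """Emulator component values of the reference design."""
    return CircuitValues(R=10e3, C=100e-9, Ra=10e3, Rb=2e3, g=0.1)


@pytest.fixture
def drive_4v_400hz():
    return DriveSignal(Vm=4.0, f=400.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
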