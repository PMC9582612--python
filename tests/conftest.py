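import numpy as np
import pytest

from stimsafe.types import (
    CircuitParams,
    ElectrodeSpec,
    InterfaceParams,
    MediumParams,
    SafetyParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ptnr_spec():
    return ElectrodeSpec(material="PtNR", diameter_m=200e-6)


@pytest.fixture
def invivo_spec():
    return ElectrodeSpec(material="PtNR", diameter_m=200e-6, medium="in_vivo")


@pytest.fixture
def example_circuit():
    """Representative bipolar circuit with CPE interfaces and a bulk branch."""
    iface = InterfaceParams(q_dl=3e-7, n_dl=0.88, r_ct=5e6)
    medium = MediumParams(r_spread=800.0, r_ex=1200.0, r_in=1200.0, c_in=2e-7)
    return CircuitParams(working=iface, counter=iface, medium=medium)


@pytest.fixture
def truth_params():
    """A typical excitation-law truth in the (uA, us, kOhm) convention."""
    return SafetyParams(a=0.35, b=1e-5, k2=1.0, k4=0.9, k6=1.0)


def random_safety_params(rng) -> SafetyParams:
    return SafetyParams(
        a=float(rng.uniform(0.1, 1.0)),
        b=float(10.0 ** rng.uniform(-5.0, -1.0)),
        k2=float(rng.uniform(0.5, 1.5)),
        k4=float(rng.uniform(0.5, 1.5)),
        k6=float(rng.uniform(0.5, 1.5)),
    )
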