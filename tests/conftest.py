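import pytest

from pyeloflow.hydraulics import (
    FluidProperties,
    resistance_set,
    sheath_from_label,
    table1_anatomy,
    table1_scope,
)
from pyeloflow.dynamics import CircuitParameters
from pyeloflow.units import cmH2O_to_Pa


@pytest.fixture(scope="session")
def scope():
    return table1_scope()


@pytest.fixture(scope="session")
def anatomy():
    return table1_anatomy()


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def make_params(scope, anatomy, fluid):
    """Build CircuitParameters for a sheath label (None = no sheath)."""

    def _make(sheath_label=None, p_irr_cmH2O=150.0, p0_cmH2O=0.0):
        sheath = None if sheath_label is None else sheath_from_label(sheath_label)
        return CircuitParameters(
            resistances=resistance_set(scope, anatomy, sheath, fluid),
            stiffness=anatomy.stiffness,
            irrigation_pressure=cmH2O_to_Pa(p_irr_cmH2O),
            initial_pressure=cmH2O_to_Pa(p0_cmH2O),
        )

    return _make
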