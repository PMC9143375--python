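import pytest

from slsfit import (
    CreepProtocol,
    RelaxationProtocol,
    benchmark_materials,
    make_sls,
    simulate_creep,
    simulate_relaxation,
)


@pytest.fixture(scope="session")
def soft_material():
    """Softest benchmark material: E1=5 kPa, E2=20 kPa, eta=10 kPa.s (tau_R=0.5 s)."""
    return make_sls(5e3, 20e3, 10e3)


@pytest.fixture(scope="session")
def materials():
    return benchmark_materials()


@pytest.fixture(scope="session")
def relaxation_curve(soft_material):
    """Noiseless ramp-hold relaxation curve at a moderate strain rate."""
    proto = RelaxationProtocol(0.01, 0.01, 8 * soft_material.tau_R)
    return simulate_relaxation(soft_material, proto)


@pytest.fixture(scope="session")
def creep_curve(soft_material):
    """Noiseless ramp-hold creep curve at a moderate stress rate."""
    proto = CreepProtocol(1000.0, 100.0, 8 * soft_material.tau_C)
    return simulate_creep(soft_material, proto)
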