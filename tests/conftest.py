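import numpy as np
import pytest

from dendrosim.morphology import (
    CompartmentSpec,
    Geometry,
    NeuronModelSpec,
    PassiveParams,
    build_model,
)
from dendrosim.dynamics import DSpikeParams, SomaParams


@pytest.fixture
def passive_single():
    """One passive compartment: C_m = 6.283 pF, g_L = 0.314 nS, τ = 20 ms."""
    comp = CompartmentSpec(
        "soma", "soma", Geometry(100, 2),
        PassiveParams(1.0, 20.0, 150.0, -70.0), spine_factor=1.0,
    )
    spec = NeuronModelSpec(
        compartments=(comp,), edges=(),
        soma_params=SomaParams(V_th=1e3, V_spike=2e3, V_reset=-80.0),
    )
    return build_model(spec)


@pytest.fixture
def passive_pair():
    """Soma + one passive dendrite, non-spiking soma."""
    P = PassiveParams(1.0, 20.0, 150.0, -70.0)
    spec = NeuronModelSpec(
        compartments=(
            CompartmentSpec("soma", "soma", Geometry(20, 20), P, spine_factor=1.0),
            CompartmentSpec("dend", "dendrite", Geometry(200, 1.5), P, spine_factor=1.0),
        ),
        edges=(("soma", "dend"),),
        soma_params=SomaParams(V_th=1e3, V_spike=2e3, V_reset=-80.0),
    )
    return build_model(spec)


def active_dendrite_model(dspike: DSpikeParams | None):
    """Soma + one dendrite, optionally with the dSpike mechanism."""
    P = PassiveParams(1.0, 20.0, 150.0, -70.0)
    spec = NeuronModelSpec(
        compartments=(
            CompartmentSpec("soma", "soma", Geometry(20, 20), P, spine_factor=1.0),
            CompartmentSpec("dend", "dendrite", Geometry(200, 1.5), P,
                            spine_factor=1.0, dspike=dspike),
        ),
        edges=(("soma", "dend"),),
        soma_params=SomaParams(V_th=1e3, V_spike=2e3, V_reset=-80.0),
    )
    return build_model(spec)


@pytest.fixture
def dspike_params():
    return DSpikeParams(
        gbar_Na_nS=20.0, gbar_Kdr_nS=20.0, tau_Na_ms=1.0, tau_Kdr_ms=2.0,
        V_th_d_mV=-35.0, t_ref_Na_ms=5.0, t_offset_Kdr_ms=1.0,
    )


@pytest.fixture(scope="session")
def model_b():
    from dendrosim import fixtures

    return fixtures.model_b()


@pytest.fixture(scope="session")
def model_a():
    from dendrosim import fixtures

    return fixtures.model_a()
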