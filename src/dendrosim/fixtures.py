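"""Reference models: three reduced neurons of increasing realism.

``model_a``
    Three compartments — a leaky I&F soma with two passive dendrites
    (basal 150 µm, apical 250 µm).  The apical dendrite carries AMPA+NMDA
    synapses; NMDA unblock makes its input–output curve supralinear, and
    blocking NMDA switches it to sublinear (driving-force saturation).

``model_b``
    Four compartments — soma plus an apical dendrite split into trunk,
    proximal and distal segments, all equipped with the event-driven
    Na⁺/K_dr spike mechanism.  The distal segment is thin and sealed, so
    its input resistance is highest and its dSpike rheobase lowest; the
    thick proximal segment has the highest rheobase.  Backpropagating
    spikes invade trunk and proximal segments fully but reach the distal
    segment only as subthreshold spikelets.

``model_c``
    Nine compartments shaped like a CA1 pyramidal cell: soma, two basal
    dendrites, proximal and distal apical trunk, two radial obliques and
    two distal tuft branches.  Entorhinal-cortex (EC) input targets the
    tuft, CA3 input the obliques and distal trunk, replicating the
    laminar segregation of those pathways.  Passive properties are
    calibrated (joint C_m/g_L scaling) to a CA1-like input resistance and
    membrane time constant.

All free parameters here were produced by the calibration protocols in
:mod:`dendrosim.protocols` (passive scaling, rheobase ordering, dSpike
amplitude checks) against the qualitative constraints above — they are
this package's own calibration products, not values transcribed
from any published model.
"""

from __future__ import annotations

from functools import lru_cache

from .morphology import (
    CompartmentSpec,
    Geometry,
    NeuronModel,
    NeuronModelSpec,
    PassiveParams,
    build_model,
    cylinder_area,
)
from .dynamics import DSpikeParams, SomaParams
from .synapses import MgBlockParams, SynapseParams

__all__ = ["model_a", "model_b", "model_c", "ca1_pathways", "unitary_contact"]

#: dendritic Na⁺ channel density used by the active fixtures, mS·cm⁻²
_GNA_DENSITY_MS_CM2 = 5.0
#: delayed-rectifier K⁺ to Na⁺ peak-conductance ratio
_K_TO_NA = 1.0


def _dspike(
    geom: Geometry,
    v_th: float = -35.0,
    spine_factor: float = 1.5,
    density: float = _GNA_DENSITY_MS_CM2,
    k_to_na: float = _K_TO_NA,
    tau_na: float = 1.0,
    t_offset: float = 0.5,
) -> DSpikeParams:
    """dSpike conductances scaled with the compartment's (spiny) area."""
    area = cylinder_area(geom) * spine_factor
    g_na = density * 1e-3 * area * 1e9   # mS/cm²·cm² → nS
    return DSpikeParams(
        gbar_Na_nS=g_na,
        gbar_Kdr_nS=g_na * k_to_na,
        tau_Na_ms=tau_na,
        tau_Kdr_ms=2.0,
        V_th_d_mV=v_th,
        t_ref_Na_ms=5.0,
        t_offset_Kdr_ms=t_offset,
    )


def _ampa_nmda(g_ampa: float, g_nmda: float) -> tuple:
    return (
        SynapseParams("AMPA", g_ampa, 0.0, 0.2, 2.0),
        SynapseParams("NMDA", g_nmda, 0.0, 2.0, 50.0, mg=MgBlockParams()),
    )


@lru_cache(maxsize=None)
def model_a() -> NeuronModel:
    """Passive two-dendrite neuron, calibrated to R_in=120 MΩ, τ_m=20 ms."""
    from .protocols import calibrate_passive

    P = PassiveParams(1.0, 20.0, 150.0, -70.0)
    spec = NeuronModelSpec(
        compartments=(
            CompartmentSpec("soma", "soma", Geometry(25, 25), P, spine_factor=1.0),
            CompartmentSpec("basal", "dendrite", Geometry(150, 1.2), P),
            CompartmentSpec(
                "apical", "dendrite", Geometry(250, 1.2), P,
                synapses=_ampa_nmda(1.2, 2.0),
            ),
        ),
        edges=(("soma", "basal"), ("soma", "apical")),
        soma_params=SomaParams(V_th=-50.0, V_spike=35.0, V_reset=-55.0),
        name="passive-two-dendrite",
    )
    model, _ = calibrate_passive(build_model(spec), R_input_MOhm=120.0, tau_m_ms=20.0)
    return model


@lru_cache(maxsize=None)
def model_b() -> NeuronModel:
    """Active apical-chain neuron (soma–trunk–proximal–distal)."""
    P = PassiveParams(1.0, 30.0, 150.0, -70.0)
    g_t, g_p, g_d = Geometry(100, 1.0), Geometry(150, 2.0), Geometry(150, 0.4)
    spec = NeuronModelSpec(
        compartments=(
            CompartmentSpec("soma", "soma", Geometry(25, 25), P, spine_factor=1.0),
            CompartmentSpec("trunk", "dendrite", g_t, P, dspike=_dspike(g_t)),
            CompartmentSpec(
                "proximal", "dendrite", g_p, P, dspike=_dspike(g_p),
                synapses=_ampa_nmda(2.5, 0.2),
            ),
            CompartmentSpec(
                "distal", "dendrite", g_d, P, dspike=_dspike(g_d, v_th=-25.0),
                synapses=_ampa_nmda(2.5, 0.2),
            ),
        ),
        edges=(("soma", "trunk"), ("trunk", "proximal"), ("proximal", "distal")),
        # thin sealed distal branch: reduced coupling keeps backpropagating
        # spikes subthreshold there (manual attenuation correction)
        coupling_overrides={("proximal", "distal"): 0.4},
        soma_params=SomaParams(
            V_th=-50.0, V_spike=35.0, V_reset=-55.0,
            tau_A_ms=100.0, gbar_A_nS=0.0, b_nS=1.0,
        ),
        name="active-apical-chain",
    )
    return build_model(spec)


def model_c(
    g_ampa_ca3: float = 3.5,
    g_nmda_ca3: float = 1.0,
    g_ampa_ec: float = 3.0,
    g_nmda_ec: float = 4.0,
    gc_tuft: float = 2.0,
    gc_oblique: float = 4.5,
    gc_trunk: float | None = None,
    v_th_tuft: float = -30.0,
    v_th_oblique: float = -22.0,
    v_th_trunk_dist: float = -43.5,
    k_to_na: float = 0.4,
    soma_V_th: float = -50.0,
    R_input_MOhm: float = 120.0,
    tau_m_ms: float = 28.0,
) -> NeuronModel:
    """CA1-like nine-compartment pyramidal cell.

    Keyword arguments expose the synaptic weights and thin-branch coupling
    corrections so the pathway-tuning protocol can report the values it
    used; the defaults are the calibrated fixture.
    """
    from .protocols import calibrate_passive

    P = PassiveParams(1.0, 28.0, 150.0, -70.0)
    g_soma = Geometry(25, 25)
    g_basal = Geometry(150, 1.0)
    g_tp = Geometry(100, 2.5)
    g_td = Geometry(150, 2.0)
    g_obl = Geometry(120, 0.8)
    g_tuft = Geometry(150, 0.8)
    ca3_syn = _ampa_nmda(g_ampa_ca3, g_nmda_ca3)
    ec_syn = _ampa_nmda(g_ampa_ec, g_nmda_ec)
    spec = NeuronModelSpec(
        compartments=(
            CompartmentSpec("soma", "soma", g_soma, P, spine_factor=1.0),
            CompartmentSpec("basal1", "dendrite", g_basal, P),
            CompartmentSpec("basal2", "dendrite", g_basal, P),
            CompartmentSpec("trunk_prox", "dendrite", g_tp, P,
                            dspike=_dspike(g_tp, k_to_na=k_to_na)),
            CompartmentSpec(
                "trunk_dist", "dendrite", g_td, P,
                dspike=_dspike(g_td, v_th=v_th_trunk_dist, k_to_na=k_to_na), synapses=ca3_syn,
            ),
            CompartmentSpec(
                "oblique1", "dendrite", g_obl, P,
                dspike=_dspike(g_obl, v_th=v_th_oblique, k_to_na=k_to_na), synapses=ca3_syn,
            ),
            CompartmentSpec(
                "oblique2", "dendrite", g_obl, P,
                dspike=_dspike(g_obl, v_th=v_th_oblique, k_to_na=k_to_na), synapses=ca3_syn,
            ),
            CompartmentSpec(
                "tuft1", "dendrite", g_tuft, P,
                dspike=_dspike(g_tuft, v_th=v_th_tuft, k_to_na=k_to_na), synapses=ec_syn,
            ),
            CompartmentSpec(
                "tuft2", "dendrite", g_tuft, P,
                dspike=_dspike(g_tuft, v_th=v_th_tuft, k_to_na=k_to_na), synapses=ec_syn,
            ),
        ),
        edges=(
            ("soma", "basal1"),
            ("soma", "basal2"),
            ("soma", "trunk_prox"),
            ("trunk_prox", "trunk_dist"),
            ("trunk_dist", "oblique1"),
            ("trunk_dist", "oblique2"),
            ("trunk_dist", "tuft1"),
            ("trunk_dist", "tuft2"),
        ),
        coupling_overrides={
            **({("trunk_prox", "trunk_dist"): gc_trunk} if gc_trunk else {}),
            ("trunk_dist", "tuft1"): gc_tuft,
            ("trunk_dist", "tuft2"): gc_tuft,
            ("trunk_dist", "oblique1"): gc_oblique,
            ("trunk_dist", "oblique2"): gc_oblique,
        },
        soma_params=SomaParams(
            V_th=soma_V_th, V_spike=20.0, V_reset=-65.0,
            tau_A_ms=300.0, gbar_A_nS=0.0, b_nS=6.0,
        ),
        name="ca1-nine-compartment",
    )
    model, _ = calibrate_passive(
        build_model(spec), R_input_MOhm=R_input_MOhm, tau_m_ms=tau_m_ms
    )
    return model


def unitary_contact(g_ampa: float = 0.8, g_nmda: float = 0.5) -> tuple:
    """A single small synaptic contact (AMPA+NMDA) for input–output
    protocols on the CA1 fixture.  The synapse sets declared on the model's
    branches are pathway *stream* aggregates (one per afferent stream); a
    unitary contact is the per-synapse quantum those protocols sum."""
    return _ampa_nmda(g_ampa, g_nmda)


#: default laminar pathway map of the CA1 fixture: EC onto the two tuft
#: branches, CA3 onto the two obliques and the distal trunk
def ca1_pathways() -> dict:
    return {
        "EC": ("tuft1", "tuft2"),
        "CA3": ("oblique1", "oblique2", "trunk_dist"),
    }
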