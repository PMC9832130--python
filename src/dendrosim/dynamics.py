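"""Membrane dynamics: adaptive I&F soma and event-driven dendritic spikes.

The soma is a leaky integrate-and-fire unit with a conductance-based
adaptation variable ``g_A`` and a two-stage spike reset: on threshold
crossing the voltage jumps to ``V_spike`` (a stylised action-potential
peak), ``g_A`` is incremented by ``b``, and after ``reset_delay`` the
voltage is reset to ``V_reset``.  While the spike plateau lasts, threshold
detection is suppressed — otherwise ``V_spike > V_th`` would retrigger on
every step.

Dendritic compartments carry no adaptation.  Instead they may host a
phenomenological Na⁺/K_dr spike mechanism: when the local voltage exceeds
``V_th_d`` (and the mechanism is armed and outside its refractory period),
the Na⁺ conductance is stepped up by ``gbar_Na`` and decays exponentially
with ``tau_Na``; after ``t_offset_Kdr`` the delayed-rectifier K⁺
conductance is stepped up by ``gbar_Kdr`` and decays with ``tau_Kdr``,
repolarising the branch.  Two Boolean flags (``f_Na`` armed / ``f_Kdr``
K-pending) implement the event state machine; they are never both 1.

All functions here are pure and operate on scalars or NumPy arrays; the
time loop lives in :mod:`dendrosim.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import ModelValidationError, NeuronModel

__all__ = ["SomaParams", "DSpikeParams", "soma_rhs", "dendrite_rhs", "axial_currents"]


@dataclass(frozen=True)
class SomaParams:
    """Spiking and adaptation parameters of the somatic compartment (mV/ms/nS)."""

    V_th: float = -50.0
    V_spike: float = 35.0
    V_reset: float = -55.0
    reset_delay_ms: float = 0.5
    tau_A_ms: float = 100.0
    gbar_A_nS: float = 0.0   # subthreshold adaptation strength
    b_nS: float = 0.0        # spike-triggered adaptation increment
    E_A_mV: float = -80.0    # adaptation reversal potential
    V_A_mV: float = -70.0    # reference voltage of the |V - V_A| drive

    def __post_init__(self) -> None:
        if not (self.V_spike > self.V_th > self.V_reset):
            raise ModelValidationError(
                f"require V_spike > V_th > V_reset, got "
                f"{self.V_spike} / {self.V_th} / {self.V_reset} mV"
            )
        if self.reset_delay_ms <= 0 or self.tau_A_ms <= 0:
            raise ModelValidationError("reset_delay and tau_A must be positive")
        if self.gbar_A_nS < 0 or self.b_nS < 0:
            raise ModelValidationError("adaptation conductances must be >= 0")


@dataclass(frozen=True)
class DSpikeParams:
    """Parameters of the event-driven dendritic Na⁺/K_dr spike mechanism.

    ``t_offset_Kdr < t_ref_Na`` is enforced so the K_dr event (which
    re-arms the Na mechanism) always fires before the refractory window can
    end — the state machine would otherwise deadlock disarmed.
    """

    gbar_Na_nS: float
    gbar_Kdr_nS: float
    E_Na_mV: float = 70.0
    E_K_mV: float = -89.0
    tau_Na_ms: float = 1.0
    tau_Kdr_ms: float = 2.0
    V_th_d_mV: float = -35.0
    t_ref_Na_ms: float = 5.0
    t_offset_Kdr_ms: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.tau_Na_ms, self.tau_Kdr_ms, self.t_ref_Na_ms, self.t_offset_Kdr_ms) <= 0:
            raise ModelValidationError("dSpike time constants and delays must be positive")
        if not self.t_offset_Kdr_ms < self.t_ref_Na_ms:
            raise ModelValidationError(
                f"t_offset_Kdr ({self.t_offset_Kdr_ms} ms) must be shorter than "
                f"t_ref_Na ({self.t_ref_Na_ms} ms)"
            )
        if not (self.E_Na_mV > self.V_th_d_mV > self.E_K_mV):
            raise ModelValidationError("require E_Na > V_th_d > E_K")
        if self.gbar_Na_nS < 0 or self.gbar_Kdr_nS < 0:
            raise ModelValidationError("dSpike conductances must be >= 0")


def soma_rhs(V, g_A, p: SomaParams, C_m, g_L, EL, I_axial=0.0, I_syn=0.0, I_ext=0.0):
    """Continuous part of the somatic dynamics.

    dV/dt = [−g_L(V−EL) − g_A(V−E_A) + I_axial + I_syn + I_ext] / C_m
    dg_A/dt = [ḡ_A·|V−V_A| − g_A] / τ_A

    Voltages in mV, conductances nS, currents pA, capacitance pF; the
    returned rates are mV/ms and nS/ms.
    """
    dV = (-g_L * (V - EL) - g_A * (V - p.E_A_mV) + I_axial + I_syn + I_ext) / C_m
    dgA = (p.gbar_A_nS * np.abs(V - p.V_A_mV) - g_A) / p.tau_A_ms
    return dV, dgA


def dendrite_rhs(V, g_Na, g_Kdr, p: DSpikeParams | None, C_m, g_L, EL,
                 I_axial=0.0, I_syn=0.0, I_ext=0.0):
    """Continuous part of the dendritic dynamics.

    The Na⁺/K_dr currents are −g(V−E) with conductances that decay
    exponentially between trigger events; with ``p=None`` (or the mechanism
    disabled) the compartment is purely passive.
    """
    if p is None:
        dV = (-g_L * (V - EL) + I_axial + I_syn + I_ext) / C_m
        return dV, 0.0 * g_Na, 0.0 * g_Kdr
    I_Na = -g_Na * (V - p.E_Na_mV)
    I_K = -g_Kdr * (V - p.E_K_mV)
    dV = (-g_L * (V - EL) + I_Na + I_K + I_axial + I_syn + I_ext) / C_m
    return dV, -g_Na / p.tau_Na_ms, -g_Kdr / p.tau_Kdr_ms


def axial_currents(model: NeuronModel, V: np.ndarray) -> np.ndarray:
    """Net axial current (pA) into every compartment.

    I_a into k = Σ_{i ~ k} g_c(i,k)·(V_i − V_k); pairwise antisymmetric, so
    the currents sum to zero over the whole neuron.  ``V`` may be shaped
    (C,) for one neuron or (n, C) for a batch.
    """
    W = model.coupling_nS
    deg = W.sum(axis=0)
    return V @ W - V * deg
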