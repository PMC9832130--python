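"""Conductance-based AMPA/NMDA/GABA synapse kinetics.

A synaptic current is ``I = −ḡ·f_syn·s(t)·(V−E_syn)·σ(V)`` where ``s`` is a
dimensionless gating waveform driven by presynaptic spikes, ``f_syn``
normalises its peak to 1 so that ``ḡ`` is the true peak conductance, and
``σ(V)`` is the sigmoidal Mg²⁺-unblock factor (NMDA only; 1 otherwise).

Three kinetic modes are provided:

``closed_form``
    the explicit dual-exponential waveform
    ``s(t) = e^{−(t−t_pre)/τ_d} − e^{−(t−t_pre)/τ_r}`` (Heaviside-gated),
``dual_exp_ode``
    the equivalent two-variable ODE with a saturating ``(1−s)`` drive —
    ``ds/dt = −s/τ_d + x(1−s)/τ_r``, ``dx/dt = −x/τ_r``, spike → ``x += 1``
    (default; ``s`` stays in [0, 1] for any spike train),
``single_exp``
    plain exponential decay, ``ds/dt = −s/τ_d``, spike → ``s += 1``
    (``f_syn = 1`` in this mode).

The closed-form and ODE modes agree in the limit of small peak ``s`` but
are not identical: the saturation term slightly depresses the ODE peak.
``f_syn`` from the closed form is applied in both, which keeps ``ḡ``
interpretable as a peak conductance to within that small discrepancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .morphology import ModelValidationError

__all__ = [
    "MgBlockParams",
    "SynapseParams",
    "t_peak_and_norm",
    "closed_form_waveform",
    "mg_sigma",
    "synaptic_current",
]


@dataclass(frozen=True)
class MgBlockParams:
    """Voltage dependence of the NMDA conductance from extracellular Mg²⁺.

    σ(V) = 1 / (1 + ([Mg²⁺]ₒ/β)·exp(−α(V−γ))).  Defaults follow the
    standard Jahr–Stevens-style parameterisation: α = 0.062 mV⁻¹,
    β = 3.57 mM, γ = 0 mV, [Mg²⁺]ₒ = 1 mM.
    """

    alpha_per_mV: float = 0.062
    beta_mM: float = 3.57
    gamma_mV: float = 0.0
    Mg_out_mM: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha_per_mV, self.beta_mM, self.Mg_out_mM) <= 0:
            raise ModelValidationError("Mg-block alpha, beta and [Mg2+]o must be positive")


@dataclass(frozen=True)
class SynapseParams:
    kind: str                     # "AMPA" | "NMDA" | "GABA"
    gbar_nS: float
    E_syn_mV: float
    tau_rise_ms: float
    tau_decay_ms: float
    kinetics: str = "dual_exp_ode"   # | "single_exp" | "closed_form"
    mg: Optional[MgBlockParams] = None

    def __post_init__(self) -> None:
        if self.kind not in ("AMPA", "NMDA", "GABA"):
            raise ModelValidationError(f"unknown synapse kind {self.kind!r}")
        if self.kinetics not in ("dual_exp_ode", "single_exp", "closed_form"):
            raise ModelValidationError(f"unknown kinetics mode {self.kinetics!r}")
        if self.kinetics != "single_exp":
            if not (self.tau_decay_ms > self.tau_rise_ms > 0):
                raise ModelValidationError(
                    f"dual-exponential kinetics require tau_decay > tau_rise > 0, "
                    f"got rise={self.tau_rise_ms} ms, decay={self.tau_decay_ms} ms"
                )
        elif self.tau_decay_ms <= 0:
            raise ModelValidationError("tau_decay must be positive")
        if (self.kind == "NMDA") != (self.mg is not None):
            raise ModelValidationError("Mg-block parameters are required iff kind is NMDA")
        if self.gbar_nS < 0:
            raise ModelValidationError("gbar must be >= 0")

    @property
    def f_norm(self) -> float:
        """Peak-normalisation factor for this synapse's waveform."""
        if self.kinetics == "single_exp":
            return 1.0
        return t_peak_and_norm(self.tau_rise_ms, self.tau_decay_ms)[1]


def t_peak_and_norm(tau_rise_ms: float, tau_decay_ms: float) -> tuple[float, float]:
    """Peak time (relative to the presynaptic spike) and normalisation factor.

    t_peak = τ_d·τ_r/(τ_d−τ_r)·ln(τ_d/τ_r);  f_syn = 1/s(t_peak) for the
    un-normalised dual-exponential waveform.  τ_d = τ_r (the alpha-function
    limit) is rejected rather than special-cased.
    """
    if not (tau_decay_ms > tau_rise_ms > 0):
        raise ModelValidationError(
            f"require tau_decay > tau_rise > 0, got rise={tau_rise_ms}, decay={tau_decay_ms}"
        )
    td, tr = tau_decay_ms, tau_rise_ms
    t_peak = td * tr / (td - tr) * math.log(td / tr)
    s_peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    return t_peak, 1.0 / s_peak


def closed_form_waveform(params: SynapseParams, t, t_pre: float = 0.0):
    """Un-normalised gating waveform s(t) for a single presynaptic spike.

    Dual exponential (or plain decay for ``single_exp``), zero before
    ``t_pre``.  Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    dt = t - t_pre
    gate = (dt >= 0).astype(float)
    if params.kinetics == "single_exp":
        s = np.exp(-np.clip(dt, 0.0, None) / params.tau_decay_ms)
    else:
        dt_pos = np.clip(dt, 0.0, None)
        s = np.exp(-dt_pos / params.tau_decay_ms) - np.exp(-dt_pos / params.tau_rise_ms)
    out = gate * s
    return out if out.ndim else float(out)


def mg_sigma(mg: MgBlockParams, V):
    """Fraction of NMDA conductance not blocked by Mg²⁺ at voltage V (mV)."""
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + (mg.Mg_out_mM / mg.beta_mM) * np.exp(-mg.alpha_per_mV * (V - mg.gamma_mV)))
    return out if out.ndim else float(out)


def synaptic_current(params: SynapseParams, s_total, V):
    """Current (pA) produced by summed gating ``s_total`` at voltage ``V``.

    I = −ḡ·f_syn·s_total·(V−E)·σ(V); depolarising while V < E_syn.  σ(V)
    applies to NMDA only.
    """
    sigma = mg_sigma(params.mg, V) if params.kind == "NMDA" else 1.0
    return -params.gbar_nS * params.f_norm * np.asarray(s_total) * (
        np.asarray(V) - params.E_syn_mV
    ) * sigma
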