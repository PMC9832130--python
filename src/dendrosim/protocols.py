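"""Electrophysiology protocols: the measurements used to validate a model.

Each protocol builds stimuli, runs the engine and reduces the traces to the
quantities an experimentalist would report: input resistance and membrane
time constant from a small hyperpolarising step, sag ratio, F–I curve,
rheobase by bisection, steady-state and EPSP attenuation profiles,
expected-vs-actual synaptic input–output curves, peak dV/dt, and the
spatial profile of backpropagating spikes.  A passive-calibration routine
implements the joint C_m/g_L scaling used to bring a reduced morphology to
a target input resistance without disturbing the membrane time constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphology import NeuronModel
from .engine import (
    IntegratorSpec,
    StepCurrent,
    SynapticDrive,
    run,
    synchronous_train,
)

__all__ = [
    "PassivePropsResult",
    "IOCurve",
    "RheobaseResult",
    "passive_properties",
    "fi_curve",
    "find_rheobase",
    "attenuation_profiles",
    "expected_vs_actual",
    "peak_dvdt",
    "bpap_profile",
    "calibrate_passive",
    "ProtocolError",
]

_DEFAULT_INT = IntegratorSpec("euler", 0.1)


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class PassivePropsResult:
    R_input_MOhm: float
    tau_m_ms: float
    sag_ratio: float
    baseline_V_mV: float


@dataclass(frozen=True)
class IOCurve:
    n_synapses: tuple
    expected_mV: tuple
    actual_mV: tuple
    mode: str                   # "supralinear" | "sublinear" | "linear"
    margin: float = 0.05

    def ratio(self) -> np.ndarray:
        return np.asarray(self.actual_mV) / np.asarray(self.expected_mV)


@dataclass(frozen=True)
class RheobaseResult:
    compartment: str
    pulse_duration_ms: float
    rheobase_pA: float
    resolution_pA: float
    event: str


def passive_properties(
    model: NeuronModel,
    I_test_pA: float = -10.0,
    duration_ms: float = 1000.0,
    baseline_ms: float = 200.0,
    integrator: IntegratorSpec = _DEFAULT_INT,
    compartment: str | None = None,
) -> PassivePropsResult:
    """Input resistance, membrane time constant and sag from a current step.

    A ``duration_ms`` square pulse of ``I_test_pA`` is injected at the soma
    (or ``compartment``); R_input = |ΔV_ss / I|, τ_m from a log-linear
    single-exponential fit to the final 63% of the charging transient, and
    sag ratio = (V_base − V_ss)/(V_base − V_extreme) (1 when there is no
    sag mechanism).
    """
    target = compartment or model.names[model.soma_index]
    res = run(
        model,
        [StepCurrent(target, I_test_pA, onset_ms=baseline_ms, duration_ms=duration_ms)],
        baseline_ms + duration_ms + 100.0,
        integrator,
    )
    t = res.t_ms
    v = res.V(target)
    pre = t < baseline_ms
    base = float(v[pre][-1])
    in_pulse = (t >= baseline_ms) & (t < baseline_ms + duration_ms)
    tail = (t >= baseline_ms + 0.8 * duration_ms) & in_pulse
    v_ss = float(v[tail].mean())
    dV = v_ss - base
    if abs(dV) < 1e-12:
        raise ProtocolError("no measurable steady-state response; increase I_test")
    R_MOhm = abs(dV / I_test_pA) * 1e3      # mV/pA = GΩ → MΩ

    # τ_m: log-linear fit to the final-63% approach of the transient
    tp = t[in_pulse] - baseline_ms
    vp = v[in_pulse]
    resid = (vp - v_ss) / (base - v_ss)       # 1 → 0
    window = (resid > 0.02) & (resid < 0.63)
    if window.sum() < 4:
        window = (resid > 0.01) & (resid < 0.95)
    if window.sum() < 4:
        raise ProtocolError(
            f"charging-transient fit failed: only {int(window.sum())} usable samples; "
            f"residual range [{resid.min():.3g}, {resid.max():.3g}]"
        )
    slope, _ = np.polyfit(tp[window], np.log(resid[window]), 1)
    if slope >= 0:
        raise ProtocolError("charging-transient fit failed: non-decaying residual")
    tau = -1.0 / slope

    extreme = float(vp.min() if dV < 0 else vp.max())
    denom = base - extreme
    sag = (base - v_ss) / denom if abs(denom) > 1e-12 else 1.0
    return PassivePropsResult(R_MOhm, tau, float(np.clip(sag, 0.0, 1.0)), base)


def fi_curve(
    model: NeuronModel,
    currents_pA,
    duration_ms: float = 1000.0,
    integrator: IntegratorSpec = _DEFAULT_INT,
) -> np.ndarray:
    """Somatic firing rate (Hz) for each current amplitude (1000 ms steps)."""
    rates = []
    for I in currents_pA:
        res = run(model, [StepCurrent(model.names[model.soma_index], I, 0.0, duration_ms)],
                  duration_ms, integrator, record_stride=None)
        rates.append(res.soma_spike_count[0] / (duration_ms * 1e-3))
    return np.asarray(rates)


def _elicits(model, compartment, amp, pulse_ms, event, integrator) -> bool:
    res = run(model, [StepCurrent(compartment, amp, 5.0, pulse_ms)],
              pulse_ms + 60.0, integrator, record_stride=None)
    if event == "soma_spike":
        return res.soma_spike_count[0] > 0
    ci = model.index[compartment]
    return res.na_count[0, ci] > 0


def find_rheobase(
    model: NeuronModel,
    compartment: str,
    pulse_duration_ms: float = 5.0,
    event: str = "dspike",
    resolution_pA: float = 1.0,
    upper_pA: float = 2000.0,
    integrator: IntegratorSpec = _DEFAULT_INT,
) -> RheobaseResult:
    """Smallest pulse amplitude (to ``resolution_pA``) eliciting the event.

    Bisection on [0, upper]; assumes the response is monotone in amplitude.
    On return the bracket invariant holds: the event fires at the reported
    rheobase but not at rheobase − resolution.
    """
    ev = "soma_spike" if event == "soma_spike" else "dspike"
    if not _elicits(model, compartment, upper_pA, pulse_duration_ms, ev, integrator):
        raise ProtocolError(
            f"event {ev!r} not elicited in {compartment!r} at the upper search "
            f"bound {upper_pA} pA"
        )
    lo, hi = 0.0, upper_pA
    while hi - lo > resolution_pA:
        mid = 0.5 * (lo + hi)
        if _elicits(model, compartment, mid, pulse_duration_ms, ev, integrator):
            hi = mid
        else:
            lo = mid
    return RheobaseResult(compartment, pulse_duration_ms, hi, resolution_pA, ev)


def attenuation_profiles(
    model: NeuronModel,
    mode: str = "steady_state_out",
    I_soma_pA: float = -10.0,
    integrator: IntegratorSpec = _DEFAULT_INT,
) -> dict[str, float]:
    """Voltage-attenuation ratio per compartment.

    ``steady_state_out``: long somatic pulse; ratio of dendritic to somatic
    steady-state deflection (dV_dend/dV_soma).  ``epsp_in``: one unitary
    synapse per location (the compartment's first declared synapse set);
    ratio of somatic to local peak deflection (dV_soma/dV_dend).
    """
    soma = model.names[model.soma_index]
    if mode == "steady_state_out":
        res = run(model, [StepCurrent(soma, I_soma_pA, 100.0, 1000.0)], 1200.0, integrator)
        t = res.t_ms
        base_idx = t < 100.0
        ss_idx = (t >= 900.0) & (t < 1100.0)
        d_soma = res.V(soma)[ss_idx].mean() - res.V(soma)[base_idx][-1]
        out = {}
        for name in model.names:
            d = res.V(name)[ss_idx].mean() - res.V(name)[base_idx][-1]
            out[name] = float(d / d_soma)
        return out
    if mode != "epsp_in":
        raise ProtocolError(f"unknown attenuation mode {mode!r}")
    out = {soma: 1.0}
    for name in model.names:
        comp = model.compartment(name)
        if name == soma or not comp.synapses:
            continue
        drive = SynapticDrive(name, tuple(comp.synapses), 1, spike_times=((50.0,),))
        res = run(model, [drive], 200.0, integrator)
        t = res.t_ms
        base = t < 50.0
        peak_d = (res.V(name) - res.V(name)[base][-1]).max()
        peak_s = (res.V(soma) - res.V(soma)[base][-1]).max()
        out[name] = float(peak_s / peak_d)
    return out


def _peak_response(model, compartment, n_syn, receptors, record_at, isi_ms,
                   integrator, onset=50.0, window_ms=50.0, dspikes=None):
    times = tuple((float(tt),) for tt in synchronous_train(n_syn, isi_ms, onset))
    drive = SynapticDrive(compartment, receptors, n_syn, spike_times=times)
    m = model
    res = run(m, [drive], onset + isi_ms * n_syn + window_ms + 50.0, integrator)
    t = res.t_ms
    v = res.V(record_at)
    base = v[t < onset][-1]
    sel = (t >= onset) & (t <= onset + isi_ms * n_syn + window_ms)
    return float(v[sel].max() - base), res


def expected_vs_actual(
    model: NeuronModel,
    compartment: str,
    n_range=range(1, 31),
    isi_ms: float = 0.1,
    record_at: str | None = None,
    receptors: tuple | None = None,
    margin: float = 0.05,
    integrator: IntegratorSpec = _DEFAULT_INT,
) -> IOCurve:
    """Synaptic input–output curve against the linear-summation prediction.

    ``n`` synapses on ``compartment`` are activated quasi-simultaneously
    (inter-spike interval ``isi_ms``); the peak depolarisation at
    ``record_at`` (default: the stimulated compartment) is compared with
    n × the unitary peak.  Classified supralinear if any actual/expected
    exceeds 1 + margin, sublinear if all fall below 1 − margin.
    """
    rec_at = record_at or compartment
    recs = receptors or tuple(model.compartment(compartment).synapses)
    if not recs:
        raise ProtocolError(f"compartment {compartment!r} declares no synapses")
    n_list = list(n_range)
    unitary, _ = _peak_response(model, compartment, 1, recs, rec_at, isi_ms, integrator)
    actual = []
    for nn in n_list:
        if nn == 1:
            actual.append(unitary)
            continue
        a, _ = _peak_response(model, compartment, nn, recs, rec_at, isi_ms, integrator)
        actual.append(a)
    expected = [nn * unitary for nn in n_list]
    # n = 1 equals the identity line by construction; classify over n > 1
    ratio = np.asarray(
        [a / e for nn, a, e in zip(n_list, actual, expected) if nn > 1]
    )
    if ratio.size == 0:
        ratio = np.asarray(actual) / np.asarray(expected)
    if np.any(ratio > 1 + margin):
        mode = "supralinear"
    elif np.all(ratio < 1 - margin):
        mode = "sublinear"
    else:
        mode = "linear"
    return IOCurve(tuple(n_list), tuple(expected), tuple(actual), mode, margin)


def peak_dvdt(t_ms: np.ndarray, v_mV: np.ndarray, window_ms: tuple | None = None) -> float:
    """Maximum first temporal derivative (mV/ms) of a uniformly sampled trace."""
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mV, dtype=float)
    if window_ms is not None:
        lo, hi = window_ms
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise ProtocolError(f"window {window_ms} outside trace range [{t[0]}, {t[-1]}]")
        sel = (t >= lo) & (t <= hi)
        t, v = t[sel], v[sel]
    return float(np.max(np.diff(v) / np.diff(t)))


def bpap_profile(
    model: NeuronModel,
    I_soma_pA: float,
    duration_ms: float = 500.0,
    min_spikelet_mV: float = 1.0,
    integrator: IntegratorSpec = _DEFAULT_INT,
) -> dict[str, str]:
    """Backpropagation classification per dendritic compartment.

    A somatic step is injected; a compartment is ``full_dspike`` if it
    fired at least one Na event, ``spikelet`` if it only showed
    passively-conducted deflections of at least ``min_spikelet_mV`` above
    its pre-stimulus baseline while the soma was spiking, else ``none``.
    """
    soma = model.names[model.soma_index]
    res = run(model, [StepCurrent(soma, I_soma_pA, 50.0, duration_ms)],
              duration_ms + 150.0, integrator)
    if res.soma_spike_count[0] == 0:
        raise ProtocolError(f"somatic step of {I_soma_pA} pA elicited no somatic spikes")
    t = res.t_ms
    out = {}
    for name in model.names:
        if name == soma:
            continue
        ci = model.index[name]
        if res.na_count[0, ci] > 0:
            out[name] = "full_dspike"
            continue
        v = res.V(name)
        base = v[t < 50.0][-1]
        depol = (v - base)[(t >= 50.0) & (t <= 50.0 + duration_ms + 20.0)].max()
        out[name] = "spikelet" if depol >= min_spikelet_mV else "none"
    return out


def calibrate_passive(
    model: NeuronModel,
    R_input_MOhm: float,
    tau_m_ms: float | None = None,
    rel_tol: float = 0.02,
    scale_bounds: tuple = (0.1, 10.0),
    integrator: IntegratorSpec = _DEFAULT_INT,
) -> tuple[NeuronModel, dict]:
    """Scale all membrane conductances/capacitances to a target R_input.

    If ``tau_m_ms`` is given, every compartment's g_L is first reset to
    C_m/τ_m (specific-capacitance and geometry untouched, so τ_m is set
    exactly).  Then all C_m and g_L are multiplied by one joint factor,
    found by bisection, until the measured input resistance lies within
    ``rel_tol`` of the target; the joint scaling leaves τ_m invariant.
    """
    m = model
    if tau_m_ms is not None:
        m = NeuronModel(
            spec=m.spec, names=m.names, index=m.index, kinds=m.kinds,
            C_m_pF=m.C_m_pF, g_L_nS=m.C_m_pF / tau_m_ms, EL_mV=m.EL_mV,
            coupling_nS=m.coupling_nS, soma_index=m.soma_index,
            parent=m.parent, dspikes_enabled=m.dspikes_enabled,
        )

    def measure(scale: float) -> float:
        return passive_properties(m.with_scaled_membrane(scale),
                                  integrator=integrator).R_input_MOhm

    from .engine import SimulationDiverged

    lo, hi = scale_bounds
    # very small membranes can be numerically unstable at the probe dt;
    # tighten the bound toward 1 until the probe integrates
    R_lo = None
    while R_lo is None:
        try:
            R_lo = measure(lo)
        except SimulationDiverged:
            lo *= 2.0
            if lo >= 1.0:
                raise
    R_hi = measure(hi)                        # R decreases as scale grows
    if not (R_hi <= R_input_MOhm <= R_lo):
        raise ProtocolError(
            f"target R_input {R_input_MOhm} MΩ unattainable within scale "
            f"bounds {scale_bounds}: achievable range [{R_hi:.1f}, {R_lo:.1f}] MΩ"
        )
    scale = 1.0
    for _ in range(60):
        scale = math.sqrt(lo * hi)
        R = measure(scale)
        if abs(R - R_input_MOhm) / R_input_MOhm <= rel_tol:
            break
        if R > R_input_MOhm:
            lo = scale
        else:
            hi = scale
    calibrated = m.with_scaled_membrane(scale)
    props = passive_properties(calibrated, integrator=integrator)
    return calibrated, {
        "scale_factor": scale,
        "R_input_MOhm": props.R_input_MOhm,
        "tau_m_ms": props.tau_m_ms,
    }
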