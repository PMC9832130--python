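"""Time-stepped simulation of reduced compartmental neurons.

The engine advances all continuous state (voltages, adaptation and dSpike
conductances, synaptic gating variables) with an explicit integrator and
applies the discrete event rules on the integration grid.  Per step, in a
fixed order:

1. delayed events that fall due — somatic voltage reset, K_dr conductance
   onset;
2. instantaneous triggers evaluated on the current state — somatic
   threshold (two-stage reset), dendritic Na⁺ threshold;
3. presynaptic spikes scheduled in ``[t, t+dt)`` are delivered to their
   gating variables;
4. one explicit integration step (Euler / midpoint / classical RK4), with
   axial and synaptic currents re-evaluated inside each stage;
5. recording.

Event delays (somatic ``reset_delay``, K_dr ``t_offset``, Na refractory)
are handled in integer step arithmetic: a delay ``d`` with a strict
"t > t₀ + d" rule fires at the first grid point strictly after ``t₀ + d``;
the somatic reset ("at t₀ + d") is rounded up to the grid.

Many neurons sharing one model run as a single batch: state arrays have
shape ``(n_neurons, n_compartments)`` and stochastic stimuli draw
independent realisations per neuron.  Each stochastic stimulus owns an RNG
stream derived from ``(master seed, stimulus index)``, so adding a stimulus
never perturbs the realisations of the others.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .morphology import ModelValidationError, NeuronModel
from .dynamics import DSpikeParams, SomaParams
from .synapses import SynapseParams, mg_sigma

__all__ = [
    "IntegratorSpec",
    "StepCurrent",
    "NoiseCurrent",
    "SynapticDrive",
    "SimulationResult",
    "SimulationDiverged",
    "run",
    "set_dspikes",
    "poisson_train",
    "synchronous_train",
]


class SimulationDiverged(RuntimeError):
    """A state variable became NaN/Inf during integration."""


@dataclass(frozen=True)
class IntegratorSpec:
    method: str = "euler"        # "euler" | "rk2" | "rk4"
    dt_ms: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("euler", "rk2", "rk4"):
            raise ModelValidationError(f"unknown integration method {self.method!r}")
        if self.dt_ms <= 0:
            raise ModelValidationError("dt must be positive")
        if self.dt_ms > 0.1:
            warnings.warn(
                f"dt = {self.dt_ms} ms is coarser than the validated regime (dt <= 0.1 ms)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StepCurrent:
    """Square current pulse injected into one compartment."""

    target: str
    amplitude_pA: float
    onset_ms: float = 0.0
    duration_ms: float = math.inf


@dataclass(frozen=True)
class NoiseCurrent:
    """Gaussian noise current: an i.i.d. normal sample per step per neuron.

    The per-step standard deviation is ``sigma_pA`` at the run's dt (the
    sequence is white on the integration grid); mean and sigma are not
    rescaled with dt.
    """

    target: str
    mean_pA: float
    sigma_pA: float
    onset_ms: float = 0.0
    duration_ms: float = math.inf


@dataclass(frozen=True)
class SynapticDrive:
    """One presynaptic source driving one or more receptor types.

    ``receptors`` lists the synapse parameter sets (e.g. a compound
    AMPA+NMDA contact) that all see the same presynaptic spikes.  The
    source is either explicit spike times (``spike_times``: one sequence
    per instance, shared across neurons) or an independent homogeneous
    Poisson process per neuron (``rate_Hz``: scalar, or one rate per neuron
    for batched parameter sweeps).
    """

    target: str
    receptors: tuple              # tuple[SynapseParams, ...]
    n_instances: int = 1
    spike_times: Optional[tuple] = None   # tuple of per-instance time tuples
    rate_Hz: Union[None, float, np.ndarray] = None

    def __post_init__(self) -> None:
        if (self.spike_times is None) == (self.rate_Hz is None):
            raise ModelValidationError(
                "SynapticDrive needs exactly one of spike_times or rate_Hz"
            )
        if self.n_instances < 1:
            raise ModelValidationError("n_instances must be >= 1")
        if not self.receptors:
            raise ModelValidationError("SynapticDrive needs at least one receptor")


def poisson_train(rate_Hz: float, duration_ms: float, seed) -> np.ndarray:
    """Spike times (ms) of a homogeneous Poisson process on [0, duration).

    Sampled via exponential inter-arrival times; sorted by construction.
    """
    if rate_Hz < 0:
        raise ModelValidationError("rate must be >= 0")
    if rate_Hz == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    mean_isi_ms = 1000.0 / rate_Hz
    # draw in chunks until past duration
    times = []
    t = 0.0
    n_guess = max(16, int(2 * rate_Hz * duration_ms / 1000.0) + 16)
    while t < duration_ms:
        isis = rng.exponential(mean_isi_ms, size=n_guess)
        arr = t + np.cumsum(isis)
        times.append(arr)
        t = arr[-1]
    all_t = np.concatenate(times)
    return all_t[all_t < duration_ms]


def synchronous_train(n: int, isi_ms: float = 0.1, t0_ms: float = 0.0) -> np.ndarray:
    """Times of ``n`` quasi-simultaneous spikes: t0, t0+isi, …, t0+(n−1)·isi."""
    if n < 1:
        raise ModelValidationError("n must be >= 1")
    return t0_ms + isi_ms * np.arange(n)


def set_dspikes(model: NeuronModel, enabled: bool) -> NeuronModel:
    """Return a copy of the model with dendritic spiking globally on/off.

    When disabled, the Na/K_dr trigger rules never fire and the dSpike
    conductances remain identically zero; all passive, synaptic and somatic
    dynamics are unchanged.
    """
    return replace(model, dspikes_enabled=enabled)


# --------------------------------------------------------------------------
# internal compiled-model representation


class _ReceptorGroup:
    """Kinetic state of one receptor population (one drive × one kind)."""

    __slots__ = ("params", "target_idx", "s", "x", "dual", "tau_r", "tau_d",
                 "g_eff", "E", "is_nmda", "mg")

    def __init__(self, params: SynapseParams, target_idx: int, n: int, m: int):
        self.params = params
        self.target_idx = target_idx
        self.dual = params.kinetics == "dual_exp_ode"
        if params.kinetics == "closed_form":
            raise ModelValidationError(
                "closed_form kinetics are for offline waveform evaluation; "
                "use dual_exp_ode or single_exp in simulations"
            )
        self.s = np.zeros((n, m))
        self.x = np.zeros((n, m)) if self.dual else None
        self.tau_r = params.tau_rise_ms
        self.tau_d = params.tau_decay_ms
        self.g_eff = params.gbar_nS * params.f_norm
        self.E = params.E_syn_mV
        self.is_nmda = params.kind == "NMDA"
        self.mg = params.mg


class _Drive:
    __slots__ = ("groups", "schedule", "rate_per_step", "rng", "m")

    def __init__(self, groups, schedule, rate_per_step, rng, m):
        self.groups = groups          # list[_ReceptorGroup]
        self.schedule = schedule      # dict[int, np.ndarray counts (m,)] | None
        self.rate_per_step = rate_per_step  # (n,1) expected count per step | None
        self.rng = rng
        self.m = m


@dataclass
class SimulationResult:
    """Recorded traces, event logs and per-neuron spike statistics.

    ``traces['V']`` has shape (samples, n_neurons, n_compartments); event
    arrays hold (time_ms, neuron) or (time_ms, neuron, compartment) rows.
    """

    t_ms: np.ndarray
    dt_ms: float
    names: tuple
    traces: dict
    soma_spikes: np.ndarray        # (k, 2): time_ms, neuron
    na_events: np.ndarray          # (k, 3): time_ms, neuron, compartment idx
    kdr_events: np.ndarray
    soma_spike_count: np.ndarray   # (n,)
    na_count: np.ndarray           # (n, C)
    metadata: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.soma_spike_count)

    def V(self, compartment: str, neuron: int = 0) -> np.ndarray:
        idx = self.names.index(compartment)
        return self.traces["V"][:, neuron, idx]

    def soma_spike_times(self, neuron: int = 0) -> np.ndarray:
        ev = self.soma_spikes
        return ev[ev[:, 1] == neuron, 0] if len(ev) else np.empty(0)

    def events_dataframe(self):
        """Tidy event table: time_ms, compartment, event kind, neuron."""
        import pandas as pd

        rows = []
        soma_name = self.metadata.get("soma_name", "soma")
        for t, nrn in self.soma_spikes:
            rows.append((t, soma_name, "soma_spike", int(nrn)))
        for t, nrn, c in self.na_events:
            rows.append((t, self.names[int(c)], "dspike_na", int(nrn)))
        for t, nrn, c in self.kdr_events:
            rows.append((t, self.names[int(c)], "dspike_kdr", int(nrn)))
        df = pd.DataFrame(rows, columns=["time_ms", "compartment", "event", "neuron"])
        return df.sort_values(["time_ms", "neuron"], kind="stable").reset_index(drop=True)


def _delay_steps_strict(delay_ms: float, dt: float) -> int:
    """Steps after which 't > t0 + delay' first holds on the grid."""
    return int(math.floor(delay_ms / dt + 1e-9)) + 1

def _delay_steps_at(delay_ms: float, dt: float) -> int:
    """Steps after which 't = t0 + delay' holds, rounded up to the grid."""
    return max(1, int(math.ceil(delay_ms / dt - 1e-9)))


@np.errstate(over="ignore", invalid="ignore")  # divergence is detected explicitly
def run(
    model: NeuronModel,
    stimuli: Sequence,
    duration_ms: float,
    integrator: IntegratorSpec = IntegratorSpec(),
    n_neurons: int = 1,
    seed: int = 0,
    record_stride: Optional[int] = 1,
    record_vars: tuple = ("V",),
    initial_V_mV: Optional[float] = None,
    recurrent: Optional[tuple] = None,
) -> SimulationResult:
    """Simulate ``model`` under ``stimuli`` for ``duration_ms``.

    Runs ⌈duration/dt⌉ steps; with ``record_stride=None`` only event logs
    and spike counts are kept (the economical mode for neuron pools).
    Identical arguments (including ``seed``) produce bit-identical results.

    ``recurrent``, if given, is ``(adjacency, receptors, target)``: somatic
    spikes of step k are delivered at step k+1 as presynaptic spikes onto
    ``target`` of each postsynaptic neuron, multiplied through the (n, n)
    0/1 ``adjacency`` matrix (row = postsynaptic neuron).
    """
    if duration_ms <= 0:
        raise ModelValidationError("duration must be positive")
    dt = integrator.dt_ms
    n_steps = int(math.ceil(duration_ms / dt - 1e-9))
    n = int(n_neurons)
    C = model.n_compartments
    si = model.soma_index

    sp: SomaParams = model.spec.soma_params or SomaParams()
    dspikes_on = getattr(model, "dspikes_enabled", True)

    # --- per-compartment dSpike parameter arrays -------------------------
    has_d = np.zeros(C, dtype=bool)
    gbar_Na = np.zeros(C)
    gbar_Kdr = np.zeros(C)
    E_Na = np.zeros(C)
    E_K = np.zeros(C)
    inv_tau_Na = np.zeros(C)
    inv_tau_Kdr = np.zeros(C)
    V_th_d = np.full(C, np.inf)
    n_ref = np.zeros(C, dtype=int)
    n_off = np.zeros(C, dtype=int)
    for i, comp in enumerate(model.spec.compartments):
        dp: DSpikeParams | None = comp.dspike
        if dp is not None and dp.enabled and dspikes_on:
            has_d[i] = True
            gbar_Na[i] = dp.gbar_Na_nS
            gbar_Kdr[i] = dp.gbar_Kdr_nS
            E_Na[i] = dp.E_Na_mV
            E_K[i] = dp.E_K_mV
            inv_tau_Na[i] = 1.0 / dp.tau_Na_ms
            inv_tau_Kdr[i] = 1.0 / dp.tau_Kdr_ms
            V_th_d[i] = dp.V_th_d_mV
            n_ref[i] = _delay_steps_strict(dp.t_ref_Na_ms, dt)
            n_off[i] = _delay_steps_strict(dp.t_offset_Kdr_ms, dt)
            if dt > dp.t_offset_Kdr_ms / 2 or dt > sp.reset_delay_ms / 2:
                warnings.warn(
                    f"dt = {dt} ms is coarse relative to event delays in "
                    f"compartment {comp.name!r}; delays are rounded to the grid",
                    stacklevel=2,
                )
    any_d = bool(has_d.any())
    n_reset = _delay_steps_at(sp.reset_delay_ms, dt)

    # --- compile stimuli -------------------------------------------------
    currents = []   # (target_idx, kind, ...)
    drives: list[_Drive] = []
    for k, stim in enumerate(stimuli):
        stream = np.random.default_rng([int(seed) & 0x7FFFFFFF, k])
        if isinstance(stim, StepCurrent):
            ci = model.index[stim.target]
            s0 = int(math.floor(stim.onset_ms / dt + 1e-9))
            s1 = n_steps if math.isinf(stim.duration_ms) else int(
                math.floor((stim.onset_ms + stim.duration_ms) / dt + 1e-9))
            currents.append(("step", ci, stim.amplitude_pA, s0, s1, None))
        elif isinstance(stim, NoiseCurrent):
            ci = model.index[stim.target]
            s0 = int(math.floor(stim.onset_ms / dt + 1e-9))
            s1 = n_steps if math.isinf(stim.duration_ms) else int(
                math.floor((stim.onset_ms + stim.duration_ms) / dt + 1e-9))
            currents.append(("noise", ci, (stim.mean_pA, stim.sigma_pA), s0, s1, stream))
        elif isinstance(stim, SynapticDrive):
            ci = model.index[stim.target]
            m = stim.n_instances
            groups = [_ReceptorGroup(p, ci, n, m) for p in stim.receptors]
            if stim.spike_times is not None:
                times = stim.spike_times
                if len(times) and np.isscalar(times[0]):
                    times = (tuple(times),) * m if m > 1 else (tuple(times),)
                if len(times) != m:
                    raise ModelValidationError(
                        "spike_times must give one sequence per instance"
                    )
                schedule: dict[int, np.ndarray] = {}
                for j, seq in enumerate(times):
                    for tpre in seq:
                        step = int(math.floor(tpre / dt + 1e-9))   # binned to grid
                        if 0 <= step < n_steps:
                            schedule.setdefault(step, np.zeros(m))[j] += 1.0
                drives.append(_Drive(groups, schedule, None, None, m))
            else:
                rate = np.asarray(stim.rate_Hz, dtype=float)
                if rate.ndim == 0:
                    rate = np.full(n, float(rate))
                if rate.shape != (n,):
                    raise ModelValidationError(
                        f"per-neuron rate array must have shape ({n},)"
                    )
                lam = (rate * dt * 1e-3)[:, None]   # expected count per step
                drives.append(_Drive(groups, None, lam, stream, m))
        else:
            raise ModelValidationError(f"unknown stimulus type {type(stim).__name__}")

    # --- state -----------------------------------------------------------
    V = np.tile(model.EL_mV if initial_V_mV is None else np.full(C, initial_V_mV), (n, 1))
    g_A = np.zeros(n)
    g_Na = np.zeros((n, C))
    g_Kdr = np.zeros((n, C))
    f_Na = np.ones((n, C), dtype=bool)      # armed
    f_Kdr = np.zeros((n, C), dtype=bool)    # Na fired, K pending
    last_d = np.full((n, C), -(10**9), dtype=np.int64)
    last_s = np.full(n, -(10**9), dtype=np.int64)
    plateau = np.zeros(n, dtype=bool)

    W = model.coupling_nS
    deg = W.sum(axis=0)
    C_m, g_L, EL = model.C_m_pF, model.g_L_nS, model.EL_mV
    gbarA, tauA, E_A, V_A = sp.gbar_A_nS, sp.tau_A_ms, sp.E_A_mV, sp.V_A_mV

    rec_A = None
    if recurrent is not None:
        rec_A, rec_receptors, rec_target = recurrent
        rec_A = np.asarray(rec_A, dtype=float)
        if rec_A.shape != (n, n):
            raise ModelValidationError("recurrent adjacency must be (n_neurons, n_neurons)")
        rci = model.index[rec_target]
        rec_groups = [_ReceptorGroup(p, rci, n, 1) for p in rec_receptors]
        drives.append(_Drive(rec_groups, {}, None, None, 1))
        prev_spikes = np.zeros(n)

    all_groups = [g for d in drives for g in d.groups]

    def rhs(Vv, gAv, gNav, gKv, s_list, x_list, I_ext):
        I_tot = Vv @ W - Vv * deg          # axial
        if I_ext is not None:
            I_tot = I_tot + I_ext
        for g, s in zip(all_groups, s_list):
            vt = Vv[:, g.target_idx]
            stot = s.sum(axis=1)
            sigma = mg_sigma(g.mg, vt) if g.is_nmda else 1.0
            I_tot[:, g.target_idx] += -g.g_eff * stot * (vt - g.E) * sigma
        if any_d:
            I_tot = I_tot + (-gNav * (Vv - E_Na) - gKv * (Vv - E_K))
        dV = (-g_L * (Vv - EL) + I_tot) / C_m
        dV[:, si] += (-gAv * (Vv[:, si] - E_A)) / C_m[si]
        dgA = (gbarA * np.abs(Vv[:, si] - V_A) - gAv) / tauA
        dgNa = -gNav * inv_tau_Na
        dgK = -gKv * inv_tau_Kdr
        ds_list, dx_list = [], []
        for g, s, x in zip(all_groups, s_list, x_list):
            if g.dual:
                ds_list.append(-s / g.tau_d + x * (1.0 - s) / g.tau_r)
                dx_list.append(-x / g.tau_r)
            else:
                ds_list.append(-s / g.tau_d)
                dx_list.append(None)
        return dV, dgA, dgNa, dgK, ds_list, dx_list

    # --- recording -------------------------------------------------------
    rec = record_stride is not None
    traces: dict[str, list] = {v: [] for v in record_vars} if rec else {}
    samp_t: list[float] = []

    def snapshot(t):
        samp_t.append(t)
        if "V" in traces:
            traces["V"].append(V.copy())
        if "g_A" in traces:
            traces["g_A"].append(g_A.copy())
        if "g_Na" in traces:
            traces["g_Na"].append(g_Na.copy())
        if "g_Kdr" in traces:
            traces["g_Kdr"].append(g_Kdr.copy())
        if "s" in traces:
            traces["s"].append([g.s.copy() for g in all_groups])

    soma_ev: list[np.ndarray] = []
    na_ev: list[np.ndarray] = []
    kdr_ev: list[np.ndarray] = []
    spike_count = np.zeros(n, dtype=np.int64)
    na_count = np.zeros((n, C), dtype=np.int64)

    if rec:
        snapshot(0.0)

    method = integrator.method
    for step in range(n_steps):
        t = step * dt

        # (1) due delayed events ------------------------------------------
        due = plateau & (step >= last_s + n_reset)
        if due.any():
            V[due, si] = sp.V_reset
            plateau[due] = False
        if any_d:
            kdue = f_Kdr & (step >= last_d + n_off)
            if kdue.any():
                g_Kdr[kdue] += np.broadcast_to(gbar_Kdr, (n, C))[kdue]
                f_Na[kdue] = True
                f_Kdr[kdue] = False
                rows, cols = np.nonzero(kdue)
                kdr_ev.append(np.column_stack([np.full(rows.size, t), rows, cols]))

        # (2) instantaneous triggers --------------------------------------
        if any_d:
            trig = f_Na & (V > V_th_d) & (step >= last_d + n_ref)
            if trig.any():
                g_Na[trig] += np.broadcast_to(gbar_Na, (n, C))[trig]
                f_Na[trig] = False
                f_Kdr[trig] = True
                last_d[trig] = step
                rows, cols = np.nonzero(trig)
                na_ev.append(np.column_stack([np.full(rows.size, t), rows, cols]))
                np.add.at(na_count, (rows, cols), 1)
        strig = (~plateau) & (V[:, si] > sp.V_th)
        if strig.any():
            V[strig, si] = sp.V_spike
            g_A[strig] += sp.b_nS
            last_s[strig] = step
            plateau[strig] = True
            spike_count[strig] += 1
            rows = np.nonzero(strig)[0]
            soma_ev.append(np.column_stack([np.full(rows.size, t), rows]))

        # (3) presynaptic spike delivery ----------------------------------
        if rec_A is not None:
            if prev_spikes.any():
                counts = (rec_A @ prev_spikes)[:, None]
                for g in rec_groups:
                    if g.dual:
                        g.x += counts
                    else:
                        g.s += counts
            prev_spikes = strig.astype(float)
        for d in drives:
            if d.schedule is not None:
                counts = d.schedule.get(step)
                if counts is not None:
                    for g in d.groups:
                        if g.dual:
                            g.x += counts
                        else:
                            g.s += counts
            else:
                counts = d.rng.poisson(d.rate_per_step, size=(n, d.m))
                if counts.any():
                    counts = counts.astype(float)
                    for g in d.groups:
                        if g.dual:
                            g.x += counts
                        else:
                            g.s += counts

        # external currents (held constant across stages of this step)
        I_ext = None
        for kind, ci, payload, s0, s1, stream in currents:
            if s0 <= step < s1:
                if I_ext is None:
                    I_ext = np.zeros((n, C))
                if kind == "step":
                    I_ext[:, ci] += payload
                else:
                    mean, sigma = payload
                    I_ext[:, ci] += stream.normal(mean, sigma, size=n)

        # (4) integrate -----------------------------------------------------
        s_list = [g.s for g in all_groups]
        x_list = [g.x for g in all_groups]
        if method == "euler":
            dV, dgA, dgNa, dgK, ds_l, dx_l = rhs(V, g_A, g_Na, g_Kdr, s_list, x_list, I_ext)
            V += dt * dV
            g_A += dt * dgA
            if any_d:
                g_Na += dt * dgNa
                g_Kdr += dt * dgK
            for g, ds, dx in zip(all_groups, ds_l, dx_l):
                g.s += dt * ds
                if g.dual:
                    g.x += dt * dx
        else:
            y0 = (V, g_A, g_Na, g_Kdr, s_list, x_list)
            ks = []
            if method == "rk2":
                coefs = [(0.5, None)]
                weights = [0.0, 1.0]
            else:  # rk4
                coefs = [(0.5, None), (0.5, None), (1.0, None)]
                weights = [1 / 6, 1 / 3, 1 / 3, 1 / 6]
            k = rhs(*y0, I_ext)
            ks.append(k)
            for c, _ in coefs:
                Vs = V + c * dt * k[0]
                gAs = g_A + c * dt * k[1]
                gNas = g_Na + c * dt * k[2]
                gKs = g_Kdr + c * dt * k[3]
                ss = [s + c * dt * d for s, d in zip(s_list, k[4])]
                xs = [x if d is None else x + c * dt * d for x, d in zip(x_list, k[5])]
                k = rhs(Vs, gAs, gNas, gKs, ss, xs, I_ext)
                ks.append(k)
            V += dt * sum(w * kk[0] for w, kk in zip(weights, ks))
            g_A += dt * sum(w * kk[1] for w, kk in zip(weights, ks))
            if any_d:
                g_Na += dt * sum(w * kk[2] for w, kk in zip(weights, ks))
                g_Kdr += dt * sum(w * kk[3] for w, kk in zip(weights, ks))
            for j, g in enumerate(all_groups):
                g.s = g.s + dt * sum(w * kk[4][j] for w, kk in zip(weights, ks))
                if g.dual:
                    g.x = g.x + dt * sum(w * kk[5][j] for w, kk in zip(weights, ks))

        if not np.isfinite(V.sum()):
            bad = np.argwhere(~np.isfinite(V))
            nrn, ci = bad[0]
            raise SimulationDiverged(
                f"non-finite voltage in compartment {model.names[ci]!r} "
                f"(neuron {nrn}) at t = {(step + 1) * dt:.3f} ms"
            )

        # (5) record ---------------------------------------------------------
        if rec and (step + 1) % record_stride == 0:
            snapshot((step + 1) * dt)

    def _stack(evs, width):
        return np.concatenate(evs) if evs else np.empty((0, width))

    out_traces = {}
    if rec:
        for key, frames in traces.items():
            if key == "s":
                out_traces["s"] = [
                    np.stack([fr[j] for fr in frames]) for j in range(len(all_groups))
                ]
            else:
                out_traces[key] = np.stack(frames)

    return SimulationResult(
        t_ms=np.asarray(samp_t),
        dt_ms=dt,
        names=model.names,
        traces=out_traces,
        soma_spikes=_stack(soma_ev, 2),
        na_events=_stack(na_ev, 3),
        kdr_events=_stack(kdr_ev, 3),
        soma_spike_count=spike_count,
        na_count=na_count,
        metadata={
            "duration_ms": duration_ms,
            "dt_ms": dt,
            "method": method,
            "seed": int(seed),
            "n_neurons": n,
            "soma_name": model.names[si],
            "dspikes_enabled": dspikes_on,
        },
    )
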