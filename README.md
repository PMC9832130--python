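# dendrosim

Reduced compartmental spiking neurons with event-driven dendritic spikes.

Point integrate-and-fire neurons ignore dendrites; morphologically detailed
biophysical models are too costly for network simulation.  `dendrosim`
implements the middle ground: neurons built from a few cylindrical
compartments — a leaky integrate-and-fire soma with conductance adaptation
and a two-stage spike reset, passive cable coupling, phenomenological
event-driven dendritic Na⁺/K_dr spikes, and conductance-based
AMPA/NMDA/GABA synapses with magnesium block — together with the
electrophysiology protocols used to calibrate and validate such models and
pool/network experiments for studying dendritic contributions to circuit
function.  It is written for computational neuroscientists who want
dendritic nonlinearities in spiking-network models at a few state
variables per neuron.

## The model

A compartment of length ℓ and diameter d has area A = 2π(d/2)ℓ and absolute
membrane parameters C_m = c_m·A·s, g_L = (A/r_m)·s (s = spine-correction
factor).  Adjacent compartments couple through a conductance
g_c = 1/R_long, with R_long the axial resistance of the distal cylinder or,
by default, the half-cylinder (centre-to-centre) sum.  The soma obeys

    C_m dV/dt = −g_L(V−E_L) − g_A(V−E_A) + Σ I_axial + Σ I_syn + I_ext
    τ_A dg_A/dt = ḡ_A|V−V_A| − g_A

with threshold V_th, a spike plateau at V_spike, an adaptation increment b
per spike, and a delayed reset to V_reset.  Dendrites replace the
adaptation current with two event-driven conductances: when the local
voltage crosses V_th_d (armed, outside the refractory period t_ref_Na),
g_Na steps up by ḡ_Na and decays with τ_Na; after t_offset_Kdr the
delayed-rectifier g_Kdr steps up and repolarises the branch.  Synaptic
currents are −ḡ·f_syn·s(t)·(V−E_syn)·σ(V) with dual-exponential or
single-exponential kinetics, peak-normalised by f_syn, and the standard
sigmoidal Mg²⁺ unblock σ(V) on NMDA.  See `docs/methods.md` for the full
description, numerical scheme and design decisions.

## A worked example

```bash
python examples/02_dendritic_spikes.py
```

prints, for the four-compartment active reference neuron:

```
dSpike rheobase (5 ms pulses):
  trunk       172.9 pA
  proximal    193.4 pA
  distal       38.1 pA
The thin sealed distal branch has the highest input resistance and
therefore the lowest threshold current.

distal input-output mode, dSpikes ON : supralinear
distal input-output mode, dSpikes OFF: sublinear
supralinear jump above ~2 quasi-simultaneous synapses

backpropagation of somatic spikes (135 pA / 300 ms):
  trunk     full_dspike
  proximal  full_dspike
  distal    spikelet
Full dSpikes invade the proximal segments; in the weakly coupled
distal branch they appear only as subthreshold spikelets.
```

The rheobase ordering follows local input resistance; quasi-simultaneous
synaptic input integrates supralinearly only while the dendritic spike
mechanism is available; and backpropagating spikes invade proximal
dendrites fully but reach the thin distal branch only as small spikelets.

The other examples build a passive neuron and measure R_input/τ_m/
attenuation (`01`), run the CA1 pathway coincidence-detection experiment
(`03`), and round-trip a model through its JSON document form (`04`).
A thin CLI wraps the same functionality
(`dendrosim fixtures generate`, `dendrosim protocol passive --model m.json`,
`dendrosim pathway-demo`, `dendrosim benchmark`).

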