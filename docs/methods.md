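# Methods

`dendrosim` simulates neurons reduced to a handful of cylindrical
compartments, each a single isopotential RC node, connected by constant
axial (coupling) conductances.  The design goal is the middle ground
between point integrate-and-fire neurons and morphologically detailed
biophysical models: few state variables per neuron, explicit fixed-step
integration, but with the dendritic phenomena that shape input integration
— local regenerative spikes, NMDA voltage dependence, location-dependent
attenuation — retained in phenomenological form.

## Model equations

**Passive structure.**  A compartment with length ℓ and diameter d (µm)
has open-cylinder area A = 2π(d/2)ℓ.  Specific constants (c_m in µF·cm⁻²,
r_m in kΩ·cm², r_a in Ω·cm) give absolute values C_m = c_m·A·s and
g_L = (A/r_m)·s, where the spine factor s (default 1.5 for dendrites, 1
for the soma) compensates for membrane area in spines that are not
modelled; it scales C_m and g_L together, so the membrane time constant
τ_m = c_m·r_m is unaffected.  Adjacent compartments i, k are coupled by a
conductance computed either from the distal compartment's whole-cylinder
axial resistance R = r_a·ℓ/(π(d/2)²) ("full cylinder", appropriate when a
few large compartments hug the soma) or, by default, from the
centre-to-centre resistance ½(Rᵢ + Rₖ) ("half cylinder").  Explicit
per-edge overrides are supported because reduced morphologies often need
small manual corrections to reproduce realistic attenuation.  The axial
current into compartment k is Σᵢ g_c(i,k)(Vᵢ − Vₖ): the diffusive
orientation, under which coupled compartments relax toward each other.

**Soma.**  A leaky integrate-and-fire unit with a conductance-based
adaptation variable:

    C_m dV/dt = −g_L(V−E_L) − g_A(V−E_A) + I_axial + I_syn + I_ext
    τ_A dg_A/dt = ḡ_A·|V−V_A| − g_A

with a two-stage reset: when V exceeds V_th, V jumps to V_spike (a
stylised action-potential peak that drives realistic depolarization into
the dendrites), g_A increments by b, and after `reset_delay` (0.5 ms) V is
set to V_reset.  Threshold detection is suppressed during the plateau —
V_spike > V_th would otherwise retrigger every step.  V_A is the reference
voltage of the subthreshold adaptation drive and is an independent
parameter from the reversal potential E_A; reference models set V_A = E_L.

**Dendritic spikes.**  Each dendritic compartment may carry two
conductances g_Na and g_Kdr that decay exponentially (τ_Na, τ_Kdr) and
enter the membrane equation as −g(V−E).  Two Boolean flags implement an
event-driven state machine: when V crosses V_th_d while the mechanism is
armed and outside the Na⁺ refractory period t_ref_Na, g_Na increments by
ḡ_Na (the rising phase); after t_offset_Kdr the delayed-rectifier
conductance increments by ḡ_Kdr and the mechanism re-arms (the falling
phase).  The constraint t_offset_Kdr < t_ref_Na is enforced so the state
machine always re-arms.  The decay acts on the conductances; under voltage
clamp this is indistinguishable from decaying currents, while with free
voltage the current additionally follows the driving force — the
physically sensible phenomenological reading.  Disabling the mechanism
(`set_dspikes`) gates the trigger rules; conductances left over from
earlier events would simply decay (when disabled from the start the model
is bit-identical to a passive one).

**Synapses.**  I_syn = −ḡ·f_syn·s(t)·(V−E_syn)·σ(V).  The gating s is
driven by presynaptic spikes in one of three kinetic modes: the explicit
dual-exponential waveform; the equivalent two-variable ODE
ds/dt = −s/τ_decay + x(1−s)/τ_rise, dx/dt = −x/τ_rise with x→x+1 per spike
(default; the saturation term keeps s ∈ [0,1]); or plain exponential
decay with s→s+1 per spike.  f_syn = 1/s(t_peak) with
t_peak = τ_d·τ_r/(τ_d−τ_r)·ln(τ_d/τ_r) normalises the peak so ḡ is a peak
conductance (f_syn = 1 in single-exponential mode).  The closed-form
normaliser is applied in ODE mode as well; the saturating ODE peak is
slightly below the closed-form peak for strong inputs, so ḡ is then an
upper bound on the realised peak conductance.  σ(V) is the sigmoidal
magnesium-unblock factor 1/(1 + ([Mg²⁺]ₒ/β)·e^{−α(V−γ)}), applied to NMDA
only (α = 0.062 mV⁻¹, β = 3.57 mM, γ = 0, [Mg²⁺]ₒ = 1 mM by default);
AMPA and GABA are voltage-independent.  The equal-τ (alpha-function)
limit is rejected rather than special-cased.  τ_rise = τ_decay is out of
scope.

## Numerical scheme

Internal units are mV, ms, nS, pF, pA — an algebraically closed system
(nS·mV = pA, pA/pF = mV/ms) that keeps state values near unity; files and
reports use the same conventional units.  All continuous state is advanced
with explicit fixed-step integrators (forward Euler by default, midpoint
and classical Runge–Kutta available), dt = 0.1 ms by default; a warning is
issued above that.  Per step, in fixed order: (1) delayed events falling
due (somatic reset, K_dr onset); (2) instantaneous threshold triggers
evaluated on the current state; (3) presynaptic spike delivery (spike
times binned to the grid by floor, so 0.1 ms inter-spike intervals land on
consecutive steps at dt = 0.1 ms); (4) one integration step, with axial
and synaptic currents re-evaluated inside each stage; (5) recording.
Event delays use integer step arithmetic: strict "t > t₀+d" rules fire at
the first grid point strictly after t₀+d; the somatic reset is rounded up
to the grid.  Threshold comparisons are strict (>).  Non-finite state
aborts the run naming the compartment and time.  Stability note: explicit
integration requires peak conductance-to-capacitance ratios below ~2/dt
per compartment; the reference models keep dendritic spike conductance
densities (5 mS·cm⁻²) inside that envelope at dt = 0.1 ms.

Batches of neurons sharing one model are simulated as (n_neurons ×
n_compartments) arrays.  Every stochastic stimulus owns an RNG stream
seeded by (master seed, stimulus index), so results are bit-reproducible
and adding a stimulus never perturbs the others.  Pool Poisson input is
drawn as per-step Poisson counts, distributionally identical to binning a
homogeneous Poisson process onto the grid; the standalone `poisson_train`
generator samples exponential inter-arrival times.

## Protocols

`passive_properties` injects a −10 pA, 1000 ms pulse: R_input = |ΔV_ss/I|;
τ_m from a log-linear single-exponential fit restricted to the final 63%
of the charging transient (the early multi-exponential phase of coupled
compartments is excluded); sag ratio = (V_base−V_ss)/(V_base−V_min),
which is 1 without a sag mechanism — the protocol exists for completeness
but no reference model claims realistic sag, as none carries an
h-type current.  `find_rheobase` bisects the 5 ms pulse amplitude on
[0, 2000] pA to 1 pA resolution assuming monotone recruitment, and
guarantees on return that the event fires at the reported amplitude and
not one resolution below.  `expected_vs_actual` activates n synapse
instances quasi-simultaneously (0.1 ms intervals) and compares peak
depolarization (relative to the pre-stimulus baseline, maximum over the
stimulus window plus 50 ms) with n × the unitary peak; classification uses
a 5% margin around the identity line, evaluated over n > 1 (the n = 1
point is the identity by construction).  `bpap_profile` classifies each
dendrite after a somatic step as full dSpike (a local Na event fired),
spikelet (passively conducted deflection ≥ 1 mV during somatic spiking),
or none.  `calibrate_passive` first sets g_L = C_m/τ_m per compartment
(fixing τ_m exactly), then bisects one joint scale factor on all C_m and
g_L (bounds [0.1, 10]) until measured R_input is within 2% of target —
the joint scaling leaves τ_m invariant, so the two targets decouple.

## Reference models

Three fixtures, all calibrated with the package's own protocols; their
parameters are this package's calibration products, not published values.

*Passive two-dendrite neuron* (`model_a`): soma (25×25 µm) with basal
(150 µm) and apical (250 µm) dendrites, c_m = 1 µF·cm⁻², r_m = 20 kΩ·cm²,
r_a = 150 Ω·cm, jointly scaled to R_input = 120 MΩ at τ_m = 20 ms.  The
apical dendrite carries AMPA (ḡ = 1.2 nS, τ 0.2/2 ms) and NMDA (2.0 nS,
τ 2/50 ms) synapses; NMDA unblock at depolarized dendritic voltages makes
apical input–output supralinear, and removing the NMDA component switches
it to sublinear through driving-force saturation.

*Active apical chain* (`model_b`): soma–trunk–proximal–distal with
diameters 1.0/2.0/0.4 µm chosen so local input resistance, and hence
dSpike rheobase, orders distal < trunk < proximal (the thin sealed distal
branch is the most excitable; the thick proximal segment the least).  All
dendrites carry the spike mechanism at 5 mS·cm⁻² Na⁺ density (K/Na = 1),
thresholds −35 mV (distal −25 mV), and the proximal–distal coupling is
manually reduced to 0.4 nS so that backpropagating spikes reach the distal
branch only as subthreshold spikelets while proximal segments spike fully.

*CA1-like nine-compartment cell* (`model_c`): soma, 2 basal dendrites,
proximal and distal apical trunk (ending 250 µm from the soma), 2 radial
obliques, 2 distal tuft branches, calibrated to R_input = 120 MΩ,
τ_m = 28 ms.  The soma uses V_th = −50 mV, V_spike = +20 mV,
V_reset = −65 mV and strong spike-triggered adaptation (b = 6 nS,
τ_A = 300 ms); these active parameters were set so that a somatic spike's
plateau does not recycle enough charge through the apical trunk to
retrigger by itself, and a neuron whose drive barely crosses threshold
fires a single spike.  Dendritic thresholds: trunk −35/−43.5 mV
(proximal/distal), obliques −22 mV, tuft −30 mV, with K/Na = 0.4 so that
a dendritic spike is net-depolarizing downstream.  Entorhinal (EC) input
targets the tuft (AMPA 3.0 / NMDA 4.0 nS per stream), CA3 input the
obliques and distal trunk (AMPA 3.5 / NMDA 1.0 nS — AMPA-dominant, so the
proximal drive fluctuates rather than saturates); tuft and oblique
couplings are manually set (2.0 and 4.5 nS).  Each pathway stream is one
compound AMPA+NMDA contact per branch; the synapse sets declared on the
branches are these stream aggregates, and `unitary_contact()` provides the
small per-synapse quantum used by input–output protocols.

## The coincidence-detection experiment

A pool of N independent copies of the CA1 model receives 2 EC streams
(one per tuft branch) and 3 CA3 streams (obliques + distal trunk), each an
independent Poisson train per neuron.  `tune_rates` fixes the operating
point from three conditions evaluated on a 200-neuron subsample:

1. λ_EC is the smallest grid rate (5 Hz steps) whose EC-only response has
   distal-dSpike probability above 0.55 with zero somatic spikes.  The
   tuner requires the bound plus a 0.10 safety margin: the probability
   jumps by roughly 0.08 per grid step and varies between seed sets, so a
   smaller margin would not guarantee that held-out realisations clear the
   stated bound.
2. λ_CA3 is capped by the largest rate whose CA3-only response is free of
   dendritic and somatic spikes anywhere.
3. Within that cap, λ_CA3 is the grid rate whose *passive* coincident
   response (both pathways, dendritic spikes disabled) activates a
   fraction of the subsample closest to the 10% level — the operational
   definition of "moderate" CA3 drive, whose somatic effect beyond a small
   minority of neurons depends entirely on dendritic amplification.  A
   nearest-to-level rule is used rather than a hard bound because the
   passive fraction at adjacent grid rates differs by several points
   (well above subsample noise), whereas a bound placed near the level
   itself would flip between neighbouring rates from seed to seed.

With dendritic spikes enabled, tuft spikes inject charge into the distal
trunk, which the CA3 drive holds a few millivolts below its own threshold;
the resulting trunk spikes propagate through the proximal trunk and fire
the soma.  Disabling the mechanism removes that chain, leaving only the
passive summation tail.  The robustness grid scales both tuned rates over
50–150% in 10% steps (11×11 = 121 cells), runs each cell with the
mechanism on and off (every cell simulated in one batched pool with
per-neuron rates), and reports the percentage MFR decrease
100·(MFR_on−MFR_off)/MFR_on; cells with MFR_on < 0.1 Hz or < 5% active
neurons are excluded before the division.  MFR averages over all neurons
including silent ones, which is what makes the 5%-activity floor a
distinct criterion from the MFR floor.

Default problem sizes — 1,000 neurons for the pool conditions, 200 per
grid cell, 500 ms at dt = 0.1 ms — were chosen as the smallest sizes at
which the binomial error of an active-fraction estimate (≈1.3 points at
N = 1,000) is well below the effect sizes of interest; `examples/
03_coincidence_detection.py` accepts any N.

## What the synthetic experiments do and do not show

The pool experiment emulates repeated trials of one stimulation protocol
on a single stereotyped cell: identical parameters, independent input
realisations.  It does not emulate cell-to-cell parameter variability,
inhibition, synaptic plasticity, or correlations between input streams —
all absent here.  Passing tests therefore demonstrate the conditional
pathway-interaction computation in a calibrated reduced model, not a
quantitative reproduction of any particular biological dataset.  Somatic
bursting is likewise out of reach by construction: it would require
dendritic Ca²⁺ plateau potentials, which this mechanism set does not
include.  Depolarization block and activity-dependent backpropagation
failure cannot be replicated by threshold-triggered conductance events.

## Known limitations

- Explicit integrators only; very large conductance densities or very
  small compartments can destabilise Euler at dt = 0.1 ms (diagnosed at
  run time, and by the calibration routine when probing extreme scales).
- One compartment per functional region: no spatial resolution within a
  branch, and synaptic "location" is resolved only to the compartment.
- The event-driven spike mechanism has no gradual activation: response to
  just-subthreshold input is strictly passive.
- Recurrent networks deliver spikes with a one-step (dt) synaptic delay
  and no axonal conduction delays.
- In the CA1 fixture, the strong spike-triggered adaptation that limits
  passive crossers to a single spike also prevents repetitive passive
  firing at any rate inside the 50–150% grid; the effect of dendritic
  spiking on inter-spike intervals therefore appears in its limiting form
  (bursts versus no ISIs at all) rather than as a shift between two ISI
  distributions.
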