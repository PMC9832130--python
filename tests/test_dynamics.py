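import numpy as np
import pytest

from dendrosim.dynamics import DSpikeParams, SomaParams, axial_currents, dendrite_rhs, soma_rhs
from dendrosim.engine import IntegratorSpec, StepCurrent, run, set_dspikes
from dendrosim.morphology import ModelValidationError

from conftest import active_dendrite_model


class TestSomaRhs:
    P = SomaParams(V_th=-50, V_spike=35, V_reset=-60, tau_A_ms=100.0,
                   gbar_A_nS=2.0, b_nS=1.0, E_A_mV=-80, V_A_mV=-70)

    def test_rest_is_fixed_point(self):
        dV, dgA = soma_rhs(-70.0, 0.0, self.P, C_m=100.0, g_L=5.0, EL=-70.0)
        assert dV == 0.0 and dgA == 0.0

    def test_initial_slope_under_current(self):
        # 100 pA into 100 pF from rest → 1 mV/ms
        dV, _ = soma_rhs(-70.0, 0.0, self.P, C_m=100.0, g_L=5.0, EL=-70.0, I_ext=100.0)
        assert dV == pytest.approx(1.0)

    def test_adaptation_decays_at_reference_voltage(self):
        _, dgA = soma_rhs(self.P.V_A_mV, 4.0, self.P, C_m=100.0, g_L=5.0, EL=-70.0)
        assert dgA == pytest.approx(-4.0 / self.P.tau_A_ms)

    def test_reset_ordering_enforced(self):
        with pytest.raises(ModelValidationError):
            SomaParams(V_th=-50, V_spike=-55, V_reset=-60)


class TestDendriteRhs:
    def test_reduces_to_passive_without_conductances(self, dspike_params):
        dV_active, _, _ = dendrite_rhs(-60.0, 0.0, 0.0, dspike_params,
                                       C_m=10.0, g_L=0.5, EL=-70.0)
        dV_passive, _, _ = dendrite_rhs(-60.0, 0.0, 0.0, None,
                                        C_m=10.0, g_L=0.5, EL=-70.0)
        assert dV_active == dV_passive

    def test_sodium_current_depolarizing(self, dspike_params):
        # g_Na = 10 nS at V = −60 mV with E_Na = 70 → +1300 pA into the membrane
        dV_with, dgNa, _ = dendrite_rhs(-60.0, 10.0, 0.0, dspike_params,
                                        C_m=10.0, g_L=0.0, EL=-70.0)
        I_na = dV_with * 10.0 - (-0.0 * (-60 + 70))
        assert I_na == pytest.approx(1300.0)
        assert dgNa == pytest.approx(-10.0 / dspike_params.tau_Na_ms)

    def test_conductance_decay_under_voltage_clamp(self, dspike_params):
        # dg/dt = −g/τ integrates to an exponential; two half-lives
        g = 8.0
        dt = 0.001
        for _ in range(2000):
            _, dg, _ = dendrite_rhs(-60.0, g, 0.0, dspike_params, 10.0, 0.0, -70.0)
            g += dt * dg
        assert g == pytest.approx(8.0 * np.exp(-2.0 / dspike_params.tau_Na_ms), rel=3e-3)

    def test_offset_must_precede_refractory(self):
        with pytest.raises(ModelValidationError):
            DSpikeParams(gbar_Na_nS=1, gbar_Kdr_nS=1, t_ref_Na_ms=2.0,
                         t_offset_Kdr_ms=3.0)


class TestAxialCurrents:
    def test_equal_voltages_no_current(self, passive_pair):
        V = np.full(2, -65.0)
        assert np.allclose(axial_currents(passive_pair, V), 0.0)

    def test_two_compartment_hand_value(self, passive_pair):
        m = passive_pair
        g = m.coupling_nS[0, 1]
        V = np.array([-60.0, -70.0])
        I = axial_currents(m, V)
        assert I[1] == pytest.approx(g * 10.0)     # toward the hyperpolarized side
        assert I[0] == pytest.approx(-g * 10.0)

    def test_currents_sum_to_zero(self, model_b):
        rng = np.random.default_rng(0)
        V = rng.uniform(-80, 0, size=(7, model_b.n_compartments))
        I = axial_currents(model_b, V)
        assert np.allclose(I.sum(axis=-1), 0.0, atol=1e-9)


class TestSomaSpikeEvents:
    def soma_model(self, **kw):
        from dendrosim.morphology import (CompartmentSpec, Geometry,
                                          NeuronModelSpec, PassiveParams, build_model)

        P = PassiveParams(1.0, 20.0, 150.0, -70.0)
        params = dict(V_th=-50.0, V_spike=35.0, V_reset=-60.0, reset_delay_ms=0.5,
                      tau_A_ms=100.0, gbar_A_nS=0.0, b_nS=2.0)
        params.update(kw)
        spec = NeuronModelSpec(
            compartments=(CompartmentSpec("soma", "soma", Geometry(40, 20), P,
                                          spine_factor=1.0),),
            edges=(), soma_params=SomaParams(**params),
        )
        return build_model(spec)

    def test_two_stage_reset(self):
        m = self.soma_model()
        res = run(m, [StepCurrent("soma", 200.0)], 50.0, IntegratorSpec("euler", 0.1))
        t_spk = res.soma_spike_times()[0]
        t, v = res.t_ms, res.V("soma")
        at = lambda tt: v[np.argmin(np.abs(t - tt))]
        assert at(t_spk + 0.1) == pytest.approx(35.0, abs=2.0)     # plateau
        assert at(t_spk + 0.4) > 30.0                              # still on plateau
        # the reset event fires at t_spk + 0.5; samples are post-integration,
        # so the first sample showing V_reset is one grid step later
        assert at(t_spk + 0.6) == pytest.approx(-60.0, abs=1.0)
        # adaptation incremented exactly once per spike
        n_spk = res.soma_spike_count[0]
        assert n_spk >= 2

    def test_plateau_suppresses_retrigger(self):
        m = self.soma_model()
        res = run(m, [StepCurrent("soma", 500.0)], 20.0, IntegratorSpec("euler", 0.1))
        isis = np.diff(res.soma_spike_times())
        assert (isis >= 0.5 - 1e-9).all()

    def test_subthreshold_never_spikes(self):
        m = self.soma_model()
        res = run(m, [StepCurrent("soma", 1.0)], 100.0)
        assert res.soma_spike_count[0] == 0


class TestDSpikeEvents:
    def test_flag_gate_blocks_retrigger_within_refractory(self, dspike_params):
        m = active_dendrite_model(dspike_params)
        res = run(m, [StepCurrent("dend", 300.0)], 100.0, IntegratorSpec("euler", 0.1))
        na = res.na_events
        dend_events = na[na[:, 2] == m.index["dend"], 0]
        assert len(dend_events) >= 2
        # no two Na events closer than the refractory period (strict >)
        assert (np.diff(dend_events) > dspike_params.t_ref_Na_ms - 1e-9).all()

    def test_kdr_follows_na_at_offset(self, dspike_params):
        m = active_dendrite_model(dspike_params)
        res = run(m, [StepCurrent("dend", 300.0, 5.0, 3.0)], 40.0,
                  IntegratorSpec("euler", 0.1))
        t_na = res.na_events[0, 0]
        t_k = res.kdr_events[0, 0]
        # first grid time strictly after t_na + offset
        assert t_k == pytest.approx(t_na + dspike_params.t_offset_Kdr_ms + 0.1, abs=1e-9)

    def test_repetitive_firing_at_refractory_limit(self, dspike_params):
        m = active_dendrite_model(dspike_params)
        res = run(m, [StepCurrent("dend", 500.0)], 200.0, IntegratorSpec("euler", 0.1))
        isis = np.diff(res.na_events[res.na_events[:, 2] == m.index["dend"], 0])
        # V held above threshold → spikes at the refractory limit (grid-rounded)
        assert np.median(isis) == pytest.approx(dspike_params.t_ref_Na_ms + 0.1, abs=0.11)

    def test_disabled_is_bitwise_passive(self, dspike_params):
        m_active = active_dendrite_model(dspike_params)
        m_off = set_dspikes(m_active, False)
        m_none = active_dendrite_model(None)
        stim = [StepCurrent("dend", 300.0)]
        r_off = run(m_off, stim, 100.0)
        r_none = run(m_none, stim, 100.0)
        assert np.max(np.abs(r_off.traces["V"] - r_none.traces["V"])) <= 1e-9
        assert len(r_off.na_events) == 0

    def test_conductances_never_negative(self, dspike_params):
        m = active_dendrite_model(dspike_params)
        res = run(m, [StepCurrent("dend", 400.0)], 150.0,
                  record_vars=("V", "g_Na", "g_Kdr"))
        assert (res.traces["g_Na"] >= 0).all()
        assert (res.traces["g_Kdr"] >= 0).all()
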