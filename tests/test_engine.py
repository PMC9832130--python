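import numpy as np
import pytest

from dendrosim.engine import (
    IntegratorSpec,
    NoiseCurrent,
    SimulationDiverged,
    StepCurrent,
    SynapticDrive,
    poisson_train,
    run,
    synchronous_train,
)
from dendrosim.morphology import ModelValidationError
from dendrosim.synapses import SynapseParams


def analytic_step_response(model, I_pA, t):
    g, C, EL = model.g_L_nS[0], model.C_m_pF[0], model.EL_mV[0]
    return EL + I_pA / g * (1.0 - np.exp(-t * g / C))


class TestIntegration:
    def test_rest_without_stimulus(self, passive_pair):
        res = run(passive_pair, [], 50.0)
        assert np.allclose(res.traces["V"], -70.0)

    def test_passive_step_matches_closed_form(self, passive_single):
        res = run(passive_single, [StepCurrent("soma", 100.0)], 100.0,
                  IntegratorSpec("rk4", 0.01))
        expected = analytic_step_response(passive_single, 100.0, res.t_ms)
        scale = 100.0 / passive_single.g_L_nS[0]
        assert np.max(np.abs(res.V("soma") - expected)) / scale < 0.005

    def test_passive_step_euler_at_default_dt(self, passive_single):
        res = run(passive_single, [StepCurrent("soma", 100.0)], 100.0,
                  IntegratorSpec("euler", 0.1))
        expected = analytic_step_response(passive_single, 100.0, res.t_ms)
        scale = 100.0 / passive_single.g_L_nS[0]
        assert np.max(np.abs(res.V("soma") - expected)) / scale < 0.005

    def test_two_compartment_steady_state_matches_linear_system(self, passive_pair):
        m = passive_pair
        I = np.array([0.0, 20.0])               # 20 pA into the dendrite
        res = run(m, [StepCurrent("dend", 20.0)], 600.0)
        # steady state solves G·ΔV = I with G the conductance Laplacian + leak
        W = m.coupling_nS
        G = np.diag(m.g_L_nS + W.sum(axis=0)) - W
        dV = np.linalg.solve(G, I)
        expected = m.EL_mV + dV
        final = res.traces["V"][-1, 0]
        assert np.max(np.abs(final - expected) / np.abs(dV.max())) < 0.005

    def test_convergence_orders(self, passive_single):
        # euler halving error ratio ≈ 2 (O(dt)); rk4 is at machine precision
        errs = {}
        for method in ("euler", "rk4"):
            errs[method] = []
            for dt in (0.1, 0.05, 0.025):
                res = run(passive_single, [StepCurrent("soma", 100.0)], 20.0,
                          IntegratorSpec(method, dt))
                exact = analytic_step_response(passive_single, 100.0, res.t_ms[-1])
                errs[method].append(abs(res.V("soma")[-1] - exact))
        e = errs["euler"]
        assert e[0] / e[1] == pytest.approx(2.0, rel=0.15)
        assert e[1] / e[2] == pytest.approx(2.0, rel=0.15)
        assert all(r4 < 1e-9 for r4 in errs["rk4"])

    def test_euler_vs_rk4_agree_on_smooth_problem(self, passive_pair):
        stim = [StepCurrent("dend", 15.0)]
        v1 = run(passive_pair, stim, 100.0, IntegratorSpec("euler", 0.01)).traces["V"]
        v2 = run(passive_pair, stim, 100.0, IntegratorSpec("rk4", 0.01)).traces["V"]
        assert np.max(np.abs(v1 - v2)) / 15.0 * passive_pair.g_L_nS[0] < 1e-3

    def test_step_and_sample_counts(self, passive_single):
        res = run(passive_single, [], 1.0, IntegratorSpec("euler", 0.1))
        assert len(res.t_ms) == 11
        assert res.t_ms[-1] == pytest.approx(1.0)

    def test_nan_aborts_with_location(self, passive_single):
        with pytest.raises(SimulationDiverged, match="soma.*t = "):
            run(passive_single, [StepCurrent("soma", float("nan"))], 1.0)

    def test_coarse_dt_warns(self):
        with pytest.warns(UserWarning, match="coarser"):
            IntegratorSpec("euler", 0.5)


class TestDeterminism:
    def test_identical_runs_bit_identical(self, passive_pair):
        stim = [NoiseCurrent("dend", 10.0, 20.0)]
        r1 = run(passive_pair, stim, 200.0, seed=7)
        r2 = run(passive_pair, stim, 200.0, seed=7)
        assert np.array_equal(r1.traces["V"], r2.traces["V"])

    def test_seed_changes_noise(self, passive_pair):
        stim = [NoiseCurrent("dend", 10.0, 20.0)]
        r1 = run(passive_pair, stim, 50.0, seed=7)
        r2 = run(passive_pair, stim, 50.0, seed=8)
        assert not np.array_equal(r1.traces["V"], r2.traces["V"])

    def test_added_stimulus_does_not_perturb_existing_stream(self, passive_pair):
        base = [NoiseCurrent("dend", 0.0, 5.0)]
        extra = base + [StepCurrent("soma", 1.0, 1e6, 1.0)]   # never active
        r1 = run(passive_pair, base, 50.0, seed=3)
        r2 = run(passive_pair, extra, 50.0, seed=3)
        assert np.array_equal(r1.traces["V"], r2.traces["V"])


class TestStimuli:
    def test_noise_current_sample_statistics(self, passive_single):
        # engine draws one normal per step per neuron from the stimulus stream
        stim = NoiseCurrent("soma", 12.0, 30.0)
        n_steps = 20000
        rng = np.random.default_rng([0 & 0x7FFFFFFF, 0])
        draws = np.concatenate([rng.normal(12.0, 30.0, size=1) for _ in range(200)])
        assert abs(draws.mean() - 12.0) <= 3 * 30.0 / np.sqrt(200)

    def test_poisson_train_empty_at_zero_rate(self):
        assert len(poisson_train(0.0, 1000.0, seed=1)) == 0

    def test_poisson_train_count_statistics(self):
        counts = [len(poisson_train(20.0, 10000.0, seed=s)) for s in range(500)]
        mean = np.mean(counts)
        se = np.sqrt(200.0 / 500.0)     # Poisson(200) mean over 500 seeds
        assert abs(mean - 200.0) <= 3 * se

    def test_poisson_train_sorted_within_bounds(self):
        t = poisson_train(50.0, 2000.0, seed=42)
        assert (np.diff(t) >= 0).all()
        assert t[0] >= 0 and t[-1] < 2000.0

    def test_poisson_train_deterministic(self):
        assert np.array_equal(poisson_train(20.0, 1000.0, 5), poisson_train(20.0, 1000.0, 5))

    def test_synchronous_train(self):
        assert np.allclose(synchronous_train(5, 0.1, 100.0),
                           [100.0, 100.1, 100.2, 100.3, 100.4])
        assert np.allclose(synchronous_train(1, t0_ms=3.0), [3.0])
        with pytest.raises(ModelValidationError):
            synchronous_train(0)

    def test_synaptic_drive_requires_exactly_one_source(self):
        syn = SynapseParams("AMPA", 1.0, 0.0, 0.2, 2.0)
        with pytest.raises(ModelValidationError):
            SynapticDrive("dend", (syn,), 1)
        with pytest.raises(ModelValidationError):
            SynapticDrive("dend", (syn,), 1, spike_times=((1.0,),), rate_Hz=5.0)


class TestSynapticIntegration:
    def test_single_exp_matches_superposition(self, passive_pair):
        # gating of a single-exponential synapse superposes spike by spike
        syn = SynapseParams("AMPA", 0.5, 0.0, 0.2, 5.0, kinetics="single_exp")
        times = (5.0, 12.0, 13.0, 40.0)
        drive = SynapticDrive("dend", (syn,), 1, spike_times=(times,))
        res = run(passive_pair, [drive], 80.0, IntegratorSpec("euler", 0.01),
                  record_vars=("V", "s"))
        s = res.traces["s"][0][:, 0, 0]
        t = res.t_ms
        expected = np.zeros_like(t)
        for tp in times:
            tp_grid = np.floor(tp / 0.01 + 1e-9) * 0.01
            expected += np.where(t > tp_grid, np.exp(-(t - tp_grid) / 5.0), 0.0)
        # expected at sample k reflects decay of increments; integrator error only
        assert np.max(np.abs(s - expected)) < 5e-3

    def test_dual_exp_ode_bounded_and_peaks_near_t_peak(self, passive_pair):
        syn = SynapseParams("AMPA", 0.1, 0.0, 2.0, 10.0)
        drive = SynapticDrive("dend", (syn,), 1, spike_times=((10.0,),))
        res = run(passive_pair, [drive], 80.0, IntegratorSpec("rk4", 0.01),
                  record_vars=("V", "s"))
        s = res.traces["s"][0][:, 0, 0]
        assert s.min() >= 0.0 and s.max() <= 1.0
        t_peak = res.t_ms[np.argmax(s)] - 10.0
        # small-amplitude limit: ODE peak time approaches the closed form 4.0236 ms
        assert t_peak == pytest.approx(4.0236, abs=0.75)

    def test_dual_exp_saturates_under_spike_bombardment(self, passive_pair):
        syn = SynapseParams("AMPA", 0.5, 0.0, 0.5, 5.0)
        times = tuple(float(x) for x in np.arange(1.0, 50.0, 0.5))
        drive = SynapticDrive("dend", (syn,), 1, spike_times=(times,))
        res = run(passive_pair, [drive], 60.0, record_vars=("V", "s"))
        s = res.traces["s"][0]
        assert s.max() <= 1.0 + 1e-9

    def test_epsp_depolarizes_gaba_hyperpolarizes(self, passive_pair):
        ampa = SynapseParams("AMPA", 1.0, 0.0, 0.2, 2.0)
        gaba = SynapseParams("GABA", 1.0, -80.0, 0.5, 8.0)
        r_a = run(passive_pair, [SynapticDrive("dend", (ampa,), 1, spike_times=((10.0,),))], 60.0)
        r_g = run(passive_pair, [SynapticDrive("dend", (gaba,), 1, spike_times=((10.0,),))], 60.0)
        assert r_a.V("dend").max() > -69.9
        assert r_g.V("dend").min() < -70.05


class TestBatchedPools:
    def test_pool_of_one_equals_single_run(self, passive_pair):
        stim = [StepCurrent("dend", 10.0)]
        r1 = run(passive_pair, stim, 50.0)
        rn = run(passive_pair, stim, 50.0, n_neurons=4)
        assert np.allclose(r1.traces["V"][:, 0], rn.traces["V"][:, 2])

    def test_poisson_neurons_independent(self, passive_pair):
        syn = SynapseParams("AMPA", 1.0, 0.0, 0.2, 2.0)
        drive = SynapticDrive("dend", (syn,), 1, rate_Hz=50.0)
        res = run(passive_pair, [drive], 200.0, n_neurons=3, seed=1)
        v = res.traces["V"][:, :, 1]
        assert not np.allclose(v[:, 0], v[:, 1])
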