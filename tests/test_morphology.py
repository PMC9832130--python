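import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrosim.morphology import (
    CompartmentSpec,
    Geometry,
    ModelValidationError,
    NeuronModelSpec,
    PassiveParams,
    absolute_passive,
    build_model,
    coupling_conductance,
    cylinder_area,
)

P = PassiveParams(1.0, 20.0, 150.0, -70.0)

geoms = st.builds(
    Geometry,
    length_um=st.floats(1.0, 1000.0),
    diameter_um=st.floats(0.1, 50.0),
)


class TestCylinderArea:
    def test_unit_cylinder(self):
        assert cylinder_area(Geometry(1, 1)) == pytest.approx(math.pi * 1e-8)

    def test_hand_value(self):
        # d = 2 µm, l = 100 µm → 2π·(1 µm)·(100 µm) = 628.319 µm²
        assert cylinder_area(Geometry(100, 2)) == pytest.approx(6.28319e-6, rel=1e-5)

    @given(geoms)
    def test_bilinear_scaling(self, g):
        doubled = Geometry(2 * g.length_um, 2 * g.diameter_um)
        assert cylinder_area(doubled) == pytest.approx(4 * cylinder_area(g), rel=1e-12)

    @pytest.mark.parametrize("length,diameter", [(0, 1), (1, 0), (-5, 1)])
    def test_invalid_geometry_rejected(self, length, diameter):
        with pytest.raises(ModelValidationError):
            Geometry(length, diameter)


class TestAbsolutePassive:
    def test_hand_values(self):
        comp = CompartmentSpec("c", "dendrite", Geometry(100, 2), P, spine_factor=1.0)
        C_m, g_L = absolute_passive(comp)
        assert C_m == pytest.approx(6.28319, rel=1e-5)     # pF
        assert g_L == pytest.approx(0.314159, rel=1e-5)    # nS

    def test_spine_factor_scales_both(self):
        base = CompartmentSpec("c", "dendrite", Geometry(100, 2), P, spine_factor=1.0)
        spiny = CompartmentSpec("c", "dendrite", Geometry(100, 2), P, spine_factor=1.5)
        C0, g0 = absolute_passive(base)
        C1, g1 = absolute_passive(spiny)
        assert C1 == pytest.approx(1.5 * C0) and g1 == pytest.approx(1.5 * g0)

    @given(geoms, st.floats(1.0, 2.0))
    @settings(max_examples=50)
    def test_tau_m_independent_of_geometry(self, g, sf):
        comp = CompartmentSpec("c", "dendrite", g, P, spine_factor=sf)
        C_m, g_L = absolute_passive(comp)
        tau = C_m / g_L                                    # pF/nS = ms
        assert tau == pytest.approx(P.cm_uF_cm2 * P.rm_kOhm_cm2, rel=1e-12)

    def test_dendrite_spine_default(self):
        dend = CompartmentSpec("d", "dendrite", Geometry(100, 2), P)
        soma = CompartmentSpec("s", "soma", Geometry(100, 2), P)
        assert dend.effective_spine_factor == 1.5
        assert soma.effective_spine_factor == 1.0


class TestCouplingConductance:
    def c(self, l, d):
        return CompartmentSpec("x", "dendrite", Geometry(l, d), P, spine_factor=1.0)

    def test_full_cylinder_hand_value(self):
        # r_a = 150 Ω·cm, l = 100 µm, d = 1 µm → R = 190.986 MΩ, g = 5.2360 nS
        g = coupling_conductance(self.c(100, 1), self.c(50, 5), "full_cylinder")
        exact = math.pi * (0.5e-4) ** 2 / (150.0 * 100e-4) * 1e9
        assert g == pytest.approx(exact, rel=1e-12)
        assert g == pytest.approx(5.23599, rel=1e-5)
        assert 1e3 / g == pytest.approx(190.986, rel=1e-5)

    def test_half_cylinder_hand_value(self):
        g = coupling_conductance(self.c(100, 1), self.c(200, 2), "half_cylinder")
        assert g == pytest.approx(6.98132, rel=1e-5)
        # R = 143.239 MΩ
        assert 1e3 / g == pytest.approx(143.239, rel=1e-5)

    def test_half_cylinder_identical_equals_full(self):
        a, b = self.c(120, 1.4), self.c(120, 1.4)
        assert coupling_conductance(a, b, "half_cylinder") == pytest.approx(
            coupling_conductance(a, b, "full_cylinder"), rel=1e-12
        )

    @given(geoms, geoms)
    @settings(max_examples=50)
    def test_half_cylinder_symmetric(self, g1, g2):
        a = CompartmentSpec("a", "dendrite", g1, P)
        b = CompartmentSpec("b", "dendrite", g2, P)
        assert coupling_conductance(a, b) == coupling_conductance(b, a)

    @given(geoms, st.floats(1.05, 3.0))
    @settings(max_examples=50)
    def test_monotone_in_diameter_and_length(self, g, factor):
        base = self.c(g.length_um, g.diameter_um)
        wider = self.c(g.length_um, g.diameter_um * factor)
        longer = self.c(g.length_um * factor, g.diameter_um)
        ref = coupling_conductance(base, base)
        assert coupling_conductance(wider, wider) > ref
        assert coupling_conductance(longer, longer) < ref


class TestBuildModel:
    def chain(self, names, edges, **kw):
        comps = tuple(
            CompartmentSpec(n, "soma" if i == 0 else "dendrite", Geometry(100, 2), P)
            for i, n in enumerate(names)
        )
        return NeuronModelSpec(compartments=comps, edges=edges, **kw)

    def test_two_compartment_chain(self):
        m = build_model(self.chain(("soma", "d"), (("soma", "d"),)))
        W = m.coupling_nS
        assert W[0, 1] == W[1, 0] > 0
        assert np.count_nonzero(W) == 2

    def test_five_compartment_ca1_skeleton(self):
        spec = self.chain(
            ("soma", "basal", "trunk_prox", "trunk_dist", "tuft"),
            (("soma", "basal"), ("soma", "trunk_prox"),
             ("trunk_prox", "trunk_dist"), ("trunk_dist", "tuft")),
        )
        m = build_model(spec)
        assert m.n_compartments == 5
        assert m.parent["tuft"] == "trunk_dist"

    def test_cycle_rejected(self):
        spec = self.chain(("a", "b", "c"), (("a", "b"), ("b", "c"), ("c", "a")))
        with pytest.raises(ModelValidationError):
            build_model(spec)

    def test_disconnected_rejected(self):
        spec = self.chain(("a", "b", "c", "d"), (("a", "b"), ("c", "d"), ("a", "b")))
        with pytest.raises(ModelValidationError):
            build_model(spec)

    def test_duplicate_names_rejected(self):
        comps = (
            CompartmentSpec("s", "soma", Geometry(10, 10), P),
            CompartmentSpec("s", "dendrite", Geometry(10, 10), P),
        )
        with pytest.raises(ModelValidationError, match="duplicate"):
            build_model(NeuronModelSpec(compartments=comps, edges=(("s", "s"),)))

    def test_two_somata_rejected(self):
        comps = (
            CompartmentSpec("s1", "soma", Geometry(10, 10), P),
            CompartmentSpec("s2", "soma", Geometry(10, 10), P),
        )
        with pytest.raises(ModelValidationError, match="soma"):
            build_model(NeuronModelSpec(compartments=comps, edges=(("s1", "s2"),)))

    def test_coupling_override_precedence(self):
        spec = self.chain(("soma", "d"), (("soma", "d"),))
        spec = NeuronModelSpec(
            compartments=spec.compartments, edges=spec.edges,
            coupling_overrides={("soma", "d"): 3.25},
        )
        m = build_model(spec)
        assert m.coupling_nS[0, 1] == 3.25 == m.coupling_nS[1, 0]

    def test_coupling_exactly_symmetric(self, model_b):
        W = model_b.coupling_nS
        assert np.array_equal(W, W.T)
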