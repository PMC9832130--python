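"""Compartment geometry and passive electrical structure.

Every compartment is an open cylinder (no end caps) described by its length
and diameter in micrometres.  Specific membrane constants (capacitance per
area, membrane resistivity, axial resistivity) are converted here into the
absolute quantities the simulator works with: total capacitance ``C_m`` (pF),
leak conductance ``g_L`` (nS) and inter-compartment coupling conductances
``g_c`` (nS).  Dendritic compartments may carry a spine-correction factor
that scales both ``C_m`` and ``g_L`` to account for membrane area contributed
by spines that are not modelled explicitly.

Internal unit system: mV, ms, nS, pF, pA, µm.  This set is algebraically
closed (nS·mV = pA, pA/pF = mV/ms), so no conversion constants appear in the
dynamical equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Geometry",
    "PassiveParams",
    "CompartmentSpec",
    "NeuronModelSpec",
    "NeuronModel",
    "cylinder_area",
    "absolute_passive",
    "coupling_conductance",
    "build_model",
    "ModelValidationError",
]

#: µm² → cm²
_UM2_TO_CM2 = 1e-8


class ModelValidationError(ValueError):
    """A model specification violates a structural invariant."""


@dataclass(frozen=True)
class Geometry:
    """Cylinder dimensions in micrometres."""

    length_um: float
    diameter_um: float

    def __post_init__(self) -> None:
        if not (self.length_um > 0 and self.diameter_um > 0):
            raise ModelValidationError(
                f"cylinder dimensions must be positive, got "
                f"l={self.length_um} µm, d={self.diameter_um} µm"
            )


@dataclass(frozen=True)
class PassiveParams:
    """Specific passive constants in the conventional experimental units."""

    cm_uF_cm2: float = 1.0      # specific capacitance, µF·cm⁻²
    rm_kOhm_cm2: float = 30.0   # specific membrane resistivity, kΩ·cm²
    ra_Ohm_cm: float = 150.0    # specific axial resistivity, Ω·cm
    EL_mV: float = -70.0        # leak reversal potential, mV

    def __post_init__(self) -> None:
        if min(self.cm_uF_cm2, self.rm_kOhm_cm2, self.ra_Ohm_cm) <= 0:
            raise ModelValidationError(
                "specific capacitance/resistivities must be strictly positive"
            )


@dataclass(frozen=True)
class CompartmentSpec:
    """One named cylindrical compartment.

    ``spine_factor`` scales both C_m and g_L; dendrites default to 1.5
    (membrane added by unmodelled spines), the soma to 1.0.  ``dspike`` and
    ``synapses`` attach active and synaptic mechanisms (see
    :mod:`dendrosim.dynamics` and :mod:`dendrosim.synapses`).
    """

    name: str
    kind: str                      # "soma" | "dendrite"
    geometry: Geometry
    passive: PassiveParams = field(default_factory=PassiveParams)
    spine_factor: Optional[float] = None   # None → kind-dependent default
    dspike: object = None                  # DSpikeParams | None
    synapses: tuple = ()                   # tuple[SynapseParams, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("soma", "dendrite"):
            raise ModelValidationError(
                f"compartment {self.name!r}: kind must be 'soma' or "
                f"'dendrite', got {self.kind!r}"
            )
        sf = self.effective_spine_factor
        if not (1.0 <= sf <= 2.0):
            raise ModelValidationError(
                f"compartment {self.name!r}: spine_factor {sf} outside [1, 2]"
            )

    @property
    def effective_spine_factor(self) -> float:
        if self.spine_factor is not None:
            return self.spine_factor
        return 1.5 if self.kind == "dendrite" else 1.0


@dataclass(frozen=True)
class NeuronModelSpec:
    """Declarative neuron: compartments plus a tree of electrical couplings.

    ``coupling_method`` selects between the full-cylinder formula (axial
    resistance of the distal compartment's whole cylinder) and the default
    half-cylinder formula (centre-to-centre resistance, mean of the two half
    cylinders).  ``coupling_overrides`` maps an edge ``(a, b)`` to an explicit
    conductance in nS, taking precedence over either formula.
    """

    compartments: tuple
    edges: tuple                      # tuple[(parent, child), ...]
    coupling_method: str = "half_cylinder"
    coupling_overrides: dict = field(default_factory=dict)
    soma_params: object = None        # SomaParams (dynamics module)
    name: str = "neuron"


def cylinder_area(geometry: Geometry) -> float:
    """Lateral surface area of an open cylinder, in cm².

    A = 2π(d/2)·l, end caps excluded.
    """
    return (
        2.0 * math.pi * (geometry.diameter_um / 2.0) * geometry.length_um
    ) * _UM2_TO_CM2


def absolute_passive(comp: CompartmentSpec) -> tuple[float, float]:
    """Total membrane capacitance (pF) and leak conductance (nS).

    C_m = c_m·A·spine_factor and g_L = (A/r_m)·spine_factor.  The membrane
    time constant C_m/g_L = c_m·r_m is independent of geometry and of the
    spine factor.
    """
    area_cm2 = cylinder_area(comp.geometry)
    sf = comp.effective_spine_factor
    cm_pF = comp.passive.cm_uF_cm2 * area_cm2 * 1e6 * sf          # µF → pF
    gl_nS = area_cm2 / (comp.passive.rm_kOhm_cm2 * 1e3) * 1e9 * sf  # S → nS
    return cm_pF, gl_nS


def _axial_resistance_Ohm(geometry: Geometry, ra_Ohm_cm: float) -> float:
    """Longitudinal resistance of one full cylinder, r_a·l/(π(d/2)²), in Ω."""
    l_cm = geometry.length_um * 1e-4
    r_cm = geometry.diameter_um / 2.0 * 1e-4
    return ra_Ohm_cm * l_cm / (math.pi * r_cm * r_cm)


def coupling_conductance(
    comp_distal: CompartmentSpec,
    comp_proximal: CompartmentSpec,
    method: str = "half_cylinder",
) -> float:
    """Coupling conductance between two adjacent compartments, in nS.

    ``full_cylinder`` uses the whole-cylinder axial resistance of the
    *distal* compartment (first argument); appropriate when few compartments
    are strongly coupled to the soma.  ``half_cylinder`` (default) takes the
    centre-to-centre resistance, the mean of the two compartments' full
    cylinder resistances, and is symmetric under argument swap.
    """
    ra = comp_distal.passive.ra_Ohm_cm
    if method == "full_cylinder":
        R = _axial_resistance_Ohm(comp_distal.geometry, ra)
    elif method == "half_cylinder":
        R = 0.5 * (
            _axial_resistance_Ohm(comp_distal.geometry, comp_distal.passive.ra_Ohm_cm)
            + _axial_resistance_Ohm(comp_proximal.geometry, comp_proximal.passive.ra_Ohm_cm)
        )
    else:
        raise ModelValidationError(f"unknown coupling method {method!r}")
    return 1.0 / R * 1e9  # S → nS


@dataclass(frozen=True)
class NeuronModel:
    """Assembled, validated neuron model (immutable).

    Arrays are indexed by compartment, with the soma always at index
    ``soma_index``.  ``coupling_nS`` is the symmetric conductance matrix;
    off-tree entries are zero.
    """

    spec: NeuronModelSpec
    names: tuple
    index: dict                  # name → int
    kinds: tuple
    C_m_pF: np.ndarray
    g_L_nS: np.ndarray
    EL_mV: np.ndarray
    coupling_nS: np.ndarray      # (C, C) symmetric
    soma_index: int
    parent: dict                 # child name → parent name (soma has none)
    dspikes_enabled: bool = True # global switch for the dendritic spike mechanism

    @property
    def n_compartments(self) -> int:
        return len(self.names)

    def compartment(self, name: str) -> CompartmentSpec:
        return self.spec.compartments[self.index[name]]

    def neighbors(self, name: str) -> list[str]:
        i = self.index[name]
        return [self.names[k] for k in np.nonzero(self.coupling_nS[i])[0]]

    def path_distance_um(self, name: str) -> float:
        """Path length from the soma centre to the distal end of ``name``.

        Sum of full lengths of compartments on the root-to-node path
        (excluding the soma itself); a simple monotone distance coordinate
        along unbranched paths.
        """
        d = 0.0
        node = name
        while node != self.names[self.soma_index]:
            d += self.compartment(node).geometry.length_um
            node = self.parent[node]
        return d

    def with_scaled_membrane(self, factor: float) -> "NeuronModel":
        """Copy with all C_m and g_L multiplied by ``factor`` (τ_m preserved)."""
        return NeuronModel(
            spec=self.spec,
            names=self.names,
            index=self.index,
            kinds=self.kinds,
            C_m_pF=self.C_m_pF * factor,
            g_L_nS=self.g_L_nS * factor,
            EL_mV=self.EL_mV,
            coupling_nS=self.coupling_nS,
            soma_index=self.soma_index,
            parent=self.parent,
            dspikes_enabled=self.dspikes_enabled,
        )


def build_model(spec: NeuronModelSpec) -> NeuronModel:
    """Validate a :class:`NeuronModelSpec` and assemble a :class:`NeuronModel`.

    Checks: unique names, exactly one soma, edge endpoints exist, the edge
    set forms a connected tree.  Coupling conductances are computed with the
    spec's method; for ``full_cylinder`` the child (distal) compartment of
    each edge supplies the geometry.  Overrides are applied symmetrically.
    """
    comps = spec.compartments
    names = tuple(c.name for c in comps)
    problems: list[str] = []

    seen: set[str] = set()
    for n in names:
        if n in seen:
            problems.append(f"duplicate compartment name {n!r}")
        seen.add(n)

    somata = [c.name for c in comps if c.kind == "soma"]
    if len(somata) != 1:
        problems.append(f"expected exactly one soma, found {somata!r}")

    index = {n: i for i, n in enumerate(names)}
    for a, b in spec.edges:
        for endpoint in (a, b):
            if endpoint not in index:
                problems.append(f"edge ({a!r}, {b!r}) references unknown compartment {endpoint!r}")

    if problems:
        raise ModelValidationError("; ".join(problems))

    # Tree check: n-1 edges, connected, acyclic (BFS from soma).
    n = len(names)
    if len(spec.edges) != n - 1:
        raise ModelValidationError(
            f"{n} compartments require exactly {n - 1} edges for a tree, "
            f"got {len(spec.edges)} (cycle or disconnection)"
        )
    adjacency: dict[str, list[str]] = {nm: [] for nm in names}
    for a, b in spec.edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    soma_name = somata[0]
    parent: dict[str, str] = {}
    order = [soma_name]
    visited = {soma_name}
    for node in order:
        for nb in adjacency[node]:
            if nb not in visited:
                visited.add(nb)
                parent[nb] = node
                order.append(nb)
    if len(visited) != n:
        missing = sorted(set(names) - visited)
        raise ModelValidationError(
            f"compartments unreachable from the soma (disconnected or cyclic): {missing}"
        )

    C_m = np.empty(n)
    g_L = np.empty(n)
    EL = np.empty(n)
    for i, c in enumerate(comps):
        C_m[i], g_L[i] = absolute_passive(c)
        EL[i] = c.passive.EL_mV

    W = np.zeros((n, n))
    for a, b in spec.edges:
        # orient the edge: the child (farther from soma) is the distal one
        child, par = (a, b) if parent.get(a) == b else (b, a)
        key_ab, key_ba = (a, b), (b, a)
        if key_ab in spec.coupling_overrides:
            g = float(spec.coupling_overrides[key_ab])
        elif key_ba in spec.coupling_overrides:
            g = float(spec.coupling_overrides[key_ba])
        else:
            g = coupling_conductance(
                comps[index[child]], comps[index[par]], spec.coupling_method
            )
        W[index[a], index[b]] = g
        W[index[b], index[a]] = g

    return NeuronModel(
        spec=spec,
        names=names,
        index=index,
        kinds=tuple(c.kind for c in comps),
        C_m_pF=C_m,
        g_L_nS=g_L,
        EL_mV=EL,
        coupling_nS=W,
        soma_index=index[soma_name],
        parent=parent,
    )
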