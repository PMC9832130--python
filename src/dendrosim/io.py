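"""Model documents: JSON serialisation of neuron models and experiments.

A model document is a JSON object with unit-suffixed field names
(``length_um``, ``gbar_nS`` …) so files are self-describing.  Schema::

    {
      "schema_version": 1,
      "name": "...",
      "coupling_method": "half_cylinder",
      "compartments": [
        {"name": "soma", "kind": "soma",
         "geometry": {"length_um": 25, "diameter_um": 25},
         "passive": {"cm_uF_cm2": 1, "rm_kOhm_cm2": 30,
                     "ra_Ohm_cm": 150, "EL_mV": -70},
         "spine_factor": 1.0,                  # optional
         "dspike": {...DSpikeParams fields...},  # optional
         "synapses": [{...SynapseParams fields...}, ...]},
        ...
      ],
      "edges": [["soma", "dend"], ...],
      "coupling_overrides_nS": {"soma|dend": 5.0},   # optional
      "soma": {...SomaParams fields...},
      "provenance": {"note": "free text"}            # optional
    }

Unknown fields raise in strict mode (default) and warn in lenient mode;
errors name the offending JSON path.  ``parse(serialize(spec))`` returns an
equal spec.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

from .morphology import (
    CompartmentSpec,
    Geometry,
    ModelValidationError,
    NeuronModel,
    NeuronModelSpec,
    PassiveParams,
    build_model,
)
from .dynamics import DSpikeParams, SomaParams
from .synapses import MgBlockParams, SynapseParams

__all__ = ["model_spec_to_dict", "model_spec_from_dict", "save_model",
           "load_model", "write_traces_csv", "write_events_csv"]

SCHEMA_VERSION = 1


class DocumentError(ModelValidationError):
    """A model document violates the schema; the message names the path."""


def _asdict_clean(obj) -> dict:
    return {k: v for k, v in dataclasses.asdict(obj).items()}


def model_spec_to_dict(spec: NeuronModelSpec) -> dict:
    comps = []
    for c in spec.compartments:
        entry = {
            "name": c.name,
            "kind": c.kind,
            "geometry": _asdict_clean(c.geometry),
            "passive": _asdict_clean(c.passive),
        }
        if c.spine_factor is not None:
            entry["spine_factor"] = c.spine_factor
        if c.dspike is not None:
            entry["dspike"] = _asdict_clean(c.dspike)
        if c.synapses:
            entry["synapses"] = [_asdict_clean(s) for s in c.synapses]
        comps.append(entry)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": spec.name,
        "coupling_method": spec.coupling_method,
        "compartments": comps,
        "edges": [list(e) for e in spec.edges],
    }
    if spec.coupling_overrides:
        doc["coupling_overrides_nS"] = {
            f"{a}|{b}": g for (a, b), g in spec.coupling_overrides.items()
        }
    if spec.soma_params is not None:
        doc["soma"] = _asdict_clean(spec.soma_params)
    return doc


def _check_fields(d: dict, allowed: set, required: set, path: str, strict: bool):
    unknown = set(d) - allowed
    if unknown:
        msg = f"{path}: unknown field(s) {sorted(unknown)}"
        if strict:
            raise DocumentError(msg)
        warnings.warn(msg, stacklevel=3)
    missing = required - set(d)
    if missing:
        raise DocumentError(f"{path}: missing required field(s) {sorted(missing)}")


def _build(cls, d: dict, path: str, strict: bool):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    required = {n for n, f in fields.items()
                if f.default is dataclasses.MISSING
                and f.default_factory is dataclasses.MISSING}
    _check_fields(d, set(fields), required, path, strict)
    kwargs = {k: v for k, v in d.items() if k in fields}
    try:
        return cls(**kwargs)
    except ModelValidationError as e:
        raise DocumentError(f"{path}: {e}") from e


def model_spec_from_dict(doc: dict, strict: bool = True) -> NeuronModelSpec:
    if not isinstance(doc, dict):
        raise DocumentError("/: document must be a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DocumentError(
            f"/schema_version: unsupported version {version!r} "
            f"(this reader supports {SCHEMA_VERSION})"
        )
    _check_fields(
        doc,
        {"schema_version", "name", "coupling_method", "compartments", "edges",
         "coupling_overrides_nS", "soma", "provenance"},
        {"schema_version", "compartments", "edges"},
        "/", strict,
    )
    comps = []
    for i, c in enumerate(doc["compartments"]):
        path = f"/compartments/{i}"
        _check_fields(
            c,
            {"name", "kind", "geometry", "passive", "spine_factor", "dspike", "synapses"},
            {"name", "kind", "geometry"},
            path, strict,
        )
        geometry = _build(Geometry, c["geometry"], path + "/geometry", strict)
        passive = (_build(PassiveParams, c["passive"], path + "/passive", strict)
                   if "passive" in c else PassiveParams())
        dspike = (_build(DSpikeParams, c["dspike"], path + "/dspike", strict)
                  if c.get("dspike") else None)
        synapses = []
        for j, s in enumerate(c.get("synapses", ())):
            spath = f"{path}/synapses/{j}"
            s = dict(s)
            mg = s.pop("mg", None)
            mg_obj = _build(MgBlockParams, mg, spath + "/mg", strict) if mg else None
            synapses.append(_build(SynapseParams, {**s, "mg": mg_obj}, spath, strict))
        comps.append(CompartmentSpec(
            name=c["name"], kind=c["kind"], geometry=geometry, passive=passive,
            spine_factor=c.get("spine_factor"), dspike=dspike,
            synapses=tuple(synapses),
        ))
    overrides = {}
    for key, g in doc.get("coupling_overrides_nS", {}).items():
        a, _, b = key.partition("|")
        if not b:
            raise DocumentError(f"/coupling_overrides_nS/{key}: key must be 'a|b'")
        overrides[(a, b)] = float(g)
    soma_params = (_build(SomaParams, doc["soma"], "/soma", strict)
                   if "soma" in doc else None)
    return NeuronModelSpec(
        compartments=tuple(comps),
        edges=tuple((a, b) for a, b in doc["edges"]),
        coupling_method=doc.get("coupling_method", "half_cylinder"),
        coupling_overrides=overrides,
        soma_params=soma_params,
        name=doc.get("name", "neuron"),
    )


def save_model(spec_or_model, path, provenance: str | None = None) -> None:
    """Write a model (spec or built model) as a JSON document."""
    spec = spec_or_model.spec if isinstance(spec_or_model, NeuronModel) else spec_or_model
    doc = model_spec_to_dict(spec)
    if provenance:
        doc["provenance"] = {"note": provenance}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path, strict: bool = True, build: bool = True):
    """Read a JSON model document; returns a built model (or the spec)."""
    doc = json.loads(Path(path).read_text())
    spec = model_spec_from_dict(doc, strict=strict)
    return build_model(spec) if build else spec


def write_traces_csv(result, path) -> None:
    """Voltage traces as CSV: time_ms, then <compartment>_V per neuron 0."""
    import pandas as pd

    data = {"time_ms": result.t_ms}
    V = result.traces.get("V")
    if V is None:
        raise ModelValidationError("result holds no recorded voltage traces")
    for i, name in enumerate(result.names):
        data[f"{name}_V_mV"] = V[:, 0, i]
    pd.DataFrame(data).to_csv(path, index=False)


def write_events_csv(result, path) -> None:
    """Tidy event log as CSV (time_ms, compartment, event, neuron)."""
    result.events_dataframe().to_csv(path, index=False)
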