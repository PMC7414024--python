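"""File formats: native YAML model files, SBML Level 3, and run configs.

The native model file is a YAML rendering of :meth:`ModelDefinition.to_dict`
with sorted keys, so serialise -> load -> serialise is byte-identical.

The SBML path covers the subset this model family needs: three
compartments, species with initial amounts, global parameters, irreversible
reactions with pure mass-action kinetic laws (a MathML product of one
parameter and the reactant/modifier species), and two time-triggered events
(activation and reset).  Any other kinetic law raises
:class:`UnsupportedKineticLawError` naming the reaction.  Model metadata
that core SBML cannot express (species roles, binding-pair grouping,
reaction compartment attribution) travels in a package annotation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from lxml import etree

from .model import (
    ActivationScheme,
    BindingPair,
    Compartment,
    ModelDefinition,
    RateConstant,
    Reaction,
    Species,
)

__all__ = [
    "save_model",
    "load_model",
    "model_to_yaml",
    "model_from_yaml",
    "write_sbml",
    "read_sbml",
    "UnsupportedKineticLawError",
    "RunConfig",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://picycle.invalid/annotations"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"


class UnsupportedKineticLawError(ValueError):
    """A reaction's kinetic law is not pure mass action."""


# ---------------------------------------------------------------------------
# Native YAML model file
# ---------------------------------------------------------------------------


def model_to_yaml(model: ModelDefinition) -> str:
    return yaml.safe_dump(model.to_dict(), sort_keys=True, default_flow_style=False)


def model_from_yaml(text: str) -> ModelDefinition:
    return ModelDefinition.from_dict(yaml.safe_load(text))


def save_model(model: ModelDefinition, path) -> None:
    Path(path).write_text(model_to_yaml(model))


def load_model(path) -> ModelDefinition:
    return model_from_yaml(Path(path).read_text())


# ---------------------------------------------------------------------------
# SBML Level 3 subset
# ---------------------------------------------------------------------------


def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _s(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _cn(parent, value: float):
    el = etree.SubElement(parent, _m("cn"))
    el.text = repr(float(value))
    return el


def _ci(parent, name: str):
    el = etree.SubElement(parent, _m("ci"))
    el.text = f" {name} "
    return el


def write_sbml(model: ModelDefinition, path) -> None:
    """Export to SBML L3 with mass-action kinetic laws and timed events."""
    model.validate()
    nsmap = {None: SBML_NS}
    sbml = etree.Element(_s("sbml"), nsmap=nsmap, level="3", version="2")
    mdl = etree.SubElement(sbml, _s("model"), id=model.name)

    annot = etree.SubElement(mdl, _s("annotation"))
    extra = {
        "roles": {sp.name: sp.role for sp in model.species.values()},
        "parents": {
            sp.name: [sp.lipid_parent, sp.bp_parent]
            for sp in model.species.values() if sp.role == "complex"
        },
        "binding": [
            {"lipid": b.lipid, "bp": b.bp, "complex": b.complex,
             "k_on": b.k_on_id, "k_off": b.k_off_id, "bp_total": b.bp_total}
            for b in model.binding_pairs
        ],
        "reaction_compartments": {r.id: r.compartment for r in model.reactions},
        "rate_switches": list(model.activation.rate_switches) if model.activation else [],
        "metadata": model.metadata,
    }
    pk = etree.SubElement(annot, f"{{{ANNOT_NS}}}picycle", nsmap={"picycle": ANNOT_NS})
    pk.text = json.dumps(extra, sort_keys=True)

    lc = etree.SubElement(mdl, _s("listOfCompartments"))
    for c in model.compartments.values():
        etree.SubElement(lc, _s("compartment"), id=c.name, size=repr(c.volume),
                         spatialDimensions="3", constant="true")
    ls = etree.SubElement(mdl, _s("listOfSpecies"))
    for sp in model.species.values():
        etree.SubElement(
            ls, _s("species"), id=sp.name, compartment=sp.compartment,
            initialAmount=repr(sp.initial_amount), hasOnlySubstanceUnits="true",
            boundaryCondition="false", constant="false",
        )
    lp = etree.SubElement(mdl, _s("listOfParameters"))
    switched = set(model.activation.rate_switches) if model.activation else set()
    for rc in model.rate_constants.values():
        etree.SubElement(lp, _s("parameter"), id=rc.id, value=repr(rc.basal_value),
                         constant="false" if rc.id in switched else "true")
        if rc.activated_value is not None:
            etree.SubElement(lp, _s("parameter"), id=f"{rc.id}_active",
                             value=repr(rc.activated_value), constant="true")

    lr = etree.SubElement(mdl, _s("listOfReactions"))
    for rx in model.reactions:
        r = etree.SubElement(lr, _s("reaction"), id=rx.id, reversible="false")
        lrt = etree.SubElement(r, _s("listOfReactants"))
        for name, stoich in rx.reactants:
            etree.SubElement(lrt, _s("speciesReference"), species=name,
                             stoichiometry=repr(float(stoich)), constant="true")
        lpr = etree.SubElement(r, _s("listOfProducts"))
        for name, stoich in rx.products:
            etree.SubElement(lpr, _s("speciesReference"), species=name,
                             stoichiometry=repr(float(stoich)), constant="true")
        if rx.enzyme is not None:
            lm = etree.SubElement(r, _s("listOfModifiers"))
            etree.SubElement(lm, _s("modifierSpeciesReference"), species=rx.enzyme)
        kl = etree.SubElement(r, _s("kineticLaw"))
        math = etree.SubElement(kl, _m("math"))
        apply = etree.SubElement(math, _m("apply"))
        etree.SubElement(apply, _m("times"))
        _ci(apply, rx.rate_constant_id)
        for name, stoich in rx.reactants:
            for _ in range(stoich):
                _ci(apply, name)
        if rx.enzyme is not None:
            _ci(apply, rx.enzyme)

    if model.activation is not None:
        a = model.activation
        le = etree.SubElement(mdl, _s("listOfEvents"))

        def _event(eid, t, assignments):
            ev = etree.SubElement(le, _s("event"), id=eid,
                                  useValuesFromTriggerTime="true")
            trig = etree.SubElement(ev, _s("trigger"), initialValue="false",
                                    persistent="true")
            math = etree.SubElement(trig, _m("math"))
            apply = etree.SubElement(math, _m("apply"))
            etree.SubElement(apply, _m("geq"))
            cs = etree.SubElement(apply, _m("csymbol"), encoding="text",
                                  definitionURL=TIME_CSYMBOL)
            cs.text = " time "
            _cn(apply, t)
            lea = etree.SubElement(ev, _s("listOfEventAssignments"))
            for target, value in assignments:
                ea = etree.SubElement(lea, _s("eventAssignment"), variable=target)
                math = etree.SubElement(ea, _m("math"))
                _cn(math, value)

        on = [("Ra", a.receptor_count)]
        for rid in a.rate_switches:
            rc = model.rate_constants[rid]
            if rc.activated_value is not None:
                on.append((rid, rc.activated_value))
        _event("activation", a.t_activation, on)
        if a.termination == "reset":
            off = [(rid, model.rate_constants[rid].basal_value)
                   for rid in a.rate_switches
                   if model.rate_constants[rid].activated_value is not None]
            _event("termination", a.t_activation + a.termination_timescale, off)

    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _math_factors(apply_el, reaction_id: str) -> list[str]:
    """Flatten a MathML product into its <ci> factor names."""
    children = list(apply_el)
    if not children or children[0].tag != _m("times"):
        raise UnsupportedKineticLawError(
            f"reaction {reaction_id}: kinetic law is not a mass-action product"
        )
    names: list[str] = []
    for el in children[1:]:
        if el.tag == _m("ci"):
            names.append(el.text.strip())
        elif el.tag == _m("apply"):
            names.extend(_math_factors(el, reaction_id))
        else:
            raise UnsupportedKineticLawError(
                f"reaction {reaction_id}: unsupported term {etree.QName(el).localname!r}"
            )
    return names


def read_sbml(path) -> ModelDefinition:
    """Import an SBML L3 file written by :func:`write_sbml` (or equivalent).

    Kinetic laws must be pure mass-action products; anything else (a
    Michaelis-Menten rational law, sums, powers) raises
    :class:`UnsupportedKineticLawError` naming the offending reaction.
    """
    tree = etree.parse(str(path))
    mdl = tree.getroot().find(_s("model"))
    if mdl is None:
        raise ValueError("no <model> element")
    extra = {}
    annot = mdl.find(_s("annotation"))
    if annot is not None:
        pk = annot.find(f"{{{ANNOT_NS}}}picycle")
        if pk is not None and pk.text:
            extra = json.loads(pk.text)
    roles = extra.get("roles", {})
    parents = extra.get("parents", {})
    rx_comp = extra.get("reaction_compartments", {})

    compartments = {
        el.get("id"): Compartment(el.get("id"), float(el.get("size")))
        for el in mdl.find(_s("listOfCompartments"))
    }
    species = {}
    for el in mdl.find(_s("listOfSpecies")):
        name = el.get("id")
        lp, bp = (parents.get(name) or (None, None))
        species[name] = Species(
            name, el.get("compartment"), float(el.get("initialAmount")),
            roles.get(name, "enzyme"), lp, bp,
        )
    params = {}
    for el in mdl.find(_s("listOfParameters")):
        params[el.get("id")] = float(el.get("value"))
    rate_constants = {
        pid: RateConstant(pid, value, params.get(f"{pid}_active"))
        for pid, value in params.items() if not pid.endswith("_active")
    }

    reactions = []
    for el in mdl.find(_s("listOfReactions")):
        rid = el.get("id")
        reactants, products = [], []
        lrt = el.find(_s("listOfReactants"))
        if lrt is not None:
            for sr in lrt:
                reactants.append((sr.get("species"), int(float(sr.get("stoichiometry", "1")))))
        lpr = el.find(_s("listOfProducts"))
        if lpr is not None:
            for sr in lpr:
                products.append((sr.get("species"), int(float(sr.get("stoichiometry", "1")))))
        modifiers = []
        lm = el.find(_s("listOfModifiers"))
        if lm is not None:
            modifiers = [sr.get("species") for sr in lm]
        if len(modifiers) > 1:
            raise UnsupportedKineticLawError(f"reaction {rid}: multiple modifiers")
        enzyme = modifiers[0] if modifiers else None

        kl = el.find(_s("kineticLaw"))
        if kl is None:
            raise UnsupportedKineticLawError(f"reaction {rid}: no kinetic law")
        math = kl.find(_m("math"))
        apply = math.find(_m("apply")) if math is not None else None
        if apply is None:
            raise UnsupportedKineticLawError(f"reaction {rid}: no rate expression")
        factors = _math_factors(apply, rid)
        param_factors = [f for f in factors if f in rate_constants]
        if len(param_factors) != 1:
            raise UnsupportedKineticLawError(
                f"reaction {rid}: expected exactly one rate constant in the law"
            )
        expected = sorted(
            [name for name, stoich in reactants for _ in range(stoich)]
            + ([enzyme] if enzyme else [])
        )
        actual = sorted(f for f in factors if f not in rate_constants)
        if expected != actual:
            raise UnsupportedKineticLawError(
                f"reaction {rid}: law factors {actual} do not match mass action "
                f"over reactants and modifier {expected}"
            )
        reactions.append(Reaction(rid, reactants, products, param_factors[0],
                                  enzyme, rx_comp.get(rid, "plasma_membrane")))

    binding_pairs = [
        BindingPair(b["lipid"], b["bp"], b["complex"], b["k_on"], b["k_off"], b["bp_total"])
        for b in extra.get("binding", [])
    ]

    activation = None
    le = mdl.find(_s("listOfEvents"))
    if le is not None:
        events = {}
        for ev in le:
            trig = ev.find(_s("trigger"))
            apply = trig.find(_m("math")).find(_m("apply"))
            t = float(apply.find(_m("cn")).text)
            assigns = {}
            for ea in ev.find(_s("listOfEventAssignments")):
                assigns[ea.get("variable")] = float(ea.find(_m("math")).find(_m("cn")).text)
            events[ev.get("id")] = (t, assigns)
        t_act, on = events.get("activation", (None, {}))
        if t_act is not None:
            switches = tuple(extra.get("rate_switches")
                             or [k for k in on if k in rate_constants])
            if "termination" in events:
                t_off = events["termination"][0]
                activation = ActivationScheme(
                    t_act, on.get("Ra", 0.0), switches, "reset", t_off - t_act
                )
            else:
                activation = ActivationScheme(
                    t_act, on.get("Ra", 0.0), switches, "inactivation", 300.0
                )

    model = ModelDefinition(
        mdl.get("id") or "sbml_model", compartments, species, rate_constants,
        reactions, binding_pairs, activation, dict(extra.get("metadata", {})),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, serialisable to YAML."""

    model_path: str | None = None
    proteome_paths: dict[str, str] = field(default_factory=dict)
    geometry: dict[str, float] = field(default_factory=dict)
    t_activation: float = 100.0
    receptor_count: float = 5000.0
    t_end: float = 2000.0
    output_dir: str = "."
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-6
    fold_band: float = 5.0

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
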