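"""SBML Level 3 export/import of expanded networks.

The exchange format is deliberately minimal: compartments, species,
parameters and reactions whose kinetic laws are MathML products of a rate
constant, reactant/modifier concentrations, input-activity placeholders
(parameters named ``input_<node>``, with ``1 - input_<node>`` for
inhibitory factors), the DNA capacity factor ``(2 - DNA)`` and the
PD0332991 flag ``cdk4_activity_factor``.  The reader inverts exactly this
subset, so export -> import -> simulate reproduces trajectories; it is not
a general-purpose SBML consumer.
"""

from __future__ import annotations

import re

from lxml import etree

from .network import Reaction, ReactionNetwork, Species
from .parameters import ParameterSet

__all__ = ["write_sbml", "read_sbml", "species_from_name"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sanitize(name: str) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
    return sid if re.match(r"[A-Za-z_]", sid) else "s_" + sid


def species_from_name(name: str) -> Species:
    """Parse a canonical species name back into a :class:`Species`."""
    comp, _, body = name.partition(":")
    mols = []
    for token in body.split("."):
        m = re.fullmatch(r"(\w+)(?:\(([^)]*)\))?", token)
        if not m:
            raise ValueError(f"cannot parse species token {token!r} in {name!r}")
        sites = ()
        if m.group(2):
            sites = tuple(
                tuple(kv.split("~")) for kv in m.group(2).split(",")
            )
        mols.append((m.group(1), tuple(sorted(sites))))
    return Species.make(comp, mols)


def write_sbml(
    network: ReactionNetwork,
    path: str,
    params: ParameterSet | None = None,
    model_id: str = "g1s_transition",
) -> None:
    """Serialize the expanded network (and, optionally, parameter values)
    to an SBML L3V2 file."""
    E = lambda tag, **kw: etree.SubElement(parent_stack[-1], f"{{{SBML_NS}}}{tag}", **kw)  # noqa: E731
    root = etree.Element(f"{{{SBML_NS}}}sbml", level="3", version="2")
    parent_stack = [root]
    model = E("model", id=model_id)
    parent_stack.append(model)

    state_names = network.state_names()
    sid = {name: f"S{i}" for i, name in enumerate(state_names)}
    compartments = sorted({s.compartment for s in network.species} | {"cell"})

    lst = E("listOfCompartments")
    parent_stack.append(lst)
    for comp in compartments:
        E("compartment", id=comp, constant="true", size="1")
    parent_stack.pop()

    lst = E("listOfSpecies")
    parent_stack.append(lst)
    for s in network.species:
        E(
            "species", id=sid[s.name], name=s.name, compartment=s.compartment,
            initialAmount="0", hasOnlySubstanceUnits="true",
            boundaryCondition="false", constant="false",
        )
    if network.dna_species_name in sid:
        E(
            "species", id=sid[network.dna_species_name],
            name=network.dna_species_name, compartment="cell",
            initialAmount="1", hasOnlySubstanceUnits="true",
            boundaryCondition="false", constant="false",
        )
    parent_stack.pop()

    lst = E("listOfParameters")
    parent_stack.append(lst)
    values = params.values if params is not None else {}
    for p in network.kinetic_params:
        E("parameter", id=p, value=repr(float(values.get(p, 1.0))), constant="true")
    input_nodes = sorted(
        {tok.lstrip("~") for r in network.reactions for tok in r.input_factors}
    )
    for node in input_nodes:
        E("parameter", id=f"input_{node}", value="0", constant="false")
    if any(r.cdk4_catalyzed for r in network.reactions):
        E("parameter", id="cdk4_activity_factor", value="1", constant="false")
    parent_stack.pop()

    lst = E("listOfReactions")
    parent_stack.append(lst)
    for rxn in network.reactions:
        r_el = E("reaction", id=rxn.rxn_id, name=rxn.rule_id, reversible="false")
        parent_stack.append(r_el)
        if rxn.reactants:
            refs = E("listOfReactants")
            parent_stack.append(refs)
            for sp in rxn.reactants:
                E("speciesReference", species=sid[sp], stoichiometry="1", constant="true")
            parent_stack.pop()
        if rxn.products:
            refs = E("listOfProducts")
            parent_stack.append(refs)
            for sp in rxn.products:
                E("speciesReference", species=sid[sp], stoichiometry="1", constant="true")
            parent_stack.pop()
        if rxn.modifiers:
            refs = E("listOfModifiers")
            parent_stack.append(refs)
            for sp in rxn.modifiers:
                E("modifierSpeciesReference", species=sid[sp])
            parent_stack.pop()
        kl = E("kineticLaw")
        parent_stack.append(kl)
        kl.append(_rate_math(rxn, sid, network.dna_species_name))
        parent_stack.pop()
        parent_stack.pop()
    parent_stack.pop()

    etree.ElementTree(root).write(
        path, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _ci(text: str) -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}ci")
    el.text = f" {text} "
    return el


def _cn(value: float) -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}cn")
    el.text = f" {value:g} "
    return el


def _rate_math(rxn: Reaction, sid: dict[str, str], dna_name: str) -> etree._Element:
    math = etree.Element(f"{{{MATHML_NS}}}math")
    factors: list[etree._Element] = [_ci(rxn.rate_param)]
    for sp in rxn.reactants:
        factors.append(_ci(sid[sp]))
    for sp in rxn.modifiers:
        factors.append(_ci(sid[sp]))
    for tok in rxn.input_factors:
        if tok.startswith("~"):
            minus = etree.Element(f"{{{MATHML_NS}}}apply")
            etree.SubElement(minus, f"{{{MATHML_NS}}}minus")
            minus.append(_cn(1.0))
            minus.append(_ci(f"input_{tok[1:]}"))
            factors.append(minus)
        else:
            factors.append(_ci(f"input_{tok}"))
    if rxn.dna_capped:
        minus = etree.Element(f"{{{MATHML_NS}}}apply")
        etree.SubElement(minus, f"{{{MATHML_NS}}}minus")
        minus.append(_cn(2.0))
        minus.append(_ci(sid[dna_name]))
        factors.append(minus)
    if rxn.cdk4_catalyzed:
        factors.append(_ci("cdk4_activity_factor"))
    if len(factors) == 1:
        math.append(factors[0])
    else:
        apply = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply, f"{{{MATHML_NS}}}times")
        for f in factors:
            apply.append(f)
    return math


def read_sbml(path: str) -> tuple[ReactionNetwork, dict[str, float]]:
    """Read a file produced by :func:`write_sbml`.

    Returns the reconstructed network and the kinetic parameter values
    stored in the file (observable maps are re-attached by the caller,
    e.g. via :func:`hepg1s.rules.attach_observables`).
    """
    tree = etree.parse(path)
    ns = {"s": SBML_NS, "m": MATHML_NS}

    id_to_name: dict[str, str] = {}
    species: list[Species] = []
    dna_name = "DNA"
    for el in tree.findall(".//s:listOfSpecies/s:species", ns):
        name = el.get("name") or el.get("id")
        id_to_name[el.get("id")] = name
        if float(el.get("initialAmount", "0")) == 1.0 and ":" not in name:
            dna_name = name
        else:
            species.append(species_from_name(name))

    params: dict[str, float] = {}
    for el in tree.findall(".//s:listOfParameters/s:parameter", ns):
        pid = el.get("id")
        if pid.startswith("input_") or pid == "cdk4_activity_factor":
            continue
        params[pid] = float(el.get("value", "1"))

    reactions: list[Reaction] = []
    for el in tree.findall(".//s:listOfReactions/s:reaction", ns):
        reactants = tuple(
            id_to_name[r.get("species")]
            for r in el.findall("s:listOfReactants/s:speciesReference", ns)
        )
        products = tuple(
            id_to_name[r.get("species")]
            for r in el.findall("s:listOfProducts/s:speciesReference", ns)
        )
        modifiers = tuple(
            id_to_name[r.get("species")]
            for r in el.findall("s:listOfModifiers/s:modifierSpeciesReference", ns)
        )
        rate_param, input_factors, dna_capped, cdk4 = _parse_math(
            el.find("s:kineticLaw/m:math", ns), ns, set(params), dna_name, id_to_name
        )
        reactions.append(
            Reaction(
                rxn_id=el.get("id"), rule_id=el.get("name") or el.get("id"),
                rate_param=rate_param, reactants=reactants, products=products,
                modifiers=modifiers, input_factors=tuple(input_factors),
                dna_capped=dna_capped, cdk4_catalyzed=cdk4,
            )
        )
    net = ReactionNetwork(sorted(species), reactions, dna_species_name=dna_name)
    return net, params


def _parse_math(math, ns, param_ids, dna_name, id_to_name):
    rate_param = None
    input_factors: list[str] = []
    dna_capped = False
    cdk4 = False
    if math is None:
        raise ValueError("reaction without kinetic law")
    cis = [c.text.strip() for c in math.iter(f"{{{MATHML_NS}}}ci")]
    applies = math.findall(f".//{{{MATHML_NS}}}apply")
    # inner (minus ...) applications: inhibitory input factors or DNA cap
    for ap in applies:
        children = list(ap)
        if children and children[0].tag == f"{{{MATHML_NS}}}minus":
            const = float(children[1].text)
            ref = children[2].text.strip()
            if id_to_name.get(ref) == dna_name and const == 2.0:
                dna_capped = True
            else:
                input_factors.append("~" + ref.removeprefix("input_"))
            cis = [c for c in cis if c != ref]
    for token in cis:
        if token == "cdk4_activity_factor":
            cdk4 = True
        elif token.startswith("input_"):
            input_factors.append(token.removeprefix("input_"))
        elif token in param_ids and rate_param is None:
            rate_param = token
    if rate_param is None:
        raise ValueError("kinetic law without rate parameter")
    return rate_param, input_factors, dna_capped, cdk4
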