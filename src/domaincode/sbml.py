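"""SBML Level 3 export of compiled reaction networks.

Writes the SBML L3V2 core subset a mass-action CRN needs: one compartment,
species with initial concentrations, and irreversible reactions whose
kinetic laws are MathML products ``k * c_1 [* c_2]`` with the rate constant
as a local parameter.  :func:`read_sbml` parses any L3 core document of
that shape back into plain dictionaries, which is what the round-trip
checks use.
"""

from __future__ import annotations

import re
from typing import Optional

from lxml import etree

from .errors import DomainCodeError

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_S = "{%s}" % SBML_NS
_M = "{%s}" % MATHML_NS


def _sanitize(name: str, taken: set[str]) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "s_" + sid
    base, k = sid, 1
    while sid in taken:
        k += 1
        sid = f"{base}_{k}"
    taken.add(sid)
    return sid


def sbml_document(crn) -> etree._ElementTree:
    """Build the SBML document for a compiled CRN."""
    root = etree.Element(_S + "sbml", nsmap={None: SBML_NS})
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, _S + "model")
    taken: set[str] = set()
    model.set("id", _sanitize(
        getattr(crn.netlist, "name", None) or "crn", taken))

    compartments = etree.SubElement(model, _S + "listOfCompartments")
    comp = etree.SubElement(compartments, _S + "compartment")
    comp.set("id", "cell")
    comp.set("size", "1")
    comp.set("spatialDimensions", "3")
    comp.set("constant", "true")
    taken.add("cell")

    sid_of: dict[int, str] = {}
    if crn.species:
        species_list = etree.SubElement(model, _S + "listOfSpecies")
        for sp in crn.species:
            sid = _sanitize(sp.name, taken)
            sid_of[id(sp)] = sid
            el = etree.SubElement(species_list, _S + "species")
            el.set("id", sid)
            el.set("name", sp.name)
            el.set("compartment", "cell")
            el.set("initialConcentration", repr(float(sp.init_conc)))
            el.set("hasOnlySubstanceUnits", "false")
            el.set("boundaryCondition", "false")
            el.set("constant", "false")

    if crn.reactions:
        reactions_list = etree.SubElement(model, _S + "listOfReactions")
        for i, rxn in enumerate(crn.reactions):
            el = etree.SubElement(reactions_list, _S + "reaction")
            el.set("id", f"r{i + 1}")
            if rxn.label:
                el.set("name", rxn.label)
            el.set("reversible", "false")
            reactants = etree.SubElement(el, _S + "listOfReactants")
            for sp in rxn.reactants:
                ref = etree.SubElement(reactants, _S + "speciesReference")
                ref.set("species", sid_of[id(sp)])
                ref.set("stoichiometry", "1")
                ref.set("constant", "true")
            products = etree.SubElement(el, _S + "listOfProducts")
            for sp in rxn.products:
                ref = etree.SubElement(products, _S + "speciesReference")
                ref.set("species", sid_of[id(sp)])
                ref.set("stoichiometry", "1")
                ref.set("constant", "true")
            law = etree.SubElement(el, _S + "kineticLaw")
            math = etree.SubElement(law, _M + "math", nsmap={None: MATHML_NS})
            apply_ = etree.SubElement(math, _M + "apply")
            etree.SubElement(apply_, _M + "times")
            ci = etree.SubElement(apply_, _M + "ci")
            ci.text = "k"
            for sp in rxn.reactants:
                ci = etree.SubElement(apply_, _M + "ci")
                ci.text = sid_of[id(sp)]
            locals_ = etree.SubElement(law, _S + "listOfLocalParameters")
            param = etree.SubElement(locals_, _S + "localParameter")
            param.set("id", "k")
            param.set("value", repr(float(rxn.rate)))
    return etree.ElementTree(root)


def write_sbml(crn, path: Optional[str] = None) -> str:
    """Serialise a CRN to SBML; returns the XML text, optionally writing it.

    I/O problems surface as :class:`OSError`; malformed CRN content raises
    :class:`DomainCodeError` subclasses before any file is touched.
    """
    doc = sbml_document(crn)
    text = etree.tostring(doc, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_sbml(source) -> dict:
    """Parse an SBML L3 core document into plain dictionaries.

    ``source`` is a path or file-like object.  Returns ``{"model_id",
    "species": [{"id", "name", "initial_concentration"}], "reactions":
    [{"id", "reactants", "products", "rate"}]}``.
    """
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise DomainCodeError(f"not a parsable SBML document: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise DomainCodeError("document root is not <sbml>")
    model = next((el for el in root if _local(el.tag) == "model"), None)
    if model is None:
        raise DomainCodeError("SBML document has no <model>")
    out = {"model_id": model.get("id"), "species": [], "reactions": []}
    for el in model.iter():
        tag = _local(el.tag)
        if tag == "species":
            conc = el.get("initialConcentration")
            out["species"].append({
                "id": el.get("id"),
                "name": el.get("name"),
                "initial_concentration": float(conc) if conc else 0.0,
            })
        elif tag == "reaction":
            rxn = {"id": el.get("id"), "reactants": [], "products": [],
                   "rate": None}
            for child in el.iter():
                ctag = _local(child.tag)
                if ctag == "speciesReference":
                    parent = _local(child.getparent().tag)
                    if parent == "listOfReactants":
                        rxn["reactants"].append(child.get("species"))
                    elif parent == "listOfProducts":
                        rxn["products"].append(child.get("species"))
                elif ctag == "localParameter" and child.get("id") == "k":
                    rxn["rate"] = float(child.get("value"))
            out["reactions"].append(rxn)
    return out


def export_sbml(crn, path: Optional[str] = None) -> str:
    """Alias mirroring the compiler-facing export name."""
    return write_sbml(crn, path)
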