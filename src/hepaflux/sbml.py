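"""SBML Level 3 export of model documents.

Dynamic reactions carry their kinetic law as content MathML (generated
symbolically); static-module membership and zonation overrides are recorded
as annotations, since SBML has no native notion of a pseudo-steady-state
module.  The writer emits plain SBML L3V2 core, readable by any standard
SBML library.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import sympy as sp
from sympy.printing.mathml import MathMLContentPrinter

from .document import ModelDocument
from .ratelaws import RateLaw

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://hepaflux.readthedocs.io/annotations"


class SbmlExportError(ValueError):
    pass


def symbolic_rate(law: RateLaw) -> tuple[sp.Expr, dict[str, float]]:
    """Sympy expression for a rate law plus its local-parameter values.

    Species appear as symbols named by their id; parameters as symbols whose
    values are returned for the kineticLaw's listOfLocalParameters
    (modifier parameters are prefixed with the effector species id).
    """
    p = {k: sp.Symbol(k) for k in law.parameters}
    values = dict(law.parameters)
    S = {s: sp.Symbol(s) for s in set(law.substrates) | set(law.products)}

    def km(species):
        return p[f"Km_{species}"] if f"Km_{species}" in p else p["Km"]

    if law.form == "zero_order":
        expr = p["rate"]
    elif law.form == "mass_action":
        expr = p["k"]
        for s in law.substrates:
            expr *= S[s]
    elif law.form in ("michaelis_menten", "inhibited_mm"):
        expr = p["Vmax"]
        for s in law.substrates:
            expr *= S[s] / (km(s) + S[s])
        for name in law.parameters:
            if name.startswith("Ki_"):
                expr /= 1 + sp.Symbol(name[3:]) / p[name]
    elif law.form == "hill":
        s = sp.Symbol(law.substrates[0])
        n = p.get("n", sp.Integer(1))
        s50 = p.get("S50", p.get("Km"))
        expr = p["Vmax"] * s**n / (s50**n + s**n)
    elif law.form == "reversible_michaelis_menten":
        fwd, den_s = sp.Integer(1), sp.Integer(1)
        for s in law.substrates:
            r = S[s] / km(s)
            fwd *= r
            den_s *= 1 + r
        rev, den_p = 1 / p.get("keq", sp.Integer(1)), sp.Integer(1)
        for q in law.products:
            r = S[q] / km(q)
            rev *= r
            den_p *= 1 + r
        expr = p["Vmax"] * (fwd - rev) / (den_s + den_p - 1)
    else:  # pragma: no cover
        raise SbmlExportError(f"form {law.form!r} has no SBML serialisation")

    for mod in law.modifiers:
        m = sp.Symbol(mod.species)
        q = {k: sp.Symbol(f"{mod.species}_{k}") for k in mod.params}
        values.update({f"{mod.species}_{k}": v for k, v in mod.params.items()})
        if mod.kind == "activation":
            expr *= 1 + q.get("a", sp.Integer(1)) * m / (q["Ka"] + m)
        elif mod.kind == "activation_hill":
            n = q.get("n", sp.Integer(2))
            expr *= 1 + q.get("a", sp.Integer(1)) * m**n / (q["Ka"] ** n + m**n)
        else:
            expr *= 1 / (1 + m / q["Ki"])
    return expr, values


class _PlainSymbolPrinter(MathMLContentPrinter):
    """Content MathML with identifiers kept verbatim (no subscript markup)."""

    def _print_Symbol(self, sym):
        ci = self.dom.createElement("ci")
        ci.appendChild(self.dom.createTextNode(sym.name))
        return ci


def _mathml(expr: sp.Expr) -> ET.Element:
    printer = _PlainSymbolPrinter()
    xml_str = printer.doprint(expr)
    return ET.fromstring(f'<math xmlns="{MATHML_NS}">{xml_str}</math>')


def export_sbml(doc: ModelDocument, path: str | Path) -> None:
    """Write the document as an SBML Level 3 Version 2 file."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": "hepaflux_model"})

    compartments = sorted({m.compartment for m in doc.metabolites})
    loc = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for c in compartments:
        ET.SubElement(
            loc, f"{{{SBML_NS}}}compartment",
            {"id": c, "constant": "true", "size": "1", "spatialDimensions": "3"},
        )

    los = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for m in doc.metabolites:
        ET.SubElement(
            los, f"{{{SBML_NS}}}species",
            {
                "id": m.id,
                "name": m.name or m.id,
                "compartment": m.compartment,
                "initialConcentration": repr(float(m.initial)),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "true" if m.boundary else "false",
                "constant": "false",
            },
        )

    zone_overrides: dict[str, list[tuple[str, str, float]]] = {}
    for zone, overrides in doc.zones.items():
        for (rid, pname), value in overrides.items():
            zone_overrides.setdefault(rid, []).append((zone, pname, value))

    lor = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rxn in doc.reactions:
        r = ET.SubElement(
            lor, f"{{{SBML_NS}}}reaction",
            {"id": rxn.id, "name": rxn.name or rxn.id, "reversible": "true"},
        )
        annot = ET.SubElement(r, f"{{{SBML_NS}}}annotation")
        info = ET.SubElement(annot, f"{{{ANNOT_NS}}}info")
        extra = ET.SubElement(info, f"{{{ANNOT_NS}}}module")
        extra.set("kind", rxn.module)
        for zone, pname, value in zone_overrides.get(rxn.id, []):
            z = ET.SubElement(info, f"{{{ANNOT_NS}}}zonation")
            z.set("zone", zone)
            z.set("parameter", pname)
            z.set("value", repr(float(value)))

        reactants = {s: -c for s, c in rxn.stoichiometry.items() if c < 0}
        products = {s: c for s, c in rxn.stoichiometry.items() if c > 0}
        if reactants:
            lr = ET.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for s, c in reactants.items():
                ET.SubElement(
                    lr, f"{{{SBML_NS}}}speciesReference",
                    {"species": s, "stoichiometry": repr(float(c)), "constant": "true"},
                )
        if products:
            lp = ET.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for s, c in products.items():
                ET.SubElement(
                    lp, f"{{{SBML_NS}}}speciesReference",
                    {"species": s, "stoichiometry": repr(float(c)), "constant": "true"},
                )
        if rxn.rate_law is not None:
            law = rxn.rate_law
            refs = set(law.substrates) | set(law.products) | {
                m.species for m in law.modifiers
            }
            mods = refs - set(reactants) - set(products)
            if mods:
                lm = ET.SubElement(r, f"{{{SBML_NS}}}listOfModifiers")
                for s in sorted(mods):
                    ET.SubElement(
                        lm, f"{{{SBML_NS}}}modifierSpeciesReference", {"species": s}
                    )
            try:
                expr, values = symbolic_rate(law)
            except KeyError as exc:
                raise SbmlExportError(
                    f"reaction {rxn.id}: unserialisable rate law ({exc})"
                ) from exc
            kl = ET.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
            kl.append(_mathml(expr))
            llp = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
            for name, value in values.items():
                ET.SubElement(
                    llp, f"{{{SBML_NS}}}localParameter",
                    {"id": name, "value": repr(float(value))},
                )

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")
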