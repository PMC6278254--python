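"""Minimal SBML Level 3 Version 2 writer for mass-action CRNs.

Species are exported with sanitized ids and their canonical DSD text in the
``name`` attribute; every reaction carries a mass-action kinetic law.  The
output is deliberately a small, valid subset of SBML (no units beyond
defaults, no compartment geometry).
"""

from __future__ import annotations

from xml.sax.saxutils import escape

__all__ = ["crn_to_sbml"]


def _mathml_mass_action(kid: str, reactant_ids: list[str]) -> str:
    terms = [f"<ci> {kid} </ci>"] + [f"<ci> {r} </ci>" for r in reactant_ids]
    if len(terms) == 1:
        body = terms[0]
    else:
        body = "<apply><times/>" + "".join(terms) + "</apply>"
    return (
        '<math xmlns="http://www.w3.org/1998/Math/MathML">' + body + "</math>"
    )


def crn_to_sbml(crn) -> str:
    ids = {sp: f"s{i}" for i, sp in enumerate(crn.species)}
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" '
        'level="3" version="2">',
        '  <model id="dsd_crn" substanceUnits="nanomole" timeUnits="second">',
        "    <listOfCompartments>",
        '      <compartment id="sol" spatialDimensions="3" size="1" constant="true"/>',
        "    </listOfCompartments>",
        "    <listOfSpecies>",
    ]
    for sp, conc in crn.species.items():
        lines.append(
            f'      <species id="{ids[sp]}" name="{escape(sp.render(), {chr(34): "&quot;"})}" '
            f'compartment="sol" initialConcentration="{conc:g}" '
            'hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>'
        )
    lines.append("    </listOfSpecies>")
    lines.append("    <listOfParameters>")
    for j, rx in enumerate(crn.reactions):
        lines.append(
            f'      <parameter id="k{j}" value="{rx.rate:g}" constant="true"/>'
        )
    lines.append("    </listOfParameters>")
    lines.append("    <listOfReactions>")
    for j, rx in enumerate(crn.reactions):
        lines.append(f'      <reaction id="r{j}" reversible="false">')
        lines.append("        <listOfReactants>")
        for sp in rx.reactants:
            lines.append(
                f'          <speciesReference species="{ids[sp]}" stoichiometry="1" constant="true"/>'
            )
        lines.append("        </listOfReactants>")
        lines.append("        <listOfProducts>")
        for sp in rx.products:
            lines.append(
                f'          <speciesReference species="{ids[sp]}" stoichiometry="1" constant="true"/>'
            )
        lines.append("        </listOfProducts>")
        lines.append("        <kineticLaw>")
        lines.append(
            "          " + _mathml_mass_action(f"k{j}", [ids[s] for s in rx.reactants])
        )
        lines.append("        </kineticLaw>")
        lines.append("      </reaction>")
    lines.append("    </listOfReactions>")
    lines.append("  </model>")
    lines.append("</sbml>")
    return "\n".join(lines) + "\n"
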