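"""SBML Level 3 serialization of the configured reaction network.

Writes the network as a standard SBML Level 3 Version 2 core document:
one compartment (the homogenate), the 11 species, global Km/Vmax
parameters, and one irreversible reaction per active LOX-isozyme x
isomer branch plus the two HPL cleavage reactions, each carrying its
Michaelis-Menten kinetic law as MathML.  Concentrations are nmol/mL
and time is minutes, matching the rest of the package.

:func:`validate_sbml` is a structural consistency checker (document
shape, id uniqueness, reference integrity, kinetic-law math); it is
what the round-trip test runs against the exported document.
"""

from __future__ import annotations

from lxml import etree

from .parameters import ISOMERS, LOX_ISOZYMES, ModelConfig
from .pathway import SPECIES

__all__ = ["export_sbml", "validate_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_S = "{%s}" % SBML_NS
_M = "{%s}" % MATHML_NS


def _species_id(name: str) -> str:
    # SBML SIds must not start with a digit
    return f"M_{name}"


def _math_mm(vmax_ci: str, km_ci: str, substrate_ci: str, scale_ci: str | None):
    """MathML for scale * vmax * S / (km + S)."""
    math = etree.Element(_M + "math")
    divide = etree.SubElement(math, _M + "apply")
    etree.SubElement(divide, _M + "divide")
    num = etree.SubElement(divide, _M + "apply")
    etree.SubElement(num, _M + "times")
    for sym in filter(None, (scale_ci, vmax_ci, substrate_ci)):
        ci = etree.SubElement(num, _M + "ci")
        ci.text = sym
    den = etree.SubElement(divide, _M + "apply")
    etree.SubElement(den, _M + "plus")
    for sym in (km_ci, substrate_ci):
        ci = etree.SubElement(den, _M + "ci")
        ci.text = sym
    return math


def _add_species_ref(parent, tag: str, species: str) -> None:
    ref = etree.SubElement(parent, _S + tag)
    ref.set("species", _species_id(species))
    ref.set("stoichiometry", "1")
    ref.set("constant", "true")


def export_sbml(config: ModelConfig) -> bytes:
    """Serialize the configured network to an SBML L3V2 document."""
    sbml = etree.Element(_S + "sbml", nsmap={None: SBML_NS})
    sbml.set("level", "3")
    sbml.set("version", "2")
    model = etree.SubElement(sbml, _S + "model")
    model.set("id", "soybean_lox_pathway")
    model.set("name", "Soybean LOX/HPL n-hexanal pathway")
    model.set("timeUnits", "time")

    comps = etree.SubElement(model, _S + "listOfCompartments")
    comp = etree.SubElement(comps, _S + "compartment")
    comp.set("id", "homogenate")
    comp.set("size", "1")
    comp.set("spatialDimensions", "3")
    comp.set("constant", "true")

    species_list = etree.SubElement(model, _S + "listOfSpecies")
    for name in SPECIES:
        sp = etree.SubElement(species_list, _S + "species")
        sp.set("id", _species_id(name))
        sp.set("name", name)
        sp.set("compartment", "homogenate")
        init = config.initial_la if name == "LA" else 0.0
        sp.set("initialConcentration", repr(init))
        sp.set("hasOnlySubstanceUnits", "false")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")

    params = etree.SubElement(model, _S + "listOfParameters")

    def _param(pid: str, value: float) -> None:
        p = etree.SubElement(params, _S + "parameter")
        p.set("id", pid)
        p.set("value", repr(value))
        p.set("constant", "true")

    active = [iso for iso in LOX_ISOZYMES if config.genotype.has(iso)]
    for iso in active:
        _param(f"Km_{iso}", config.kinetics[iso].km)
        _param(f"Vmax_{iso}", config.kinetics[iso].vmax_scaled)
    if config.hpl_enabled:
        for eid in ("HPL_SZE", "HPL_RZE"):
            _param(f"Km_{eid}", config.kinetics[eid].km)
            _param(f"Vmax_{eid}", config.kinetics[eid].vmax_scaled)

    reactions = etree.SubElement(model, _S + "listOfReactions")

    # one branch reaction per active isozyme x isomer:
    # LA -> isomer at rate f_ij * Vmax_i * LA / (Km_i + LA)
    for iso in active:
        frac = config.ratios.normalized(iso)
        for isomer in ISOMERS:
            rxn = etree.SubElement(reactions, _S + "reaction")
            rxn.set("id", f"R_{iso}_{isomer}")
            rxn.set("reversible", "false")
            reactants = etree.SubElement(rxn, _S + "listOfReactants")
            _add_species_ref(reactants, "speciesReference", "LA")
            products = etree.SubElement(rxn, _S + "listOfProducts")
            _add_species_ref(products, "speciesReference", isomer)
            klaw = etree.SubElement(rxn, _S + "kineticLaw")
            klaw.append(
                _math_mm(f"Vmax_{iso}", f"Km_{iso}", _species_id("LA"), "branch_fraction")
            )
            locals_ = etree.SubElement(klaw, _S + "listOfLocalParameters")
            lp = etree.SubElement(locals_, _S + "localParameter")
            lp.set("id", "branch_fraction")
            lp.set("value", repr(frac[isomer]))

    # HPL cleavage: isomer -> hexanal + oxoacid
    if config.hpl_enabled:
        for eid, substrate in (("HPL_SZE", "13HOD_SZE"), ("HPL_RZE", "13HOD_RZE")):
            rxn = etree.SubElement(reactions, _S + "reaction")
            rxn.set("id", f"R_{eid}")
            rxn.set("reversible", "false")
            reactants = etree.SubElement(rxn, _S + "listOfReactants")
            _add_species_ref(reactants, "speciesReference", substrate)
            products = etree.SubElement(rxn, _S + "listOfProducts")
            _add_species_ref(products, "speciesReference", "hexanal")
            _add_species_ref(products, "speciesReference", "oxoacid")
            klaw = etree.SubElement(rxn, _S + "kineticLaw")
            klaw.append(
                _math_mm(f"Vmax_{eid}", f"Km_{eid}", _species_id(substrate), None)
            )

    return etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def validate_sbml(document: bytes | str) -> list[str]:
    """Structural consistency check of an SBML document.

    Returns a list of error messages; an empty list means the document
    passed every check (well-formed XML, L3 root, unique ids, species
    and parameter references resolve, every reaction carries kinetic
    math whose symbols are declared).
    """
    errors: list[str] = []
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        return [f"XML parse error: {exc}"]

    if root.tag != _S + "sbml":
        return [f"root element is {root.tag!r}, expected SBML level-3 core"]
    if root.get("level") != "3":
        errors.append("document is not SBML level 3")

    model = root.find(_S + "model")
    if model is None:
        return errors + ["missing <model>"]

    comp_ids = {c.get("id") for c in model.iter(_S + "compartment")}
    species_ids = [s.get("id") for s in model.iter(_S + "species")]
    if len(species_ids) != len(set(species_ids)):
        errors.append("duplicate species ids")
    param_ids = {p.get("id") for p in model.iter(_S + "parameter")}

    for sp in model.iter(_S + "species"):
        if sp.get("compartment") not in comp_ids:
            errors.append(
                f"species {sp.get('id')} references unknown compartment "
                f"{sp.get('compartment')!r}"
            )

    rxn_ids = []
    declared = set(species_ids) | param_ids
    for rxn in model.iter(_S + "reaction"):
        rid = rxn.get("id")
        rxn_ids.append(rid)
        for ref in rxn.iter(_S + "speciesReference"):
            if ref.get("species") not in species_ids:
                errors.append(
                    f"reaction {rid}: unknown species {ref.get('species')!r}"
                )
            stoich = float(ref.get("stoichiometry", "1"))
            if stoich <= 0:
                errors.append(f"reaction {rid}: non-positive stoichiometry")
        klaw = rxn.find(_S + "kineticLaw")
        if klaw is None:
            errors.append(f"reaction {rid}: missing kineticLaw")
            continue
        math = klaw.find(_M + "math")
        if math is None:
            errors.append(f"reaction {rid}: kineticLaw has no math")
            continue
        local_ids = {
            lp.get("id") for lp in klaw.iter(_S + "localParameter")
        }
        for ci in math.iter(_M + "ci"):
            sym = (ci.text or "").strip()
            if sym not in declared | local_ids:
                errors.append(f"reaction {rid}: undeclared symbol {sym!r}")
    if len(rxn_ids) != len(set(rxn_ids)):
        errors.append("duplicate reaction ids")
    return errors
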