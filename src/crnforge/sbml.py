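"""SBML Level 3 Version 1 export.

Every CRN species becomes one SBML species (id = sanitized canonical name,
initial concentration from the caller's map, default 0); every reaction is
written irreversible.  Mass-action kinetic laws are written as
``k * reactant1 * ...`` with ``k`` a local parameter; Hill and general
propensities become explicit rate formulas referencing reaction-scoped
global parameters, which keeps the documents plain L3V1 core and therefore
digestible by ordinary simulators.  No packages, no model history — output
is byte-stable across processes, so export/parse/re-export round-trips
exactly.
"""

from __future__ import annotations

from typing import Mapping

import libsbml

from .core import CRN, CRNForgeError, Reaction, Species

__all__ = ["sanitize_id", "export_sbml", "write_sbml", "validate_sbml", "SBMLExportError"]


class SBMLExportError(CRNForgeError):
    pass


def sanitize_id(name: str) -> str:
    """Map an arbitrary canonical name onto the SBML SId grammar.

    Letters, digits and underscores pass through; ``":"`` maps to ``"_"``;
    any other character to ``"_x<hex>_"``; a leading digit gets a ``"_"``
    prefix.  Distinct canonical names map to distinct ids.
    """
    if not name:
        raise SBMLExportError("cannot sanitize an empty name")
    out = []
    for ch in name:
        if ch.isascii() and (ch.isalnum() or ch == "_"):
            out.append(ch)
        elif ch == ":":
            out.append("_")
        else:
            out.append(f"_x{ord(ch):02x}_")
    if out[0].isdigit():
        out.insert(0, "_")
    return "".join(out)


def _check(value, message: str):
    if value is None:
        raise SBMLExportError(f"libsbml returned None: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise SBMLExportError(f"libsbml error {value}: {message}")
    return value


def _set_math(kinetic_law, formula: str):
    math_ast = libsbml.parseL3Formula(formula)
    if math_ast is None:
        raise SBMLExportError(f"could not parse rate formula {formula!r}")
    _check(kinetic_law.setMath(math_ast), f"setMath({formula})")


def _massaction_formula(reaction: Reaction) -> str:
    terms = ["k"]
    for sp, n in reaction.inputs:
        sid = sanitize_id(sp.canonical_name)
        terms.append(f"{sid}^{n}" if n > 1 else sid)
    return " * ".join(terms)


def _add_kinetic_law(model, sbml_reaction, reaction: Reaction, index: int):
    prop = reaction.propensity
    law = _check(sbml_reaction.createKineticLaw(), "createKineticLaw")
    if prop.kind == "massaction":
        param = _check(law.createLocalParameter(), "createLocalParameter")
        _check(param.setId("k"), "local parameter id")
        _check(param.setValue(prop.parameters["k"]), "local parameter value")
        _set_math(law, _massaction_formula(reaction))
        return
    # non-mass-action laws reference reaction-scoped global parameters
    suffix = f"r{index}"
    names = {}
    for pname, value in sorted(prop.parameters.items()):
        gid = sanitize_id(f"{pname}_{suffix}")
        gp = _check(model.createParameter(), "createParameter")
        _check(gp.setId(gid), "global parameter id")
        _check(gp.setValue(value), "global parameter value")
        _check(gp.setConstant(True), "global parameter constant")
        names[pname] = gid
    if prop.kind in ("hill_positive", "hill_negative"):
        r = sanitize_id(prop.regulator.canonical_name)
        d = sanitize_id(prop.scaler.canonical_name) if prop.scaler is not None else "1"
        k, K, n = names["k"], names["K"], names["n"]
        if prop.kind == "hill_negative":
            numerator = f"{K}^{n}"
        else:
            numerator = f"{r}^{n}"
        _set_math(law, f"{k} * {d} * {numerator} / ({K}^{n} + {r}^{n})")
    else:  # general expression: constants renamed to their global ids
        formula = prop.expression
        # token-wise replacement on word boundaries via the L3 parser round trip
        import re as _re
        def _sub(match):
            token = match.group(0)
            return names.get(token, token)
        formula = _re.sub(r"[A-Za-z_][A-Za-z0-9_]*", _sub, formula)
        _set_math(law, formula)


def _build_document(crn: CRN, initial: Mapping[Species, float] | None):
    initial = dict(initial or {})
    document = libsbml.SBMLDocument(3, 1)
    model = _check(document.createModel(), "createModel")
    _check(model.setId(sanitize_id(crn.name)), "model id")
    compartment = _check(model.createCompartment(), "createCompartment")
    _check(compartment.setId("default"), "compartment id")
    _check(compartment.setConstant(True), "compartment constant")
    _check(compartment.setSize(1.0), "compartment size")
    _check(compartment.setSpatialDimensions(3), "compartment dimensions")

    ids: dict[str, Species] = {}
    for sp in crn.species:
        sid = sanitize_id(sp.canonical_name)
        if sid in ids:
            raise SBMLExportError(
                f"sanitized id collision: {sp.display} and {ids[sid].display} "
                f"both map to {sid!r}"
            )
        ids[sid] = sp
        sbml_sp = _check(model.createSpecies(), "createSpecies")
        _check(sbml_sp.setId(sid), "species id")
        _check(sbml_sp.setName(sp.display), "species name")
        _check(sbml_sp.setCompartment("default"), "species compartment")
        _check(sbml_sp.setInitialConcentration(float(initial.get(sp, 0.0))),
               "species initial concentration")
        _check(sbml_sp.setBoundaryCondition(False), "species boundary")
        _check(sbml_sp.setConstant(False), "species constant")
        _check(sbml_sp.setHasOnlySubstanceUnits(False), "species units flag")

    for i, rx in enumerate(crn.reactions):
        sbml_rx = _check(model.createReaction(), "createReaction")
        _check(sbml_rx.setId(f"r{i}"), "reaction id")
        _check(sbml_rx.setReversible(False), "reaction reversible")
        _check(sbml_rx.setFast(False), "reaction fast")
        for sp, n in rx.inputs:
            ref = _check(sbml_rx.createReactant(), "createReactant")
            _check(ref.setSpecies(sanitize_id(sp.canonical_name)), "reactant species")
            _check(ref.setStoichiometry(float(n)), "reactant stoichiometry")
            _check(ref.setConstant(True), "reactant constant")
        for sp, n in rx.outputs:
            ref = _check(sbml_rx.createProduct(), "createProduct")
            _check(ref.setSpecies(sanitize_id(sp.canonical_name)), "product species")
            _check(ref.setStoichiometry(float(n)), "product stoichiometry")
            _check(ref.setConstant(True), "product constant")
        in_or_out = {sp for sp, _ in rx.inputs} | {sp for sp, _ in rx.outputs}
        for sp in rx.propensity.species:
            if sp not in in_or_out:
                mod = _check(sbml_rx.createModifier(), "createModifier")
                _check(mod.setSpecies(sanitize_id(sp.canonical_name)),
                       "modifier species")
        _add_kinetic_law(model, sbml_rx, rx, i)
    return document


def export_sbml(crn: CRN, initial: Mapping[Species, float] | None = None) -> str:
    """Serialize *crn* as an SBML L3V1 document (XML string)."""
    document = _build_document(crn, initial)
    return libsbml.writeSBMLToString(document)


def write_sbml(crn: CRN, path, initial: Mapping[Species, float] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(export_sbml(crn, initial))


def validate_sbml(xml: str) -> list[str]:
    """Run libsbml consistency checking; return error-severity messages."""
    document = libsbml.readSBMLFromString(xml)
    errors = []
    for i in range(document.getNumErrors()):
        err = document.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(err.getMessage().strip())
    document.checkConsistency()
    for i in range(document.getNumErrors()):
        err = document.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            msg = err.getMessage().strip()
            if msg not in errors:
                errors.append(msg)
    return errors
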