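"""SBML Level 3 + FBC v2 reader/writer for the restricted GSMM dialect.

Only the subset of SBML that genome-scale flux models actually use is
handled: one model, listOfCompartments/Species/Reactions, flux bounds as
FBC parameters, one active maximization objective, and
``fbc:geneProductAssociation`` and/or trees. Kinetic laws, events and rules
are out of scope.
"""

from __future__ import annotations

import os
import re

import libsbml

from .gpr import GeneRule
from .model import (DEFAULT_BOUND, Metabolite, MetabolicModel,
                    ModelValidationError, Reaction)

_SBML_ID_PREFIXES = ("M_", "R_", "G_")


def _strip(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _gpa_to_rule(assoc) -> GeneRule:
    return GeneRule.from_string(_assoc_string(assoc))


def _assoc_string(assoc) -> str:
    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return _strip(assoc.getGeneProduct(), "G_")
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_assoc_string(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_assoc_string(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise ModelValidationError(f"unsupported gene association node {type(assoc)!r}")


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML-FBC file into a :class:`MetabolicModel`.

    Bounds come from the FBC flux-bound parameters, the objective from the
    active FBC objective. Referential problems (a reaction naming a species
    absent from listOfSpecies, no active objective, an unparseable gene
    association) raise :class:`ModelValidationError` naming the culprit.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(f"SBML parse error in {path}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path}: no model element")
    fbc = sbml_model.getPlugin("fbc")

    params = {p.getId(): p.getValue() for p in sbml_model.getListOfParameters()}

    metabolites = []
    species_ids = set()
    for sp in sbml_model.getListOfSpecies():
        mid = _strip(sp.getId(), "M_")
        species_ids.add(sp.getId())
        sfbc = sp.getPlugin("fbc")
        formula = None
        charge = 0
        if sfbc is not None:
            if sfbc.isSetChemicalFormula():
                formula = sfbc.getChemicalFormula() or None
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
        metabolites.append(
            Metabolite(id=mid, name=sp.getName() or "", formula=formula,
                       charge=charge, compartment=sp.getCompartment() or "c")
        )

    genes: list[str] = []
    if fbc is not None:
        genes = [_strip(gp.getId(), "G_") for gp in fbc.getListOfGeneProducts()]

    reactions = []
    for rxn in sbml_model.getListOfReactions():
        rid = _strip(rxn.getId(), "R_")
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            if ref.getSpecies() not in species_ids:
                raise ModelValidationError(
                    f"reaction {rid!r} references unknown species {ref.getSpecies()!r}"
                )
            met = _strip(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            if ref.getSpecies() not in species_ids:
                raise ModelValidationError(
                    f"reaction {rid!r} references unknown species {ref.getSpecies()!r}"
                )
            met = _strip(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}

        rfbc = rxn.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        rule = GeneRule.empty()
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound(), lb)
            if rfbc.isSetUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound(), ub)
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                try:
                    rule = _gpa_to_rule(gpa.getAssociation())
                except Exception as exc:
                    raise ModelValidationError(
                        f"reaction {rid!r}: unparseable gene association"
                    ) from exc
        elif not rxn.getReversible():
            lb = 0.0
        reactions.append(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                     gene_rule=rule, name=rxn.getName() or "",
                     annotations=_read_annotations(rxn))
        )

    objective_id = None
    if fbc is not None and fbc.getActiveObjective() is not None:
        obj = fbc.getActiveObjective()
        for fo in obj.getListOfFluxObjectives():
            objective_id = _strip(fo.getReaction(), "R_")
    if objective_id is None:
        raise ModelValidationError(
            f"model {sbml_model.getId() or path!r} has no active objective"
        )

    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, genes=genes,
        objective_reaction_id=objective_id, name=sbml_model.getId() or "model",
    )


def _read_annotations(rxn) -> dict[str, str]:
    """Recover database annotations from identifiers.org CV terms."""
    out: dict[str, str] = {}
    for i in range(rxn.getNumCVTerms()):
        term = rxn.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            marker = "identifiers.org/"
            if marker in uri:
                tail = uri.split(marker, 1)[1]
                if "/" in tail:
                    db, ext = tail.split("/", 1)
                    out[db] = ext
    return out


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML L3V1 with the FBC v2 package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.name)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites}):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId("M_" + met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sfbc = sp.getPlugin("fbc")
        sfbc.setCharge(met.charge)
        if met.formula:
            sfbc.setChemicalFormula(met.formula)

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId("G_" + gene)
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def _param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId("R_" + rxn.id)
        sr.setName(rxn.name)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for met, coeff in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + met)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rfbc = sr.getPlugin("fbc")
        rfbc.setLowerFluxBound(_param_for(rxn.lower_bound))
        rfbc.setUpperFluxBound(_param_for(rxn.upper_bound))
        if not rxn.gene_rule.is_empty:
            gpa = rfbc.createGeneProductAssociation()
            # libsbml parses the infix dialect itself; prefix ids to match
            # the declared gene products.
            infix = rxn.gene_rule.to_string()
            for g in sorted(rxn.gene_rule.genes(), key=len, reverse=True):
                infix = re.sub(rf"\b{re.escape(g)}\b", "G_" + g, infix)
            gpa.setAssociation(infix, True, False)
        if rxn.annotations:
            sr.setMetaId("meta_R_" + rxn.id)
            cv = libsbml.CVTerm()
            cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
            cv.setBiologicalQualifierType(libsbml.BQB_IS)
            for db, ext in sorted(rxn.annotations.items()):
                cv.addResource(f"https://identifiers.org/{db}/{ext}")
            sr.addCVTerm(cv)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction("R_" + model.objective_reaction_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))
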