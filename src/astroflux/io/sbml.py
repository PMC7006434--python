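"""SBML Level 3 (core + fbc v2) reader/writer.

Scope is deliberately narrow: stoichiometry, bounds, GPR trees, formulas,
charges, compartments and the active objective — everything FBA needs.
Kinetic laws, rules, events and other constructs are skipped with a warning.

Identifiers are escaped to valid SBML SIds by replacing each character
outside ``[A-Za-z0-9_]`` with ``__<ord>__`` (and prefixing ``M_``/``R_``/
``G_``), so bracketed metabolite ids such as ``glu_L[e]`` survive a
write → read round trip exactly.
"""

from __future__ import annotations

import re
import warnings

import libsbml

from ..errors import AstrofluxError
from ..gpr import GPR
from ..model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = ["read_sbml", "write_sbml"]

_SID_OK = re.compile(r"[A-Za-z0-9_]")
_ESCAPE = re.compile(r"__(\d+)__")


def _escape(raw: str) -> str:
    return "".join(ch if _SID_OK.match(ch) else f"__{ord(ch)}__" for ch in raw)


def _unescape(sid: str) -> str:
    return _ESCAPE.sub(lambda m: chr(int(m.group(1))), sid)


def _check(value, message: str):
    if value is None:
        raise AstrofluxError(f"libsbml failure: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise AstrofluxError(f"libsbml failure ({value}): {message}")
    return value


# ---------------------------------------------------------------- writing


def write_sbml(model: MetabolicModel, path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    _check(sbml_model, "createModel")
    sbml_model.setId(_escape(model.name) or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    comps = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for comp in comps:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId("M_" + _escape(met.id))
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    genes = sorted({g for r in model.reactions for g in r.gpr.genes()})
    for gene in genes:
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _escape(gene))
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sbml_model.createReaction()
        sr.setId("R_" + _escape(rxn.id))
        sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        notes = []
        if rxn.subsystem:
            notes.append(f"SUBSYSTEM: {rxn.subsystem}")
        if rxn.kind:
            notes.append(f"KIND: {rxn.kind}")
        if notes:
            body = "".join(f"<p>{n}</p>" for n in notes)
            sr.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies("M_" + _escape(met_id))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            _write_association(gpa, rxn.gpr)

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _escape(model.objective_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise AstrofluxError(f"could not write SBML to {path}")


def _write_association(parent, gpr: GPR) -> None:
    node = _association_node(parent, gpr)
    _fill_association(node, gpr)


def _association_node(parent, gpr: GPR):
    if gpr.kind == "leaf":
        return parent.createGeneProductRef()
    if gpr.kind == "and":
        return parent.createAnd()
    if gpr.kind == "or":
        return parent.createOr()
    raise AstrofluxError(f"cannot serialize GPR node kind {gpr.kind!r}")


def _fill_association(node, gpr: GPR) -> None:
    if gpr.kind == "leaf":
        node.setGeneProduct("G_" + _escape(gpr.gene))
        return
    for child in gpr.children:
        _fill_association(_association_node(node, child), child)


# ---------------------------------------------------------------- reading


def read_sbml(path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise AstrofluxError(f"SBML parse error in {path}: {first.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise AstrofluxError(f"{path}: no model element")
    mplug = sbml_model.getPlugin("fbc")

    model = MetabolicModel(name=_unescape(sbml_model.getId()) or "model")

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        met_id = _unescape(_strip_prefix(sp.getId(), "M_"))
        formula, charge = None, None
        splug = sp.getPlugin("fbc")
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(id=met_id, name=sp.getName() or "", formula=formula, charge=charge)
        )

    gene_labels: dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _unescape(_strip_prefix(gp.getId(), "G_"))

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        if sr.isSetKineticLaw():
            warnings.warn(f"ignoring kinetic law on reaction {sr.getId()!r}")
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met_id = _unescape(_strip_prefix(ref.getSpecies(), "M_"))
            stoich[met_id] = stoich.get(met_id, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met_id = _unescape(_strip_prefix(ref.getSpecies(), "M_"))
            stoich[met_id] = stoich.get(met_id, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        lb, ub = (-DEFAULT_BOUND, DEFAULT_BOUND) if sr.getReversible() else (0.0, DEFAULT_BOUND)
        gpr = GPR.empty()
        rplug = sr.getPlugin("fbc")
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), ub)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = _read_association(gpa.getAssociation(), gene_labels)

        subsystem, kind = _parse_notes(sr)
        model.add_reaction(
            Reaction(
                id=_unescape(_strip_prefix(sr.getId(), "R_")),
                stoichiometry=stoich,
                name=sr.getName() or "",
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=subsystem,
                kind=kind,
            )
        )

    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            rid = obj.getFluxObjective(0).getReaction()
            model.objective_id = _unescape(_strip_prefix(rid, "R_"))

    for i in range(sbml_model.getNumRules()):
        warnings.warn("ignoring SBML rule (unsupported construct)")
    return model


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


_NOTE_P = re.compile(r"<p>\s*([A-Z]+)\s*:\s*(.*?)\s*</p>", re.S)


def _parse_notes(sr) -> tuple[str | None, str | None]:
    if not sr.isSetNotes():
        return None, None
    text = sr.getNotesString()
    subsystem = kind = None
    for key, value in _NOTE_P.findall(text):
        if key == "SUBSYSTEM":
            subsystem = value or None
        elif key == "KIND":
            kind = value or None
    return subsystem, kind


def _read_association(assoc, gene_labels: dict[str, str]) -> GPR:
    if assoc is None:
        return GPR.empty()
    if assoc.isGeneProductRef():
        gid = assoc.getGeneProduct()
        return GPR.leaf(gene_labels.get(gid, _unescape(_strip_prefix(gid, "G_"))))
    children = [
        _read_association(assoc.getAssociation(i), gene_labels)
        for i in range(assoc.getNumAssociations())
    ]
    if assoc.isFbcAnd():
        return GPR.and_(*children)
    if assoc.isFbcOr():
        return GPR.or_(*children)
    warnings.warn("unsupported GPR association node; skipping")
    return GPR.empty()
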