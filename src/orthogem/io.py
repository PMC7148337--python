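"""Model readers and writers: SBML Level-3 FBC v2 and a COBRA-style JSON dialect.

SBML handling goes through libsbml.  Identifiers follow the community
convention (``M_`` / ``R_`` / ``G_`` prefixes, non-SId characters escaped);
the original ids are recovered on read.  Writers emit sorted, deterministic
documents so that two saves of the same model are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import libsbml

from .gpr import (
    EMPTY,
    And,
    FalseLeaf,
    Gpr,
    Leaf,
    Or,
    gpr_to_string,
    make_and,
    make_or,
    parse_gpr,
)
from .model import Metabolite, MetabolicModel, Reaction

__all__ = ["load_model", "save_model"]


def load_model(path: str | Path, fmt: str | None = None) -> MetabolicModel:
    """Load a model from SBML-FBC (``sbml``) or the JSON dialect (``json``).

    The format is inferred from the file suffix when not given.  A model
    without a declared objective loads with ``objective_id = None`` and a
    warning; malformed stoichiometry is an error.
    """
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "sbml")
    if fmt == "json":
        return _load_json(path)
    if fmt == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path: str | Path, fmt: str | None = None) -> None:
    """Write a model; deterministic (sorted ids), valid SBML-FBC for ``sbml``."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "sbml")
    model.validate()
    if fmt == "json":
        path.write_text(_to_json(model))
    elif fmt == "sbml":
        path.write_text(_to_sbml(model))
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# JSON dialect (COBRA community schema field names)
# ---------------------------------------------------------------------------


def _to_json(model: MetabolicModel) -> str:
    doc = {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in sorted(model.metabolites.values(), key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lb,
                "upper_bound": r.ub,
                "gene_reaction_rule": gpr_to_string(r.gpr),
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
            }
            for r in sorted(model.reactions.values(), key=lambda r: r.id)
        ],
        "genes": [{"id": g} for g in sorted(model.genes)],
    }
    return json.dumps(doc, indent=1, sort_keys=False) + "\n"


def _load_json(path: Path) -> MetabolicModel:
    doc = json.loads(Path(path).read_text())
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", ""),
            formula=m.get("formula"),
            charge=m.get("charge"),
        )
        for m in doc["metabolites"]
    ]
    rxns = []
    objective_id = None
    for r in doc["reactions"]:
        stoich = {k: float(v) for k, v in r["metabolites"].items()}
        if not stoich:
            raise ValueError(f"reaction {r['id']!r}: malformed (empty) stoichiometry")
        rxns.append(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry=stoich,
                lb=float(r.get("lower_bound", -1000.0)),
                ub=float(r.get("upper_bound", 1000.0)),
                gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                subsystem=r.get("subsystem", ""),
            )
        )
        if r.get("objective_coefficient", 0.0):
            objective_id = r["id"]
    model = MetabolicModel(doc.get("id", "model"), mets, rxns)
    if objective_id is not None:
        model.set_objective(objective_id)
    else:
        warnings.warn(f"{path}: no objective declared; objective left unset")
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------

_SID_SAFE = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_")


def _sid(prefix: str, raw: str) -> str:
    out = [prefix]
    for ch in raw:
        out.append(ch if ch in _SID_SAFE else f"__{ord(ch)}__")
    sid = "".join(out)
    if sid and sid[0].isdigit():
        sid = "_" + sid
    return sid


def _unsid(prefix: str, sid: str) -> str:
    raw = sid[len(prefix):] if sid.startswith(prefix) else sid
    out = []
    i = 0
    while i < len(raw):
        if raw.startswith("__", i):
            j = raw.find("__", i + 2)
            mid = raw[i + 2 : j] if j != -1 else ""
            if j != -1 and mid.isdigit():
                out.append(chr(int(mid)))
                i = j + 2
                continue
        out.append(raw[i])
        i += 1
    return "".join(out)


def _check(value, message: str):
    if value is None:
        raise RuntimeError(f"libsbml error: {message}")
    return value


def _to_sbml(model: MetabolicModel) -> str:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid("", model.id) or "model")
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    compartments = sorted(
        {m.compartment or "c" for m in model.metabolites.values()}
    )
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(_sid("", comp))
        c.setConstant(True)

    for met in sorted(model.metabolites.values(), key=lambda m: m.id):
        sp = sbml_model.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sid("", met.compartment or "c"))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp_fbc = sp.getPlugin("fbc")
        if met.formula is not None:
            sp_fbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sp_fbc.setCharge(int(met.charge))

    bound_values = sorted(
        {r.lb for r in model.reactions.values()}
        | {r.ub for r in model.reactions.values()}
    )
    bound_ids: dict[float, str] = {}
    for k, value in enumerate(bound_values):
        pid = f"fb_{k}"
        bound_ids[value] = pid
        par = sbml_model.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)

    genes = sorted(model.genes)
    for gene in genes:
        gp = fbc.createGeneProduct()
        gp.setId(_sid("G_", gene))
        gp.setLabel(gene)

    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        sr = sbml_model.createReaction()
        sr.setId(_sid("R_", rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lb < 0)
        r_fbc = sr.getPlugin("fbc")
        r_fbc.setLowerFluxBound(bound_ids[rxn.lb])
        r_fbc.setUpperFluxBound(bound_ids[rxn.ub])
        for met_id in sorted(rxn.stoichiometry):
            coef = rxn.stoichiometry[met_id]
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sid("M_", met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        if rxn.gpr is not EMPTY:
            assoc = r_fbc.createGeneProductAssociation()
            assoc.setAssociation(_gpr_to_fbc_infix(rxn.gpr), True, False)

    objective = fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fbc.setActiveObjectiveId("obj")
    if model.objective_id is not None:
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction(_sid("R_", model.objective_id))
        flux_obj.setCoefficient(1.0)

    return libsbml.writeSBMLToString(doc)


def _gpr_to_fbc_infix(rule: Gpr) -> str:
    if isinstance(rule, Leaf):
        return _sid("G_", rule.gene)
    if isinstance(rule, FalseLeaf):
        raise ValueError("cannot serialise a FALSE-marker leaf to SBML")
    if isinstance(rule, And):
        return "(" + " and ".join(_gpr_to_fbc_infix(c) for c in rule.children) + ")"
    if isinstance(rule, Or):
        return "(" + " or ".join(_gpr_to_fbc_infix(c) for c in rule.children) + ")"
    raise ValueError(f"cannot serialise {rule!r}")


def _fbc_assoc_to_gpr(assoc, labels: dict[str, str]) -> Gpr:
    if assoc is None:
        return EMPTY
    if isinstance(assoc, libsbml.GeneProductRef):
        ref = assoc.getGeneProduct()
        return Leaf(labels.get(ref, _unsid("G_", ref)))
    children = [
        _fbc_assoc_to_gpr(assoc.getAssociation(i), labels)
        for i in range(assoc.getNumAssociations())
    ]
    if isinstance(assoc, libsbml.FbcAnd):
        return make_and(children)
    if isinstance(assoc, libsbml.FbcOr):
        return make_or(children)
    raise ValueError(f"unsupported gene association node {assoc!r}")


def _load_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(
            f"{path}: SBML parse error: "
            f"{doc.getError(0).getMessage() if doc.getNumErrors() else 'unknown'}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"{path}: no model element")
    fbc = sbml_model.getPlugin("fbc")

    labels: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            labels[gp.getId()] = gp.getLabel() or _unsid("G_", gp.getId())

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sp_fbc = sp.getPlugin("fbc")
        charge = None
        formula = None
        if sp_fbc is not None:
            if sp_fbc.isSetCharge():
                charge = sp_fbc.getCharge()
            if sp_fbc.isSetChemicalFormula():
                formula = sp_fbc.getChemicalFormula()
        mets.append(
            Metabolite(
                id=_unsid("M_", sp.getId()),
                name=sp.getName(),
                compartment=_unsid("", sp.getCompartment()),
                formula=formula,
                charge=charge,
            )
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met_id = _unsid("M_", ref.getSpecies())
            stoich[met_id] = stoich.get(met_id, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met_id = _unsid("M_", ref.getSpecies())
            stoich[met_id] = stoich.get(met_id, 0.0) + ref.getStoichiometry()
        if not stoich:
            raise ValueError(f"{path}: reaction {sr.getId()} has empty stoichiometry")
        r_fbc = sr.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        gpr: Gpr = EMPTY
        if r_fbc is not None:
            if r_fbc.isSetLowerFluxBound():
                lb = params[r_fbc.getLowerFluxBound()]
            if r_fbc.isSetUpperFluxBound():
                ub = params[r_fbc.getUpperFluxBound()]
            assoc = r_fbc.getGeneProductAssociation()
            if assoc is not None:
                gpr = _fbc_assoc_to_gpr(assoc.getAssociation(), labels)
        rxns.append(
            Reaction(
                id=_unsid("R_", sr.getId()),
                name=sr.getName(),
                stoichiometry=stoich,
                lb=lb,
                ub=ub,
                gpr=gpr,
            )
        )

    model = MetabolicModel(sbml_model.getId() or "model", mets, rxns)
    objective_id = None
    if fbc is not None:
        active = fbc.getActiveObjective()
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = _unsid("R_", active.getFluxObjective(0).getReaction())
    if objective_id is not None:
        model.set_objective(objective_id)
    else:
        warnings.warn(f"{path}: no objective declared; objective left unset")
    return model
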