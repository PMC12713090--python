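"""Model readers and writers.

Two formats are supported:

* ``json`` — a minimal, hand-writable, diffable dialect used for fixtures::

      {"id": ..., "metabolites": [{"id", "name", "compartment", "formula",
       "charge"}], "reactions": [{"id", "name", "mets": {met: coef}, "lb",
       "ub", "gpr", "subsystem"}], "biomass": rid, "objective": rid}

  Omitted bounds default to ±1000 mmol·gDW⁻¹·h⁻¹.

* ``sbml`` — SBML Level 3 with the FBC package (flux bounds, objectives,
  gene-product associations), the community interchange format, via libsbml.

Round trips through either format preserve ids, stoichiometry (to 1e-9),
bounds, and gene rules.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import libsbml

from .core import (
    DEFAULT_BOUND,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
)


class FormatError(ModelError):
    """A file failed to parse in the declared format."""


def model_checksum(path: Union[str, Path]) -> str:
    """SHA-256 of a model file, recorded in run manifests and reports."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "mets": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gene_rule,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "biomass": model.biomass_reaction_id,
        "objective": model.objective_reaction_id,
    }


def _model_from_dict(doc: dict, source: str = "<dict>") -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                charge=m.get("charge"),
            )
            for m in doc["metabolites"]
        ]
        rxns = []
        for r in doc["reactions"]:
            if not r.get("mets"):
                raise FormatError(
                    f"{source}: reaction {r.get('id')!r} has no stoichiometry"
                )
            rxns.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["mets"].items()},
                    lower_bound=float(r.get("lb", -DEFAULT_BOUND)),
                    upper_bound=float(r.get("ub", DEFAULT_BOUND)),
                    name=r.get("name", ""),
                    gene_rule=r.get("gpr", ""),
                    subsystem=r.get("subsystem", ""),
                )
            )
        return MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=doc["biomass"],
            objective_reaction_id=doc.get("objective"),
            id=doc.get("id", "model"),
        )
    except KeyError as exc:
        raise FormatError(f"{source}: missing required key {exc}") from exc


# ---------------------------------------------------------------------------
# SBML L3 + FBC
# ---------------------------------------------------------------------------


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: file contains no SBML model")
    fbc = sbml_model.getPlugin("fbc")

    mets = []
    for s in sbml_model.getListOfSpecies():
        if s.getBoundaryCondition():
            continue  # boundary species are implicit sinks, not rows of S
        formula = None
        charge = None
        splug = s.getPlugin("fbc")
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula() or None
            if splug.isSetCharge():
                charge = splug.getCharge()
        mets.append(
            Metabolite(
                id=s.getId(),
                name=s.getName() or "",
                compartment=s.getCompartment() or "c",
                formula=formula,
                charge=charge,
            )
        )
    met_ids = {m.id for m in mets}

    def _bound_value(rplug, getter, default):
        if rplug is None:
            return default
        pid = getter()
        if not pid:
            return default
        param = sbml_model.getParameter(pid)
        return param.getValue() if param is not None else default

    rxns = []
    for r in sbml_model.getListOfReactions():
        stoich = {}
        for sr in r.getListOfReactants():
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in r.getListOfProducts():
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        if not stoich:
            raise FormatError(
                f"{path}: reaction {r.getId()!r} has no stoichiometry"
            )
        rplug = r.getPlugin("fbc")
        rev_default = -DEFAULT_BOUND if r.getReversible() else 0.0
        lb = _bound_value(rplug, rplug.getLowerFluxBound if rplug else None, rev_default)
        ub = _bound_value(rplug, rplug.getUpperFluxBound if rplug else None, DEFAULT_BOUND)
        gpr = ""
        if rplug is not None:
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = _association_to_rule(sbml_model, gpa.getAssociation())
        rxns.append(
            Reaction(
                id=r.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=r.getName() or "",
                gene_rule=gpr,
            )
        )

    objective_id = None
    if fbc is not None and fbc.getActiveObjective() is not None:
        obj = fbc.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()

    biomass_id = objective_id
    if biomass_id is None:
        candidates = [r.id for r in rxns if "biomass" in r.id.lower()]
        if not candidates:
            raise FormatError(
                f"{path}: no FBC objective and no reaction id containing 'biomass'"
            )
        biomass_id = candidates[0]

    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass_id,
        objective_reaction_id=objective_id,
        id=sbml_model.getId() or path.stem,
    )


def _association_to_rule(sbml_model, assoc) -> str:
    if assoc is None:
        return ""

    def label(gp_id: str) -> str:
        fbc = sbml_model.getPlugin("fbc")
        gp = fbc.getGeneProduct(gp_id) if fbc is not None else None
        if gp is not None and gp.isSetLabel():
            return gp.getLabel()
        return gp_id

    if assoc.isGeneProductRef():
        return label(assoc.getGeneProduct())
    if assoc.isFbcAnd():
        parts = [
            _association_to_rule(sbml_model, assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if assoc.isFbcOr():
        parts = [
            _association_to_rule(sbml_model, assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    return ""


def _sanitize_sid(raw: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize_sid(model.id))
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(True)

    compartments = {m.compartment for m in model.metabolites}
    for c in sorted(compartments):
        comp = sm.createCompartment()
        comp.setId(_sanitize_sid(c))
        comp.setConstant(True)

    for m in model.metabolites:
        s = sm.createSpecies()
        s.setId(m.id)
        s.setName(m.name)
        s.setCompartment(_sanitize_sid(m.compartment))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        splug = s.getPlugin("fbc")
        if m.formula is not None:
            splug.setChemicalFormula(m.formula)
        if m.charge is not None:
            splug.setCharge(int(m.charge))

    # one shared parameter per distinct bound value
    bound_params = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    all_genes = model.genes
    for g in all_genes:
        gp = fbc.createGeneProduct()
        gp.setId("G_" + _sanitize_sid(g))
        gp.setLabel(g)

    for r in model.reactions:
        sr = sm.createReaction()
        sr.setId(r.id)
        sr.setName(r.name)
        sr.setFast(False)
        sr.setReversible(r.lower_bound < 0)
        for met, coef in r.stoichiometry.items():
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(met)
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gene_rule.strip():
            gpa = rplug.createGeneProductAssociation()
            # libsbml matches infix tokens against gene-product *labels*,
            # so the rule is passed verbatim and resolves to the products
            # registered above
            gpa.setAssociation(r.gene_rule)

    obj = fbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.objective_reaction_id)
    fo.setCoefficient(1.0)
    fbc.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def read_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    """Read a model from ``json`` or ``sbml``; format inferred from suffix
    (.json vs .xml/.sbml) when not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("json" if path.suffix == ".json" else "sbml")
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        return _model_from_dict(doc, source=str(path))
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(
    model: MetabolicModel, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a model; the emitted file re-reads to an equivalent model."""
    if not model.reactions:
        raise ModelError("refusing to write a model with no reactions")
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "sbml")
    if fmt == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=False) + "\n")
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def models_equivalent(a: MetabolicModel, b: MetabolicModel, tol: float = 1e-9) -> bool:
    """Structural equivalence: same ids, stoichiometry (within ``tol``),
    bounds, gene rules, biomass/objective designation."""
    if [m.id for m in a.metabolites] != [m.id for m in b.metabolites]:
        return False
    if [r.id for r in a.reactions] != [r.id for r in b.reactions]:
        return False
    if (a.biomass_reaction_id, a.objective_reaction_id) != (
        b.biomass_reaction_id,
        b.objective_reaction_id,
    ):
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if set(ra.stoichiometry) != set(rb.stoichiometry):
            return False
        for met in ra.stoichiometry:
            if abs(ra.stoichiometry[met] - rb.stoichiometry[met]) > tol:
                return False
        if abs(ra.lower_bound - rb.lower_bound) > tol:
            return False
        if abs(ra.upper_bound - rb.upper_bound) > tol:
            return False
        if ra.genes != rb.genes:
            return False
    return True
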