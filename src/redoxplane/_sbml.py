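"""SBML reading and writing via libsbml.

Reading prefers Level 3 with the flux-balance-constraints (fbc) extension,
where bounds are parameters referenced from each reaction and the active
objective lives in the fbc objective list.  Legacy Level 2 files (kinetic-law
parameters ``LOWER_BOUND`` / ``UPPER_BOUND`` / ``OBJECTIVE_COEFFICIENT``) are
tolerated, since older distributions of the published yeast models use that
dialect.  Species flagged as boundary conditions are dropped from the
stoichiometric matrix, which turns their consuming reactions into structural
exchanges, consistent with the package-wide convention.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

import libsbml

from redoxplane.model_core import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelParseError,
    Reaction,
)


def read_sbml(path: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"SBML parse error in {path!r}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"no <model> element in {path!r}")
    if sbml_model.getNumReactions() == 0:
        raise ModelParseError(f"model file {path!r} defines zero reactions")

    mets: list[Metabolite] = []
    met_index: dict[str, int] = {}
    for sp in sbml_model.getListOfSpecies():
        if sp.getBoundaryCondition():
            continue
        met_index[sp.getId()] = len(mets)
        mets.append(
            Metabolite(sp.getId(), sp.getName() or "", sp.getCompartment() or "")
        )

    fbc = sbml_model.getPlugin("fbc")
    obj_coeffs_by_rxn: dict[str, float] = {}
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        for fo in active.getListOfFluxObjectives():
            obj_coeffs_by_rxn[fo.getReaction()] = fo.getCoefficient()

    def parameter_value(pid: str, default: float) -> float:
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else default

    rxns: list[Reaction] = []
    lbs, ubs, objs = [], [], []
    rows, cols, vals = [], [], []
    for j, rx in enumerate(sbml_model.getListOfReactions()):
        rev = rx.getReversible()
        lb = -DEFAULT_BOUND if rev else 0.0
        ub = DEFAULT_BOUND
        obj = obj_coeffs_by_rxn.get(rx.getId(), 0.0)
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = parameter_value(rfbc.getLowerFluxBound(), lb)
            ub = parameter_value(rfbc.getUpperFluxBound(), ub)
        else:  # legacy kinetic-law bounds
            kl = rx.getKineticLaw()
            if kl is not None:
                for name, setter in (
                    ("LOWER_BOUND", "lb"),
                    ("UPPER_BOUND", "ub"),
                    ("OBJECTIVE_COEFFICIENT", "obj"),
                ):
                    p = kl.getParameter(name)
                    if p is not None:
                        if setter == "lb":
                            lb = p.getValue()
                        elif setter == "ub":
                            ub = p.getValue()
                        else:
                            obj = p.getValue()
        rxns.append(
            Reaction(rx.getId(), rx.getName() or "", lb < 0, "")
        )
        lbs.append(lb)
        ubs.append(ub)
        objs.append(obj)
        seen_any = False
        for ref, sign in ((rx.getListOfReactants(), -1.0), (rx.getListOfProducts(), 1.0)):
            for sr in ref:
                sid = sr.getSpecies()
                if sid not in met_index:  # boundary species
                    seen_any = True
                    continue
                rows.append(met_index[sid])
                cols.append(j)
                vals.append(sign * sr.getStoichiometry())
                seen_any = True
        if not seen_any:
            raise ModelParseError(
                f"reaction {rx.getId()!r} in {path!r} has no participants"
            )

    S = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(mets), len(rxns))
    ).tocsc()
    # reactions whose participants were all boundary species would leave an
    # empty column; drop a clear error naming them early
    empty = np.flatnonzero(S.getnnz(axis=0) == 0)
    if empty.size:
        raise ModelParseError(
            f"reactions with only boundary species in {path!r}: "
            f"{[rxns[k].id for k in empty[:5]]}"
        )
    return MetabolicModel(
        model_id=sbml_model.getId() or "model",
        metabolites=mets,
        reactions=rxns,
        S=S,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        objective_coeffs=np.array(objs),
    )


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write Level 3 Version 1 SBML with the fbc (version 2) extension."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid(model.model_id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in sorted(model.compartments() or {"c"}):
        c = sm.createCompartment()
        c.setId(_sid(comp or "c"))
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(_sid(met.id))
        sp.setName(met.name)
        sp.setCompartment(_sid(met.compartment or "c"))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mplug.setActiveObjectiveId("obj")

    for j, rxn in enumerate(model.reactions):
        rx = sm.createReaction()
        rx.setId(_sid(rxn.id))
        rx.setName(rxn.name)
        rx.setReversible(bool(model.lower_bounds[j] < 0))
        rx.setFast(False)
        col = model.S.getcol(j).tocoo()
        for i, coeff in zip(col.row, col.data):
            if coeff < 0:
                sr = rx.createReactant()
            else:
                sr = rx.createProduct()
            sr.setSpecies(_sid(model.metabolites[int(i)].id))
            sr.setStoichiometry(abs(float(coeff)))
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(model.lower_bounds[j]))
        rplug.setUpperFluxBound(bound_param(model.upper_bounds[j]))
        if model.objective_coeffs[j]:
            fo = objective.createFluxObjective()
            fo.setReaction(_sid(rxn.id))
            fo.setCoefficient(float(model.objective_coeffs[j]))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path!r}")


def _sid(raw: str) -> str:
    # Reading keeps ids verbatim; writing only sanitises characters the SBML
    # SId grammar forbids, which the bundled toy models never use.
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out
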