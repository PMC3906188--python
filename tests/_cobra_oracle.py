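"""Cross-check oracle: rebuild a MetabolicModel in cobrapy (GLPK solver).

A second, fully independent optimisation stack (cobrapy + optlang/GLPK vs
this package's scipy/HiGHS) for verifying objectives and flux-variability
ranges on the toy models.
"""

from __future__ import annotations

import cobra


def to_cobra(model) -> cobra.Model:
    cm = cobra.Model(model.model_id)
    cm.solver = "glpk"
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    rxns = []
    for j, r in enumerate(model.reactions):
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound = float(model.lower_bounds[j])
        cr.upper_bound = float(model.upper_bounds[j])
        rxns.append(cr)
    cm.add_reactions(rxns)
    for j, r in enumerate(model.reactions):
        col = model.S.getcol(j).tocoo()
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[model.metabolites[int(i)].id]: float(v) for i, v in zip(col.row, col.data)}
        )
    cm.objective = {
        cm.reactions.get_by_id(model.reactions[j].id): float(c)
        for j, c in enumerate(model.objective_coeffs)
        if c
    }
    return cm
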