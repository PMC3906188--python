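"""Stoichiometric model representation and I/O.

The central object is :class:`MetabolicModel`: an immutable-by-convention
container holding the stoichiometric matrix ``S`` (metabolites x reactions),
per-reaction flux bounds in mmol gDW^-1 h^-1 (the biomass column is read in
h^-1) and a linear objective.  Models come from three places: the bundled
synthetic generators (:mod:`redoxplane.synthetic_models`), SBML files
(Level 3 + fbc preferred, Level 2 kinetic-law bounds tolerated) and
BiGG-style JSON files, so the published genome-scale yeast reconstructions
can be dropped in unchanged.

Exchange convention throughout the package: an exchange column has a single
negative entry for its metabolite, negative flux is uptake and positive flux
is secretion.  Uptake rates quoted as magnitudes are applied as negative
lower bounds (:func:`set_uptake`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

DEFAULT_BOUND = 1000.0


class ModelParseError(ValueError):
    """Raised when a model file cannot be interpreted."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    reversible: bool = True
    subsystem: str = ""


@dataclass
class MetabolicModel:
    """A stoichiometric model: S, bounds and a linear objective.

    Mutating operations in this package (``set_uptake``, ``apply_deletions``,
    sink additions) always return modified copies; instances handed to
    analysis functions are never changed in place.
    """

    model_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    S: sparse.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective_coeffs: np.ndarray
    no_objective_warning: bool = False
    _met_index: dict = field(default_factory=dict, repr=False)
    _rxn_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.S = sparse.csc_matrix(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective_coeffs = np.asarray(self.objective_coeffs, dtype=float)
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite_index(self, met_id: str) -> int:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite id: {met_id!r}") from None

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction id: {rxn_id!r}") from None

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def exchange_mask(self) -> np.ndarray:
        """Boolean mask of boundary exchanges: single-metabolite columns."""
        counts = self.S.getnnz(axis=0)
        return counts == 1

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r, ex in zip(self.reactions, self.exchange_mask) if ex]

    @property
    def objective_id(self) -> str:
        nz = np.flatnonzero(self.objective_coeffs)
        if nz.size != 1:
            raise ValueError(
                f"model {self.model_id!r} must have exactly one objective "
                f"reaction, found {nz.size}"
            )
        return self.reactions[nz[0]].id

    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites}

    def metabolites_in(self, compartment: str) -> list[Metabolite]:
        return [m for m in self.metabolites if m.compartment == compartment]

    def validate(self) -> None:
        n_m, n_r = self.S.shape
        if n_m != len(self.metabolites) or n_r != len(self.reactions):
            raise ValueError("S shape does not match metabolite/reaction lists")
        if len(self._met_index) != n_m:
            raise ValueError("duplicate metabolite ids")
        if len(self._rxn_index) != n_r:
            raise ValueError("duplicate reaction ids")
        if self.lower_bounds.shape != (n_r,) or self.upper_bounds.shape != (n_r,):
            raise ValueError("bound vectors must have one entry per reaction")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = np.flatnonzero(self.lower_bounds > self.upper_bounds)
            raise ValueError(
                f"lower bound exceeds upper bound for reactions "
                f"{[self.reactions[j].id for j in bad[:5]]}"
            )
        empty = np.flatnonzero(self.S.getnnz(axis=0) == 0)
        if empty.size:
            raise ValueError(
                f"reactions with empty stoichiometry: "
                f"{[self.reactions[j].id for j in empty[:5]]}"
            )

    # -- value-semantics edits --------------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective_coeffs=self.objective_coeffs.copy(),
            no_objective_warning=self.no_objective_warning,
        )

    def with_bounds(self, rxn_id: str, lb: float, ub: float) -> "MetabolicModel":
        j = self.reaction_index(rxn_id)
        m = self.copy()
        m.lower_bounds[j] = lb
        m.upper_bounds[j] = ub
        m.validate()
        return m

    def add_reaction(
        self,
        rxn_id: str,
        stoichiometry: dict,
        lb: float,
        ub: float,
        name: str = "",
        objective_coeff: float = 0.0,
    ) -> "MetabolicModel":
        """Return a copy with one extra reaction column appended."""
        if self.has_reaction(rxn_id):
            raise ValueError(f"reaction id already present: {rxn_id!r}")
        col = np.zeros((self.n_metabolites, 1))
        for met_id, coeff in stoichiometry.items():
            col[self.metabolite_index(met_id), 0] = coeff
        S = sparse.hstack([self.S, sparse.csc_matrix(col)], format="csc")
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions)
            + [Reaction(rxn_id, name=name, reversible=lb < 0)],
            S=S,
            lower_bounds=np.append(self.lower_bounds, lb),
            upper_bounds=np.append(self.upper_bounds, ub),
            objective_coeffs=np.append(self.objective_coeffs, objective_coeff),
            no_objective_warning=self.no_objective_warning,
        )

    def reaction_stoichiometry(self, rxn_id: str) -> dict:
        j = self.reaction_index(rxn_id)
        col = self.S.getcol(j).tocoo()
        return {self.metabolites[i].id: v for i, v in zip(col.row, col.data)}

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        coo = self.S.tocoo()
        return {
            "model_id": self.model_id,
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment}
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "reversible": r.reversible,
                    "subsystem": r.subsystem,
                    "lower_bound": float(lb),
                    "upper_bound": float(ub),
                    "objective_coefficient": float(c),
                }
                for r, lb, ub, c in zip(
                    self.reactions,
                    self.lower_bounds,
                    self.upper_bounds,
                    self.objective_coeffs,
                )
            ],
            "stoichiometry": [
                [int(i), int(j), float(v)]
                for i, j, v in sorted(zip(coo.row, coo.col, coo.data))
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        mets = [
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", ""))
            for m in d["metabolites"]
        ]
        rxns = [
            Reaction(
                r["id"],
                r.get("name", ""),
                bool(r.get("reversible", r.get("lower_bound", 0) < 0)),
                r.get("subsystem", ""),
            )
            for r in d["reactions"]
        ]
        rows, cols, vals = ([], [], [])
        for i, j, v in d["stoichiometry"]:
            rows.append(i)
            cols.append(j)
            vals.append(v)
        S = sparse.csc_matrix(
            (vals, (rows, cols)), shape=(len(mets), len(rxns))
        )
        return cls(
            model_id=d.get("model_id", "model"),
            metabolites=mets,
            reactions=rxns,
            S=S,
            lower_bounds=np.array([r["lower_bound"] for r in d["reactions"]]),
            upper_bounds=np.array([r["upper_bound"] for r in d["reactions"]]),
            objective_coeffs=np.array(
                [r.get("objective_coefficient", 0.0) for r in d["reactions"]]
            ),
        )

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def write_sbml(self, path) -> None:
        from redoxplane._sbml import write_sbml

        write_sbml(self, path)


# ---------------------------------------------------------------------------
# loading


def load_model(path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML or BiGG-style JSON.

    ``format`` is one of ``"sbml"``, ``"bigg_json"`` or ``None`` (guess from
    the file suffix).  Exchange reactions are recognised structurally as
    single-metabolite boundary columns; missing bounds default to
    ``[-1000, 1000]`` for reversible and ``[0, 1000]`` for irreversible
    reactions.  A model without an objective loads with
    ``no_objective_warning`` set (growth analyses then refuse it).
    """
    path = str(path)
    if format is None:
        if path.endswith((".xml", ".sbml")):
            format = "sbml"
        elif path.endswith(".json"):
            format = "bigg_json"
        else:
            raise ModelParseError(f"cannot guess model format from {path!r}")
    if format == "sbml":
        from redoxplane._sbml import read_sbml

        model = read_sbml(path)
    elif format == "bigg_json":
        model = _read_bigg_json(path)
    else:
        raise ValueError(f"unknown model format: {format!r}")
    if not np.any(model.objective_coeffs):
        model.no_objective_warning = True
        warnings.warn(
            f"model {model.model_id!r} has no objective reaction; "
            "growth analyses will refuse it",
            stacklevel=2,
        )
    return model


def _read_bigg_json(path: str) -> MetabolicModel:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelParseError(f"unreadable BiGG JSON file {path!r}: {exc}") from exc
    if "stoichiometry" in d:
        return MetabolicModel.from_dict(d)  # canonical dump round-trip
    if not d.get("reactions"):
        raise ModelParseError(f"model file {path!r} defines zero reactions")
    mets = [
        Metabolite(m["id"], m.get("name") or "", m.get("compartment") or "")
        for m in d.get("metabolites", [])
    ]
    met_index = {m.id: i for i, m in enumerate(mets)}
    rxns, lbs, ubs, objs = [], [], [], []
    rows, cols, vals = [], [], []
    for j, r in enumerate(d["reactions"]):
        lb = float(r.get("lower_bound", -DEFAULT_BOUND))
        ub = float(r.get("upper_bound", DEFAULT_BOUND))
        rxns.append(
            Reaction(r["id"], r.get("name") or "", lb < 0, r.get("subsystem") or "")
        )
        lbs.append(lb)
        ubs.append(ub)
        objs.append(float(r.get("objective_coefficient", 0.0)))
        for met_id, coeff in r.get("metabolites", {}).items():
            if met_id not in met_index:
                raise ModelParseError(
                    f"reaction {r['id']!r} references unknown metabolite {met_id!r}"
                )
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(float(coeff))
    S = sparse.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(rxns)))
    return MetabolicModel(
        model_id=d.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        S=S,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        objective_coeffs=np.array(objs),
    )


# ---------------------------------------------------------------------------
# bound edits


def set_uptake(model: MetabolicModel, exchange_id: str, max_uptake) -> MetabolicModel:
    """Return a copy with the exchange's maximal uptake set.

    ``max_uptake`` is a non-negative magnitude in mmol gDW^-1 h^-1, or the
    string ``"unbounded"`` (lower bound -1000).  Uptake is a negative flux on
    the exchange, so the lower bound becomes ``-max_uptake``.
    """
    j = model.reaction_index(exchange_id)
    if not model.exchange_mask[j]:
        raise ValueError(f"{exchange_id!r} is not an exchange reaction")
    if isinstance(max_uptake, str):
        if max_uptake != "unbounded":
            raise ValueError(f"bad uptake spec: {max_uptake!r}")
        lb = -DEFAULT_BOUND
    else:
        if max_uptake < 0:
            raise ValueError("max_uptake must be non-negative")
        lb = -float(max_uptake)
    out = model.copy()
    out.lower_bounds[j] = lb
    if out.upper_bounds[j] < lb:
        out.upper_bounds[j] = lb
    out.validate()
    return out


def apply_deletions(model: MetabolicModel, reaction_ids) -> MetabolicModel:
    """Return a copy with the named reactions pinned to zero flux."""
    missing = sorted(r for r in reaction_ids if not model.has_reaction(r))
    if missing:
        raise KeyError(f"unknown reaction ids: {missing}")
    out = model.copy()
    for rid in reaction_ids:
        j = out.reaction_index(rid)
        out.lower_bounds[j] = 0.0
        out.upper_bounds[j] = 0.0
    return out


def objective_connectivity_report(model: MetabolicModel) -> list[str]:
    """Sanity check: metabolites of the objective reaction unreachable from
    any exchange through the bipartite metabolite-reaction graph.

    Violations are reported (list of metabolite ids), not fatal.
    """
    reachable: set[int] = set()
    frontier: set[int] = set()
    Scsr = model.S.tocsr()
    for j in np.flatnonzero(model.exchange_mask):
        col = model.S.getcol(j).tocoo()
        frontier.update(int(i) for i in col.row)
    while frontier:
        reachable |= frontier
        nxt: set[int] = set()
        for i in frontier:
            row = Scsr.getrow(i).tocoo()
            for j in row.col:
                col = model.S.getcol(int(j)).tocoo()
                nxt.update(int(k) for k in col.row)
        frontier = nxt - reachable
    obj_col = model.S.getcol(
        model.reaction_index(model.objective_id)
    ).tocoo()
    return [
        model.metabolites[int(i)].id for i in obj_col.row if int(i) not in reachable
    ]
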