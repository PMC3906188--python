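"""Linear-programming core: FBA solves, duals and loop removal.

Flux balance analysis maximises the biomass flux Z = c'v subject to the
steady-state mass balance S v = 0 and flux bounds l <= v <= u.  The solver is
HiGHS through :func:`scipy.optimize.linprog`, run single-threaded with fixed
tolerances so repeated solves are bit-reproducible.

Metabolite duals are re-signed so that gamma_i is the negative growth
sensitivity to a small external supply of metabolite i: gamma_i < 0 means the
metabolite is growth-limiting (supplying it raises Z), gamma_i > 0 means it
is in excess (supplying it lowers Z).  Duals at degenerate vertices are
non-unique; :func:`fba` flags a metabolite's dual as degenerate when a
deterministic bound jitter changes it by more than ``degeneracy_tol``, and
downstream classification then falls back on the finite-difference probe in
:mod:`redoxplane.shadow_redox`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from redoxplane.model_core import MetabolicModel

FEASIBILITY_TOL = 1e-9
MASS_BALANCE_TOL = 1e-6
DUALITY_TOL = 1e-6


@dataclass(frozen=True)
class SolverConfig:
    """Pinned LP configuration, recorded in every solution."""

    method: str = "highs"
    presolve: bool = True
    feasibility_tol: float = FEASIBILITY_TOL
    optimality_tol: float = FEASIBILITY_TOL
    jitter: float = 1e-7
    degeneracy_tol: float = 1e-4
    jitter_seed: int = 20140129

    def options(self) -> dict:
        return {
            "presolve": self.presolve,
            "primal_feasibility_tolerance": self.feasibility_tol,
            "dual_feasibility_tolerance": self.optimality_tol,
        }


DEFAULT_CONFIG = SolverConfig()


@dataclass
class FBASolution:
    """Optimal flux vector, objective and (re-signed) dual vector."""

    status: str  # optimal | infeasible | unbounded
    objective: float
    fluxes: np.ndarray
    duals: np.ndarray
    reduced_costs: np.ndarray
    degenerate_flags: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    metabolite_compartments: list[str]
    model_id: str
    config: SolverConfig = field(default=DEFAULT_CONFIG)
    loop_removed: bool = False
    dual_objective: float = float("nan")
    _met_index: dict = field(default_factory=dict, repr=False)
    _rxn_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        self._rxn_index = {r: j for j, r in enumerate(self.reaction_ids)}

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        return float(self.fluxes[self._rxn_index[rxn_id]])

    def dual(self, met_id: str) -> float:
        return float(self.duals[self._met_index[met_id]])

    def dual_degenerate(self, met_id: str) -> bool:
        return bool(self.degenerate_flags[self._met_index[met_id]])


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def _solve(
    c: np.ndarray,
    A_eq: sparse.spmatrix,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    config: SolverConfig,
    A_ub: sparse.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
    presolve: bool | None = None,
):
    options = config.options()
    if presolve is not None:
        # presolve mis-declares infeasibility on bound bands as tight as the
        # feasibility tolerance (growth pinned to Z* +/- 1e-9), so pinned
        # solves run without it
        options["presolve"] = presolve
    return linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([bounds_lo, bounds_hi]),
        method=config.method,
        options=options,
    )


def fba(
    model: MetabolicModel,
    config: SolverConfig = DEFAULT_CONFIG,
    check_degeneracy: bool = True,
) -> FBASolution:
    """Maximise the model objective; return fluxes, Z and metabolite duals.

    Raises ``ValueError`` if the model lacks a (single) objective reaction.
    An infeasible constraint set returns ``status="infeasible"`` with empty
    flux/dual vectors rather than raising.
    """
    if model.no_objective_warning or not np.any(model.objective_coeffs):
        raise ValueError(
            f"model {model.model_id!r} has no objective reaction; cannot run FBA"
        )
    nz = np.flatnonzero(model.objective_coeffs)
    if nz.size != 1:
        raise ValueError("FBA requires exactly one nonzero objective coefficient")

    c = -model.objective_coeffs  # linprog minimises
    res = _solve(c, model.S, model.lower_bounds, model.upper_bounds, config)
    status = _STATUS.get(res.status, "infeasible")
    meta = dict(
        reaction_ids=[r.id for r in model.reactions],
        metabolite_ids=[m.id for m in model.metabolites],
        metabolite_compartments=[m.compartment for m in model.metabolites],
        model_id=model.model_id,
        config=config,
    )
    if status != "optimal":
        return FBASolution(
            status="unbounded" if status == "unbounded" else "infeasible",
            objective=float("nan"),
            fluxes=np.array([]),
            duals=np.array([]),
            reduced_costs=np.array([]),
            degenerate_flags=np.array([], dtype=bool),
            **meta,
        )

    fluxes = np.asarray(res.x)
    # paper-sign duals: gamma_i = -dZ/d(supply of i); a supply flux s of
    # metabolite i shifts the balance to S v = -s e_i, and linprog marginals
    # are d(min -Z)/d(b_eq), so gamma_i = -marginals_i.
    gamma = -np.asarray(res.eqlin.marginals)
    reduced = np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals)

    dual_objective = _assert_solution_sane(model, res, fluxes, config)

    degenerate = np.zeros(model.n_metabolites, dtype=bool)
    if check_degeneracy:
        degenerate = _degeneracy_flags(model, gamma, config)

    return FBASolution(
        status="optimal",
        objective=float(-res.fun),
        fluxes=fluxes,
        duals=gamma,
        reduced_costs=reduced,
        degenerate_flags=degenerate,
        dual_objective=dual_objective,
        **meta,
    )


def _assert_solution_sane(model, res, fluxes, config) -> float:
    imbalance = np.abs(model.S @ fluxes)
    if imbalance.size and imbalance.max() > MASS_BALANCE_TOL:
        raise ArithmeticError(
            f"mass balance violated: ||S v||_inf = {imbalance.max():.2e}"
        )
    if (
        np.any(fluxes < model.lower_bounds - 1e-9)
        or np.any(fluxes > model.upper_bounds + 1e-9)
    ):
        raise ArithmeticError("flux bounds violated beyond tolerance")
    # strong duality: b=0, so the dual objective is the bound contribution
    lo = np.where(np.isfinite(model.lower_bounds), model.lower_bounds, 0.0)
    hi = np.where(np.isfinite(model.upper_bounds), model.upper_bounds, 0.0)
    dual_obj = float(lo @ res.lower.marginals + hi @ res.upper.marginals)
    if abs(dual_obj - res.fun) > DUALITY_TOL * max(1.0, abs(res.fun)):
        raise ArithmeticError(
            f"strong duality violated: primal {res.fun:.9g} vs dual {dual_obj:.9g}"
        )
    return -dual_obj  # max-form dual objective, mirrors `objective`


def _degeneracy_flags(
    model: MetabolicModel, gamma: np.ndarray, config: SolverConfig
) -> np.ndarray:
    """Flag duals that move under a deterministic 1e-7 bound jitter.

    Both a relaxed and a tightened jitter are solved: at a kink between two
    LP bases (a phase boundary) the two perturbations land in different
    bases, so either side moving the dual flags the metabolite.
    """
    rng = np.random.default_rng(config.jitter_seed)
    jig = config.jitter * rng.integers(1, 10, size=model.n_reactions)
    flags = np.zeros(model.n_metabolites, dtype=bool)
    for sign in (+1.0, -1.0):
        lo = model.lower_bounds - sign * jig
        hi = model.upper_bounds + sign * jig
        squeeze = lo > hi  # pinned reactions invert under tightening
        if np.any(squeeze):
            mid = 0.5 * (model.lower_bounds[squeeze] + model.upper_bounds[squeeze])
            lo[squeeze] = mid
            hi[squeeze] = mid
        res = _solve(-model.objective_coeffs, model.S, lo, hi, config)
        if res.status != 0:  # jittered problem failed; distrust every dual
            return np.ones(model.n_metabolites, dtype=bool)
        gamma_j = -np.asarray(res.eqlin.marginals)
        flags |= np.abs(gamma_j - gamma) > config.degeneracy_tol
    return flags


def remove_loops(
    model: MetabolicModel,
    solution: FBASolution,
    config: SolverConfig = DEFAULT_CONFIG,
) -> FBASolution:
    """Strip internal flux cycles from an optimal solution.

    Re-solves with every exchange flux and the objective pinned to their
    optimal values while minimising the L1 norm of internal fluxes, so
    thermodynamically infeasible cycles (which carry no net exchange) collapse
    while Z and all exchanges are preserved exactly.  Duals are carried over
    unchanged from the original LP, whose vertex defines them.
    """
    if not solution.optimal:
        raise ValueError("remove_loops requires an optimal solution")
    n = model.n_reactions
    internal = ~model.exchange_mask
    obj_j = model.reaction_index(model.objective_id)

    lo = model.lower_bounds.copy()
    hi = model.upper_bounds.copy()
    pin = ~internal.copy()
    pin[obj_j] = True
    lo[pin] = solution.fluxes[pin] - FEASIBILITY_TOL
    hi[pin] = solution.fluxes[pin] + FEASIBILITY_TOL

    int_idx = np.flatnonzero(internal)
    k = int_idx.size
    # variables [v (n), t (k)] with t_j >= |v_j| for internal j
    c = np.concatenate([np.zeros(n), np.ones(k)])
    A_eq = sparse.hstack([model.S, sparse.csc_matrix((model.n_metabolites, k))])
    rowsel = sparse.csc_matrix(
        (np.ones(k), (np.arange(k), int_idx)), shape=(k, n)
    )
    eye = sparse.identity(k, format="csc")
    A_ub = sparse.vstack([sparse.hstack([rowsel, -eye]), sparse.hstack([-rowsel, -eye])])
    b_ub = np.zeros(2 * k)
    opts = config.options()
    opts["presolve"] = False  # see _solve: tight pin bands break presolve
    res = linprog(
        c,
        A_eq=A_eq.tocsc(),
        b_eq=np.zeros(model.n_metabolites),
        A_ub=A_ub.tocsc(),
        b_ub=b_ub,
        bounds=np.column_stack(
            [
                np.concatenate([lo, np.zeros(k)]),
                np.concatenate([hi, np.full(k, np.inf)]),
            ]
        ),
        method=config.method,
        options=opts,
    )
    if res.status != 0:
        raise ArithmeticError(f"loop-removal LP failed with status {res.status}")
    v = np.asarray(res.x[:n])
    imbalance = np.abs(model.S @ v)
    if imbalance.size and imbalance.max() > MASS_BALANCE_TOL:
        raise ArithmeticError("loop-removed solution violates mass balance")
    out = FBASolution(
        status="optimal",
        objective=solution.objective,
        fluxes=v,
        duals=solution.duals,
        reduced_costs=solution.reduced_costs,
        degenerate_flags=solution.degenerate_flags,
        reaction_ids=solution.reaction_ids,
        metabolite_ids=solution.metabolite_ids,
        metabolite_compartments=solution.metabolite_compartments,
        model_id=solution.model_id,
        config=config,
        loop_removed=True,
    )
    return out
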