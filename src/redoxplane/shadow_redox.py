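"""Shadow-price semantics and the reducing-capacity price gamma_red.

The shadow price gamma_i of a metabolite is the sensitivity of optimal
growth to a small external supply of that metabolite, signed so that
negative means growth-limiting and positive means in excess.  The composite

    gamma_red = gamma_NADH - gamma_NAD

is the growth sensitivity to the net supply of reducing equivalents in one
compartment: supplying NADH while withdrawing NAD is exactly a transfer of
reducing capacity into the NAD(H) pool.  A negative gamma_red means reducing
capacity is limiting for biomass production, a positive one means the pool
is in excess and must be re-oxidised at the expense of growth.

Because LP duals are non-unique at degenerate vertices (phase boundaries are
precisely the degenerate loci), every dual-based verdict can be re-derived
with an independent finite-difference probe (:func:`verify_fd`,
:func:`gamma_red_fd`): a temporary supply reaction with a small fixed flux,
one extra solve, and a one-sided difference quotient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from redoxplane.lp_engine import DEFAULT_CONFIG, FBASolution, SolverConfig, fba
from redoxplane.model_core import MetabolicModel

SIGN_EPS = 1e-6
DEFAULT_PROBE = 1e-3
DEFAULT_COMPARTMENT = "c"


@dataclass(frozen=True)
class AvailabilityVerdict:
    """gamma_red for one compartment plus its sign classification."""

    gamma_red: float
    classification: str  # limiting | excess | neutral
    compartment: str
    degenerate: bool

    @property
    def excess(self) -> bool:
        return self.classification == "excess"

    @property
    def limiting(self) -> bool:
        return self.classification == "limiting"


def classify(value: float, eps: float = SIGN_EPS) -> str:
    if value > eps:
        return "excess"
    if value < -eps:
        return "limiting"
    return "neutral"


def _match_cofactor(solution_or_model, base: str, compartment: str) -> str:
    """Find the metabolite id for a cofactor base name in a compartment.

    Matches ``{base}_{compartment}`` first (BiGG convention, also used by the
    bundled toys), then any metabolite of that compartment whose id stem
    equals ``base`` case-insensitively.
    """
    if isinstance(solution_or_model, FBASolution):
        ids = solution_or_model.metabolite_ids
        comps = solution_or_model.metabolite_compartments
    else:
        ids = [m.id for m in solution_or_model.metabolites]
        comps = [m.compartment for m in solution_or_model.metabolites]
    direct = f"{base}_{compartment}"
    for mid, comp in zip(ids, comps):
        if mid.lower() == direct.lower():
            return mid
    for mid, comp in zip(ids, comps):
        if comp != compartment:
            continue
        stem = mid[: -len(comp) - 1] if mid.endswith(f"_{comp}") else mid
        if stem.lower() == base.lower():
            return mid
    raise KeyError(
        f"no metabolite with stem {base!r} in compartment {compartment!r}"
    )


def shadow_price(solution: FBASolution, metabolite_id: str) -> float:
    """Signed shadow price of one metabolite at an optimal solution."""
    if not solution.optimal:
        raise ValueError("shadow prices require an optimal solution")
    return solution.dual(metabolite_id)


def pair_difference(
    solution: FBASolution, metabolite_a: str, metabolite_b: str
) -> float:
    """gamma_a - gamma_b: the availability price of converting b into a."""
    return shadow_price(solution, metabolite_a) - shadow_price(
        solution, metabolite_b
    )


def gamma_red(
    solution: FBASolution, compartment: str = DEFAULT_COMPARTMENT
) -> AvailabilityVerdict:
    """Reducing-capacity availability verdict for one NADH/NAD pool."""
    if not solution.optimal:
        raise ValueError("gamma_red requires an optimal solution")
    nadh = _match_cofactor(solution, "nadh", compartment)
    nad = _match_cofactor(solution, "nad", compartment)
    value = solution.dual(nadh) - solution.dual(nad)
    degenerate = solution.dual_degenerate(nadh) or solution.dual_degenerate(nad)
    return AvailabilityVerdict(
        gamma_red=float(value),
        classification=classify(value),
        compartment=compartment,
        degenerate=degenerate,
    )


def gamma_red_by_compartment(solution: FBASolution) -> pd.DataFrame:
    """gamma_red for every compartment containing an NADH/NAD pair."""
    rows = []
    for comp in sorted(set(solution.metabolite_compartments)):
        try:
            v = gamma_red(solution, comp)
        except KeyError:
            continue
        rows.append(
            {
                "compartment": comp,
                "gamma_red": v.gamma_red,
                "classification": v.classification,
                "degenerate": v.degenerate,
            }
        )
    return pd.DataFrame(rows, columns=["compartment", "gamma_red", "classification", "degenerate"])


# ---------------------------------------------------------------------------
# finite-difference oracle


def _probed_objective(
    model: MetabolicModel,
    stoichiometry: dict,
    probe: float,
    config: SolverConfig,
) -> float:
    probed = model.add_reaction(
        "__fd_probe__", stoichiometry, probe, probe, name="finite-difference probe"
    )
    sol = fba(probed, config=config, check_degeneracy=False)
    if not sol.optimal:
        raise ArithmeticError(
            f"model {model.model_id!r} infeasible under probe {stoichiometry} "
            f"at rate {probe}"
        )
    return sol.objective


def verify_fd(
    model: MetabolicModel,
    metabolite_id: str,
    probe: float = DEFAULT_PROBE,
    config: SolverConfig = DEFAULT_CONFIG,
    base_solution: FBASolution | None = None,
) -> tuple[float, bool]:
    """Finite-difference estimate of gamma_i and agreement with the dual.

    Adds a temporary supply reaction (nothing -> metabolite) with flux fixed
    to ``probe`` and returns ``-(Z(probe) - Z(0)) / probe``.  ``agrees`` is
    the 1%-relative (1e-6 absolute floor) match against the LP dual and is
    only meaningful when the dual is not flagged degenerate.
    """
    if probe <= 0:
        raise ValueError("probe must be positive")
    if base_solution is None:
        base_solution = fba(model, config=config)
    if not base_solution.optimal:
        raise ValueError("base model FBA is not optimal")
    z0 = base_solution.objective
    z1 = _probed_objective(model, {metabolite_id: 1.0}, probe, config)
    fd = -(z1 - z0) / probe
    dual = base_solution.dual(metabolite_id)
    agrees = abs(fd - dual) <= max(1e-6, 0.01 * abs(dual))
    return float(fd), bool(agrees)


def gamma_red_fd(
    model: MetabolicModel,
    compartment: str = DEFAULT_COMPARTMENT,
    probe: float = DEFAULT_PROBE,
    config: SolverConfig = DEFAULT_CONFIG,
    base_solution: FBASolution | None = None,
) -> AvailabilityVerdict:
    """gamma_red from a single finite-difference probe (NAD -> NADH).

    The probe reaction converts NAD into NADH at a small fixed rate, which is
    precisely a net supply of reducing capacity, so one re-solve yields
    gamma_red = -(Z(probe) - Z(0)) / probe directly.  Used to classify grid
    points whose raw duals are degenerate.
    """
    if probe <= 0:
        raise ValueError("probe must be positive")
    if base_solution is None:
        base_solution = fba(model, config=config, check_degeneracy=False)
    if not base_solution.optimal:
        raise ValueError("base model FBA is not optimal")
    nadh = _match_cofactor(model, "nadh", compartment)
    nad = _match_cofactor(model, "nad", compartment)
    z1 = _probed_objective(model, {nad: -1.0, nadh: 1.0}, probe, config)
    value = -(z1 - base_solution.objective) / probe
    return AvailabilityVerdict(
        gamma_red=float(value),
        # difference quotients inherit ~ (solver tol / probe) noise
        classification=classify(value, eps=max(SIGN_EPS, 1e-5)),
        compartment=compartment,
        degenerate=False,
    )
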