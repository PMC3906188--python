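"""Reaction-deletion analyses: presets, pattern screens, coupled designs.

Four entry points mirror the strain-design workflow around the
reducing-capacity availability pattern:

* :func:`a_priori_presets` - the mechanistically motivated deletions
  (NDH1+AOX double, COX single) evaluated by phase-plane pattern and
  ethanol-envelope coupling.
* :func:`pattern_screen` - exhaustive screening of candidate deletion sets
  for the all-excess (Crabtree-positive) availability pattern, two-stage:
  a coarse grid screen, then fine-grid confirmation of survivors.
* :func:`growth_coupled_search` - a bounded best-first local search for
  deletion sets that couple a product to growth, iterating a minimum-growth
  ladder from 0.1 to 0.7 1/h; exhaustive single deletions are always
  evaluated first, and the search is deterministic (lexicographic
  tie-breaks).
* :func:`nadh_sink_variant` - the modified-model device: an artificial
  irreversible NADH drain plus a growth floor, biasing subsequent searches
  toward phenotypes that must compensate a low NADH availability.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from redoxplane.envelope import production_envelope
from redoxplane.fva_span import fva
from redoxplane.lp_engine import DEFAULT_CONFIG, SolverConfig, fba
from redoxplane.model_core import MetabolicModel, apply_deletions
from redoxplane.phaseplane import (
    ETHANOL_STEMS,
    ZERO_GROWTH_TOL,
    PatternSummary,
    availability_pattern,
    find_exchange,
    scan,
)
from redoxplane.shadow_redox import DEFAULT_COMPARTMENT, _match_cofactor

COUPLING_TOL = 1e-6

#: logical names of the a-priori deletion presets
A_PRIORI_PRESETS = (("NDH1_AOX", ("NDH1", "AOX")), ("COX", ("COX",)))

GROWTH_LADDER = tuple(round(0.1 * k, 1) for k in range(1, 8))  # 0.1 .. 0.7


@dataclass
class DeletionResult:
    """One deletion set with its growth, coupling and pattern evaluation."""

    deletion_set: tuple[str, ...]
    max_growth: float
    coupling: str | None  # coupled | non_coupled | None if not evaluated
    pattern: PatternSummary | None
    provenance: str  # a_priori | exhaustive_single | local_search | nadh_sink
    coupling_strength: float = 0.0  # min product flux at maximal growth

    def __post_init__(self) -> None:
        self.deletion_set = tuple(sorted(self.deletion_set))
        if len(self.deletion_set) < 1:
            raise ValueError("deletion_set must contain at least one reaction")


def a_priori_presets(
    model: MetabolicModel,
    id_map: dict | None = None,
    glc_range=(0.5, 10.0, 20),
    o2_range=(0.5, 15.0, 20),
    compartment: str = DEFAULT_COMPARTMENT,
    product_id: str | None = None,
    config: SolverConfig = DEFAULT_CONFIG,
) -> list[DeletionResult]:
    """Evaluate the mechanistic deletion presets on phase-plane pattern.

    ``id_map`` maps the logical names NDH1 / AOX / COX onto model-specific
    reaction ids (identity by default).  Presets whose ids cannot be
    resolved are skipped with a warning.
    """
    id_map = id_map or {}
    product_id = product_id or find_exchange(model, ETHANOL_STEMS)
    results = []
    for preset_name, logical_ids in A_PRIORI_PRESETS:
        try:
            rxn_ids = tuple(id_map.get(l, l) for l in logical_ids)
            deletant = apply_deletions(model, rxn_ids)
        except KeyError as exc:
            warnings.warn(
                f"preset {preset_name}: unresolvable reaction id ({exc}); skipped",
                stacklevel=2,
            )
            continue
        sol = fba(deletant, config=config, check_degeneracy=False)
        max_growth = sol.objective if sol.optimal else 0.0
        pattern = None
        coupling_verdict = None
        if sol.optimal and max_growth > ZERO_GROWTH_TOL:
            grid = scan(
                deletant,
                glc_range=glc_range,
                o2_range=o2_range,
                compartment=compartment,
                config=config,
            )
            try:
                pattern = availability_pattern(grid)
            except ValueError:
                pattern = None
            env = production_envelope(deletant, product_id, config=config)
            coupling_verdict = env.coupling
        results.append(
            DeletionResult(
                deletion_set=rxn_ids,
                max_growth=float(max_growth),
                coupling=coupling_verdict,
                pattern=pattern,
                provenance="a_priori",
            )
        )
    return results


def prune_candidates(
    model: MetabolicModel, config: SolverConfig = DEFAULT_CONFIG
) -> list[str]:
    """Deletion candidates: internal, non-biomass, nonzero span at reference.

    Exchanges, the biomass reaction and reactions whose flux span is zero at
    the reference state cannot change the optimum pattern and are dropped.
    """
    report = fva(model, config=config)
    out = []
    for j, rxn in enumerate(model.reactions):
        if model.exchange_mask[j] or rxn.id == model.objective_id:
            continue
        if report.span[j] < 1e-12 and abs(report.v_min[j]) < 1e-12:
            continue
        out.append(rxn.id)
    return out


def pattern_screen(
    model: MetabolicModel,
    candidates,
    min_growth: float = 0.0,
    max_set_size: int = 1,
    screen_grid: int = 8,
    confirm_grid: int = 20,
    glc_range=(0.5, 10.0),
    o2_range=(0.5, 15.0),
    compartment: str = DEFAULT_COMPARTMENT,
    config: SolverConfig = DEFAULT_CONFIG,
) -> list[DeletionResult]:
    """Find deletion sets producing the all-excess availability pattern.

    Every combination of ``candidates`` up to ``max_set_size`` is evaluated
    on a coarse ``screen_grid`` x ``screen_grid`` phase plane; sets showing
    ``all_excess_o2_limited`` with maximal growth >= ``min_growth`` are
    re-verified on the fine ``confirm_grid`` and only confirmed survivors
    are returned, sorted lexicographically.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("candidate list is empty")
    if min_growth < 0:
        raise ValueError("min_growth must be non-negative")
    survivors = []
    for size in range(1, max_set_size + 1):
        for combo in itertools.combinations(candidates, size):
            result = _evaluate_pattern(
                model, combo, min_growth, screen_grid,
                glc_range, o2_range, compartment, config,
            )
            if result is None or not result.pattern.all_excess_o2_limited:
                continue
            confirmed = _evaluate_pattern(
                model, combo, min_growth, confirm_grid,
                glc_range, o2_range, compartment, config,
            )
            if confirmed is not None and confirmed.pattern.all_excess_o2_limited:
                survivors.append(confirmed)
    return sorted(survivors, key=lambda r: r.deletion_set)


def _evaluate_pattern(
    model, combo, min_growth, steps, glc_range, o2_range, compartment, config
):
    try:
        deletant = apply_deletions(model, combo)
        sol = fba(deletant, config=config, check_degeneracy=False)
    except (KeyError, ValueError) as exc:
        warnings.warn(f"deletion {combo}: {exc}; skipped", stacklevel=2)
        return None
    if not sol.optimal or sol.objective < max(min_growth, ZERO_GROWTH_TOL):
        return None
    grid = scan(
        deletant,
        glc_range=(*glc_range, steps),
        o2_range=(*o2_range, steps),
        compartment=compartment,
        config=config,
    )
    try:
        pattern = availability_pattern(grid)
    except ValueError:
        return None
    return DeletionResult(
        deletion_set=combo,
        max_growth=float(sol.objective),
        coupling=None,
        pattern=pattern,
        provenance="exhaustive_single" if len(combo) == 1 else "local_search",
    )


# ---------------------------------------------------------------------------
# growth-coupled design search


def _coupling_strength(
    model: MetabolicModel,
    deletion_set,
    product_j: int,
    min_growth: float,
    config: SolverConfig,
) -> tuple[float, float]:
    """(min product flux at maximal growth, max growth); (-inf, 0) if unfit."""
    from redoxplane.lp_engine import _solve
    from redoxplane.envelope import GROWTH_PIN_TOL

    try:
        deletant = apply_deletions(model, deletion_set)
    except KeyError:
        return (-np.inf, 0.0)
    sol = fba(deletant, config=config, check_degeneracy=False)
    if not sol.optimal or sol.objective < min_growth - 1e-9:
        return (-np.inf, 0.0)
    jz = deletant.reaction_index(deletant.objective_id)
    lo = deletant.lower_bounds.copy()
    hi = deletant.upper_bounds.copy()
    lo[jz] = sol.objective - GROWTH_PIN_TOL
    hi[jz] = sol.objective + GROWTH_PIN_TOL
    c = np.zeros(deletant.n_reactions)
    c[product_j] = 1.0
    res = _solve(c, deletant.S, lo, hi, config, presolve=False)
    if res.status != 0:
        return (-np.inf, 0.0)
    return (float(res.fun), float(sol.objective))


def growth_coupled_search(
    model: MetabolicModel,
    product_id: str,
    max_deletions: int = 3,
    min_growth_ladder=GROWTH_LADDER,
    candidates=None,
    config: SolverConfig = DEFAULT_CONFIG,
) -> list[DeletionResult]:
    """Bounded local search for growth-coupled production deletion sets.

    For each growth floor in the ladder, all single deletions are scored by
    coupling strength (minimum product flux at maximal growth), then a
    best-first local search (neighbourhood: add or swap one deletion, up to
    ``max_deletions``) improves the incumbent.  All coupled sets discovered
    anywhere along the way are collected, de-duplicated and returned sorted
    lexicographically.  Fully deterministic.
    """
    if not 1 <= max_deletions <= 3:
        raise ValueError("max_deletions must be 1, 2 or 3")
    product_j = model.reaction_index(product_id)
    if candidates is None:
        candidates = prune_candidates(model, config=config)
    candidates = sorted(set(candidates))
    found: dict[tuple, DeletionResult] = {}

    def record(dset, strength, growth, provenance):
        key = tuple(sorted(dset))
        if strength > COUPLING_TOL and key not in found:
            found[key] = DeletionResult(
                deletion_set=key,
                max_growth=growth,
                coupling="coupled",
                pattern=None,
                provenance=provenance,
                coupling_strength=strength,
            )

    for floor in min_growth_ladder:
        scores = {}
        for rid in candidates:
            strength, growth = _coupling_strength(
                model, (rid,), product_j, floor, config
            )
            scores[(rid,)] = strength
            record((rid,), strength, growth, "exhaustive_single")
        incumbent = max(
            scores, key=lambda k: (scores[k], tuple(-ord(c) for c in k[0]))
        )
        if not np.isfinite(scores[incumbent]):
            continue
        best = scores[incumbent]
        improved = True
        while improved:
            improved = False
            neighbours = []
            if len(incumbent) < max_deletions:
                neighbours += [
                    tuple(sorted(incumbent + (r,)))
                    for r in candidates
                    if r not in incumbent
                ]
            for drop in incumbent:
                rest = tuple(x for x in incumbent if x != drop)
                neighbours += [
                    tuple(sorted(rest + (r,)))
                    for r in candidates
                    if r not in incumbent
                ]
            for nb in sorted(set(neighbours)):
                strength, growth = _coupling_strength(
                    model, nb, product_j, floor, config
                )
                record(nb, strength, growth, "local_search")
                if strength > best + 1e-9:
                    best = strength
                    incumbent = nb
                    improved = True
    return sorted(found.values(), key=lambda r: r.deletion_set)


def nadh_sink_variant(
    model: MetabolicModel,
    sink_range: tuple[float, float] = (0.1, 0.6),
    min_growth: float = 0.20,
    compartment: str = DEFAULT_COMPARTMENT,
    config: SolverConfig = DEFAULT_CONFIG,
) -> MetabolicModel:
    """Return a copy with an artificial irreversible NADH drain.

    The sink consumes NADH without regenerating NAD (a pure drain, not an
    oxidase) at a flux forced into ``sink_range``, and the biomass reaction
    gets a lower bound of ``min_growth``.  Raises if the variant is
    infeasible, reporting the maximal feasible sink flux.
    """
    lb, ub = sink_range
    if lb > ub or lb < 0:
        raise ValueError("sink_range must satisfy 0 <= lb <= ub")
    nadh = _match_cofactor(model, "nadh", compartment)
    variant = model.add_reaction(
        "NADH_SINK",
        {nadh: -1.0},
        lb,
        ub,
        name="artificial NADH sink (pure drain)",
    )
    jz = variant.reaction_index(variant.objective_id)
    variant.lower_bounds[jz] = min_growth
    sol = fba(variant, config=config, check_degeneracy=False)
    if not sol.optimal:
        probe = model.add_reaction(
            "NADH_SINK", {nadh: -1.0}, 0.0, ub, name="sink feasibility probe"
        )
        probe.lower_bounds[probe.reaction_index(probe.objective_id)] = min_growth
        probe.objective_coeffs[:] = 0.0
        probe.objective_coeffs[probe.reaction_index("NADH_SINK")] = 1.0
        psol = fba(probe, config=config, check_degeneracy=False)
        max_sink = psol.objective if psol.optimal else 0.0
        raise ValueError(
            f"NADH sink of at least {lb} infeasible at growth {min_growth}; "
            f"maximal feasible sink flux is {max_sink:.6g}"
        )
    return variant
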