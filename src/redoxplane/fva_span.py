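"""Flux variability analysis, flux spans and span-vs-oxygen profiles.

At the fixed FBA optimum every reaction flux is minimised and maximised;
the flux span ``v_max - v_min`` indexes how much freedom the network retains
at optimal growth.  Spans are binned as in the comparative analysis this
package implements:

    S1: span > 10       S2: 1 < span <= 10      S3: 0.01 <= span <= 1

with spans below 0.01 mmol gDW^-1 h^-1 excluded as numerically negligible.
A span profile repeats the analysis along an oxygen-uptake ladder at fixed
glucose uptake and reports an invariance metric: the largest relative
change of any bin count across the ladder (0 = perfectly invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from redoxplane.lp_engine import (
    DEFAULT_CONFIG,
    SolverConfig,
    _solve,
    fba,
    remove_loops,
)
from redoxplane.model_core import MetabolicModel, set_uptake
from redoxplane.phaseplane import (
    GLUCOSE_STEMS,
    OXYGEN_STEMS,
    ZERO_GROWTH_TOL,
    find_exchange,
    line_of_optimality,
)

GROWTH_PIN_TOL = 1e-9
SPAN_EXCLUDE = 0.01
BIN_EDGES = {"S3": (0.01, 1.0), "S2": (1.0, 10.0), "S1": (10.0, np.inf)}


def classify_spans(spans: np.ndarray) -> dict:
    """Bin counts for a span vector: S3=[0.01,1], S2=(1,10], S1=(10,inf)."""
    spans = np.asarray(spans, dtype=float)
    return {
        "S1": int((spans > 10.0).sum()),
        "S2": int(((spans > 1.0) & (spans <= 10.0)).sum()),
        "S3": int(((spans >= 0.01) & (spans <= 1.0)).sum()),
        "excluded": int((spans < 0.01).sum()),
    }


@dataclass
class FluxSpanReport:
    """Per-reaction (v_min, v_max, span) at fixed optimal growth."""

    reaction_ids: list[str]
    v_min: np.ndarray
    v_max: np.ndarray
    span: np.ndarray
    bin_counts: dict
    excluded_count: int
    context: dict = field(default_factory=dict)

    def span_of(self, rxn_id: str) -> float:
        return float(self.span[self.reaction_ids.index(rxn_id)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction": self.reaction_ids,
                "v_min": self.v_min,
                "v_max": self.v_max,
                "span": self.span,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    loopless: bool = False,
    config: SolverConfig = DEFAULT_CONFIG,
) -> FluxSpanReport:
    """Flux variability at ``fraction_of_optimum`` of maximal growth.

    At the default fraction 1.0 growth is pinned two-sidedly to Z*; lower
    fractions impose ``v_biomass >= fraction * Z*``.  With ``loopless`` each
    extreme flux vector is first stripped of internal cycles and the
    loop-free flux of the probed reaction is reported, which can only narrow
    spans.
    """
    if not 0.0 < fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    base = fba(model, config=config, check_degeneracy=False)
    if not base.optimal:
        raise ValueError(f"model {model.model_id!r} FBA is {base.status}")
    if base.objective <= ZERO_GROWTH_TOL:
        raise ValueError("FVA requires an optimum with Z* > 0")
    jz = model.reaction_index(model.objective_id)
    lo = model.lower_bounds.copy()
    hi = model.upper_bounds.copy()
    if fraction_of_optimum == 1.0:
        lo[jz] = base.objective - GROWTH_PIN_TOL
        hi[jz] = base.objective + GROWTH_PIN_TOL
    else:
        lo[jz] = fraction_of_optimum * base.objective

    pinned = model.copy()
    pinned.lower_bounds = lo
    pinned.upper_bounds = hi

    n = model.n_reactions
    vmin = np.empty(n)
    vmax = np.empty(n)
    c = np.zeros(n)
    for j in range(n):
        for sign, store in ((1.0, vmin), (-1.0, vmax)):
            c[j] = sign
            res = _solve(c, model.S, lo, hi, config, presolve=False)
            if res.status != 0:
                raise ArithmeticError(
                    f"FVA LP failed for reaction {model.reactions[j].id!r}"
                )
            value = float(res.x[j])
            if loopless and not model.exchange_mask[j]:
                value = _loop_free_value(pinned, res.x, j, config)
            store[j] = value
        c[j] = 0.0
    span = vmax - vmin
    span[np.abs(span) < 1e-12] = 0.0
    counts = classify_spans(span)
    return FluxSpanReport(
        reaction_ids=[r.id for r in model.reactions],
        v_min=vmin,
        v_max=vmax,
        span=span,
        bin_counts={k: counts[k] for k in ("S1", "S2", "S3")},
        excluded_count=counts["excluded"],
        context={
            "model_id": model.model_id,
            "objective": base.objective,
            "fraction_of_optimum": fraction_of_optimum,
            "loopless": loopless,
            "lower_bounds": {
                r.id: float(lb)
                for r, lb, ex in zip(model.reactions, model.lower_bounds, model.exchange_mask)
                if ex
            },
        },
    )


def _loop_free_value(pinned, x, j, config) -> float:
    from redoxplane.lp_engine import FBASolution

    sol = FBASolution(
        status="optimal",
        objective=float(x[pinned.reaction_index(pinned.objective_id)]),
        fluxes=np.asarray(x),
        duals=np.zeros(pinned.n_metabolites),
        reduced_costs=np.zeros(pinned.n_reactions),
        degenerate_flags=np.zeros(pinned.n_metabolites, dtype=bool),
        reaction_ids=[r.id for r in pinned.reactions],
        metabolite_ids=[m.id for m in pinned.metabolites],
        metabolite_compartments=[m.compartment for m in pinned.metabolites],
        model_id=pinned.model_id,
        config=config,
    )
    clean = remove_loops(pinned, sol, config=config)
    return float(clean.fluxes[j])


@dataclass
class SpanProfile:
    """Flux-span reports along an oxygen ladder at fixed glucose uptake."""

    o2_values: np.ndarray
    reports: list  # FluxSpanReport | None per oxygen value
    invariance_metric: float
    loo_o2: float
    glc_uptake: float
    model_id: str

    def bin_table(self) -> pd.DataFrame:
        rows = []
        for o2, rep in zip(self.o2_values, self.reports):
            row = {"o2": o2}
            row.update(rep.bin_counts if rep is not None else {"S1": None, "S2": None, "S3": None})
            rows.append(row)
        return pd.DataFrame(rows)


def invariance_metric(reports) -> float:
    """Largest relative change of any bin count across a profile.

    For each bin: (max - min) / max, with always-empty bins contributing 0.
    0 means the binned span structure is invariant along the ladder.
    """
    reports = [r for r in reports if r is not None]
    if not reports:
        raise ValueError("profile has no feasible points")
    worst = 0.0
    for b in ("S1", "S2", "S3"):
        counts = np.array([r.bin_counts[b] for r in reports], dtype=float)
        if counts.max() > 0:
            worst = max(worst, (counts.max() - counts.min()) / counts.max())
    return worst


def span_profile(
    model: MetabolicModel,
    glc_uptake: float = 10.0,
    o2_values=None,
    n_points: int = 8,
    loopless: bool = False,
    config: SolverConfig = DEFAULT_CONFIG,
    glucose_id: str | None = None,
    oxygen_id: str | None = None,
) -> SpanProfile:
    """Flux-span reports along an oxygen-uptake ladder at fixed glucose.

    Defaults to ``n_points`` evenly spaced oxygen uptakes from 0.5 to the
    line-of-optimality oxygen at the given glucose uptake.  Infeasible
    points are recorded as None and the profile continues.
    """
    glucose_id = glucose_id or find_exchange(model, GLUCOSE_STEMS)
    oxygen_id = oxygen_id or find_exchange(model, OXYGEN_STEMS)
    loo = float(
        line_of_optimality(
            model, [glc_uptake], config=config,
            oxygen_id=oxygen_id, glucose_id=glucose_id,
        )[0]
    )
    if o2_values is None:
        if not np.isfinite(loo):
            raise ValueError("cannot build default ladder: no line of optimality")
        o2_values = np.linspace(0.5, loo, n_points)
    o2_values = np.asarray(list(o2_values), dtype=float)
    if np.any(o2_values <= 0) or np.any(np.diff(o2_values) <= 0):
        raise ValueError("o2_values must be positive and strictly increasing")

    m_glc = set_uptake(model, glucose_id, glc_uptake)
    reports = []
    for o2 in o2_values:
        m = set_uptake(m_glc, oxygen_id, float(o2))
        try:
            rep = fva(m, loopless=loopless, config=config)
        except ValueError:
            rep = None
        if rep is not None:
            rep.context["o2_uptake"] = float(o2)
        reports.append(rep)
    return SpanProfile(
        o2_values=o2_values,
        reports=reports,
        invariance_metric=invariance_metric(reports),
        loo_o2=loo,
        glc_uptake=glc_uptake,
        model_id=model.model_id,
    )
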