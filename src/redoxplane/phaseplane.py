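"""Phenotypic phase planes over glucose x oxygen uptake space.

A scan solves one FBA per grid point with the two uptake bounds set to the
grid coordinates, records optimal growth, ethanol secretion and the
reducing-capacity verdict, and locates the line of optimality: for each
glucose uptake, the oxygen uptake of the loop-free optimum under unbounded
oxygen, i.e. the oxygen:glucose ratio of fully respiratory metabolism.
Points strictly left of that line (oxygen below it) are the oxygen-limited
phenotypes; the availability pattern summarises the sign of gamma_red over
them.  Points within one grid step of the line are excluded from pattern
statistics because the line itself is the degenerate locus of the duals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from redoxplane.lp_engine import DEFAULT_CONFIG, SolverConfig, fba, remove_loops
from redoxplane.model_core import MetabolicModel, set_uptake
from redoxplane.shadow_redox import (
    DEFAULT_COMPARTMENT,
    gamma_red,
    gamma_red_fd,
)

ZERO_GROWTH_TOL = 1e-6


def find_exchange(model: MetabolicModel, stems: tuple[str, ...]) -> str:
    """Exchange reaction whose metabolite id stem matches one of ``stems``."""
    for j in np.flatnonzero(model.exchange_mask):
        col = model.S.getcol(int(j)).tocoo()
        met = model.metabolites[int(col.row[0])]
        stem = met.id.lower()
        if met.compartment and stem.endswith("_" + met.compartment.lower()):
            stem = stem[: -len(met.compartment) - 1]
        if stem in stems:
            return model.reactions[int(j)].id
    raise KeyError(
        f"model {model.model_id!r} has no exchange for any of {stems}"
    )


GLUCOSE_STEMS = ("glc", "glc__d", "glc_d", "glucose")
OXYGEN_STEMS = ("o2", "oxygen")
ETHANOL_STEMS = ("eth", "etoh", "ethanol")


@dataclass
class PhasePlaneGrid:
    """Growth, ethanol and gamma_red verdicts over an uptake grid.

    Matrices are indexed ``[i_glc, j_o2]``.  ``loo`` is the per-glucose
    line-of-optimality oxygen uptake (NaN where growth is infeasible), and
    ``o2_limited`` marks feasible points strictly left of the line.
    """

    glc_axis: np.ndarray
    o2_axis: np.ndarray
    growth: np.ndarray
    ethanol: np.ndarray
    gamma_red_map: np.ndarray
    classification: np.ndarray
    degenerate: np.ndarray
    feasible: np.ndarray
    loo: np.ndarray
    o2_limited: np.ndarray
    compartment: str
    model_id: str

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, glc in enumerate(self.glc_axis):
            for j, o2 in enumerate(self.o2_axis):
                rows.append(
                    {
                        "glc": glc,
                        "o2": o2,
                        "growth": self.growth[i, j],
                        "ethanol": self.ethanol[i, j],
                        "gamma_red": self.gamma_red_map[i, j],
                        "classification": self.classification[i, j],
                        "feasible": bool(self.feasible[i, j]),
                        "o2_limited": bool(self.o2_limited[i, j]),
                        "loo_o2": self.loo[i],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                json.loads(self.to_dataframe().to_json(orient="records")),
                fh,
                indent=1,
            )

    @property
    def o2_step(self) -> float:
        return float(self.o2_axis[1] - self.o2_axis[0])


@dataclass(frozen=True)
class PatternSummary:
    """Sign statistics of gamma_red over the oxygen-limited phenotypes."""

    fraction_excess: float
    all_excess_o2_limited: bool
    subset_excess: bool
    n_o2_limited: int
    n_excess: int
    n_limiting: int


def line_of_optimality(
    model: MetabolicModel,
    glc_values,
    config: SolverConfig = DEFAULT_CONFIG,
    oxygen_id: str | None = None,
    glucose_id: str | None = None,
) -> np.ndarray:
    """Optimal oxygen uptake per glucose uptake (unbounded-oxygen optimum).

    The loop-free optimum is used so redundant oxidase cycling does not
    inflate the reported oxygen demand.  Entries are NaN where growth is
    infeasible or zero.
    """
    glucose_id = glucose_id or find_exchange(model, GLUCOSE_STEMS)
    oxygen_id = oxygen_id or find_exchange(model, OXYGEN_STEMS)
    out = np.full(len(list(glc_values)), np.nan)
    for i, glc in enumerate(glc_values):
        if glc < 0:
            raise ValueError("glucose uptake magnitudes must be non-negative")
        m = set_uptake(model, glucose_id, glc)
        m = set_uptake(m, oxygen_id, "unbounded")
        sol = fba(m, config=config, check_degeneracy=False)
        if not sol.optimal or sol.objective <= ZERO_GROWTH_TOL:
            continue
        clean = remove_loops(m, sol, config=config)
        out[i] = -clean.flux(oxygen_id)
    return out


def scan(
    model: MetabolicModel,
    glc_range: tuple[float, float, int] = (0.5, 10.0, 20),
    o2_range: tuple[float, float, int] = (0.5, 15.0, 20),
    compartment: str = DEFAULT_COMPARTMENT,
    config: SolverConfig = DEFAULT_CONFIG,
    glucose_id: str | None = None,
    oxygen_id: str | None = None,
    ethanol_id: str | None = None,
) -> PhasePlaneGrid:
    """Phenotypic phase plane with gamma_red verdicts at every grid point.

    Grid points whose duals are flagged degenerate are re-classified with
    the finite-difference probe, so phase boundaries get robust verdicts.
    Infeasible or zero-growth points are marked infeasible.
    """
    for rng in (glc_range, o2_range):
        if len(rng) != 3 or rng[2] < 2 or not rng[1] > rng[0]:
            raise ValueError(
                "ranges must be (min, max, steps) with steps >= 2 and max > min"
            )
    glucose_id = glucose_id or find_exchange(model, GLUCOSE_STEMS)
    oxygen_id = oxygen_id or find_exchange(model, OXYGEN_STEMS)
    ethanol_id = ethanol_id or find_exchange(model, ETHANOL_STEMS)

    glc_axis = np.linspace(*glc_range)
    o2_axis = np.linspace(*o2_range)
    shape = (len(glc_axis), len(o2_axis))
    growth = np.full(shape, np.nan)
    ethanol = np.full(shape, np.nan)
    gmap = np.full(shape, np.nan)
    cls = np.full(shape, "infeasible", dtype=object)
    degen = np.zeros(shape, dtype=bool)
    feasible = np.zeros(shape, dtype=bool)

    loo = line_of_optimality(
        model, glc_axis, config=config, oxygen_id=oxygen_id, glucose_id=glucose_id
    )

    for i, glc in enumerate(glc_axis):
        m_glc = set_uptake(model, glucose_id, glc)
        for j, o2 in enumerate(o2_axis):
            m = set_uptake(m_glc, oxygen_id, o2)
            sol = fba(m, config=config)
            if not sol.optimal or sol.objective <= ZERO_GROWTH_TOL:
                continue
            feasible[i, j] = True
            growth[i, j] = sol.objective
            clean = remove_loops(m, sol, config=config)
            ethanol[i, j] = clean.flux(ethanol_id)
            verdict = gamma_red(sol, compartment)
            if verdict.degenerate:
                verdict = gamma_red_fd(
                    m, compartment, config=config, base_solution=sol
                )
                degen[i, j] = True
            gmap[i, j] = verdict.gamma_red
            cls[i, j] = verdict.classification

    o2_limited = feasible & (o2_axis[None, :] < np.nan_to_num(loo, nan=-np.inf)[:, None])
    return PhasePlaneGrid(
        glc_axis=glc_axis,
        o2_axis=o2_axis,
        growth=growth,
        ethanol=ethanol,
        gamma_red_map=gmap,
        classification=cls,
        degenerate=degen,
        feasible=feasible,
        loo=loo,
        o2_limited=o2_limited,
        compartment=compartment,
        model_id=model.model_id,
    )


def availability_pattern(grid: PhasePlaneGrid) -> PatternSummary:
    """Summarise gamma_red signs over the oxygen-limited phenotypes.

    Points within one oxygen grid step of the line of optimality are
    excluded (degenerate locus).  ``all_excess_o2_limited`` is the
    operational definition of the Crabtree-positive availability pattern;
    ``subset_excess`` (some but not all points in excess) of the
    Crabtree-negative one.
    """
    mask = grid.o2_limited & (
        grid.o2_axis[None, :]
        < np.nan_to_num(grid.loo, nan=-np.inf)[:, None] - grid.o2_step
    )
    n = int(mask.sum())
    if n == 0:
        raise ValueError("grid has no feasible oxygen-limited points")
    n_excess = int((grid.classification[mask] == "excess").sum())
    n_limiting = int((grid.classification[mask] == "limiting").sum())
    frac = n_excess / n
    return PatternSummary(
        fraction_excess=frac,
        all_excess_o2_limited=frac == 1.0,
        subset_excess=0.0 < frac < 1.0,
        n_o2_limited=n,
        n_excess=n_excess,
        n_limiting=n_limiting,
    )
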