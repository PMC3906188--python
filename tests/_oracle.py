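"""Independent brute-force LP oracle for the toy models.

Enumerates every basic feasible solution (vertex) of {S v = 0, l <= v <= u}
by fixing each choice of n - rank(S) variables at a bound and solving the
remaining square (or overdetermined) linear system.  Completely independent
of the HiGHS-based engine under test: pure linear algebra, no LP solver.

Only usable for models with a handful of reactions; the bundled toys are
well inside that envelope.
"""

from __future__ import annotations

import itertools

import numpy as np

FEAS_TOL = 1e-7


def enumerate_vertices(model) -> tuple[np.ndarray, np.ndarray]:
    """All vertices of the flux polytope; returns (V, objectives).

    V has one row per vertex.  Duplicate vertices are removed.
    """
    S = np.asarray(model.S.todense(), dtype=float)
    lo = model.lower_bounds
    hi = model.upper_bounds
    m, n = S.shape
    r = np.linalg.matrix_rank(S, tol=1e-9)
    vertices = []
    for nonbasic in itertools.combinations(range(n), n - r):
        basic = [j for j in range(n) if j not in nonbasic]
        SB = S[:, basic]
        bound_choices = []
        for j in nonbasic:
            bound_choices.append((lo[j],) if lo[j] == hi[j] else (lo[j], hi[j]))
        for fixed in itertools.product(*bound_choices):
            rhs = -S[:, list(nonbasic)] @ np.asarray(fixed)
            vB, residual, rank, _ = np.linalg.lstsq(SB, rhs, rcond=None)
            if np.linalg.norm(SB @ vB - rhs, ord=np.inf) > FEAS_TOL:
                continue
            v = np.empty(n)
            v[basic] = vB
            v[list(nonbasic)] = fixed
            if np.any(v < lo - FEAS_TOL) or np.any(v > hi + FEAS_TOL):
                continue
            vertices.append(v)
    if not vertices:
        return np.empty((0, n)), np.empty(0)
    V = np.unique(np.round(np.asarray(vertices), 9), axis=0)
    return V, V @ model.objective_coeffs


def brute_force_fba(model) -> float:
    """Optimal objective by exhaustive vertex enumeration; NaN if infeasible."""
    _, objs = enumerate_vertices(model)
    return float(objs.max()) if objs.size else float("nan")


def brute_force_fva(model, tol: float = 1e-6):
    """Per-reaction (min, max) flux over the optimal face, via vertices."""
    V, objs = enumerate_vertices(model)
    if not objs.size:
        raise ValueError("infeasible model")
    best = objs.max()
    opt = V[objs >= best - tol]
    return opt.min(axis=0), opt.max(axis=0)


def brute_force_o2_at_optimum(model, o2_index: int, tol: float = 1e-6) -> float:
    """Smallest oxygen uptake magnitude among optimal vertices."""
    V, objs = enumerate_vertices(model)
    best = objs.max()
    opt = V[objs >= best - tol]
    return float(np.abs(opt[:, o2_index]).min())


def brute_force_max_flux_at_growth(
    model, rxn_index: int, growth: float, tol: float = 1e-6
) -> float:
    """Max flux of one reaction over vertices with pinned growth value."""
    V, objs = enumerate_vertices(model)
    sel = V[np.abs(objs - growth) <= tol]
    if not sel.size:
        raise ValueError(f"no vertex with growth {growth}")
    return float(sel[:, rxn_index].max())
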