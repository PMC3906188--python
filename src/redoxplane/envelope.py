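"""Production envelopes and growth-coupling classification.

A production envelope fixes growth at a ladder of values between zero and
the optimum Z* and minimises/maximises a product secretion flux at each
value, projecting the flux polytope onto the (growth, product) plane.  The
product is growth-coupled when its minimum at maximal growth is positive:
the network then cannot grow optimally without secreting it, the flux
signature of overflow metabolism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from redoxplane.lp_engine import DEFAULT_CONFIG, SolverConfig, _solve, fba
from redoxplane.model_core import MetabolicModel

GROWTH_PIN_TOL = 1e-9
COUPLING_TOL = 1e-6


@dataclass
class ProductionEnvelope:
    """min/max product flux along a growth ladder from 0 to Z*."""

    growth_points: np.ndarray
    min_product: np.ndarray
    max_product: np.ndarray
    product_id: str
    model_id: str

    @property
    def max_growth(self) -> float:
        return float(self.growth_points[-1])

    @property
    def coupling(self) -> str:
        return coupling(self)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "growth": self.growth_points,
                "min_product": self.min_product,
                "max_product": self.max_product,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def production_envelope(
    model: MetabolicModel,
    product_id: str,
    n_points: int = 20,
    config: SolverConfig = DEFAULT_CONFIG,
) -> ProductionEnvelope:
    """Compute the product-vs-growth envelope at ``n_points`` growth values.

    Growth is pinned with a two-sided 1e-9 band at each ladder value so the
    minimum product flux is well defined at Z* even on a degenerate optimal
    face.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    jp = model.reaction_index(product_id)
    jz = model.reaction_index(model.objective_id)
    base = fba(model, config=config, check_degeneracy=False)
    if not base.optimal:
        raise ValueError(f"base model {model.model_id!r} FBA is {base.status}")
    zmax = base.objective

    if model.lower_bounds[jp] == 0 and model.upper_bounds[jp] == 0:
        warnings.warn(
            f"product {product_id!r} has zero bounds; envelope is all zero",
            stacklevel=2,
        )

    growth_points = np.linspace(0.0, zmax, n_points)
    lo = model.lower_bounds.copy()
    hi = model.upper_bounds.copy()
    vmin = np.empty(n_points)
    vmax = np.empty(n_points)
    c = np.zeros(model.n_reactions)
    for k, z in enumerate(growth_points):
        lo[jz] = z - GROWTH_PIN_TOL
        hi[jz] = z + GROWTH_PIN_TOL
        for sign, store in ((1.0, vmin), (-1.0, vmax)):
            c[jp] = sign
            res = _solve(c, model.S, lo, hi, config, presolve=False)
            if res.status != 0:
                raise ArithmeticError(
                    f"envelope LP failed at growth {z:.6g} (status {res.status})"
                )
            store[k] = sign * res.fun if sign > 0 else -res.fun
        c[jp] = 0.0
    return ProductionEnvelope(
        growth_points=growth_points,
        min_product=vmin,
        max_product=vmax,
        product_id=product_id,
        model_id=model.model_id,
    )


def coupling(envelope: ProductionEnvelope) -> str:
    """``"coupled"`` iff the product minimum at maximal growth is positive."""
    return (
        "coupled"
        if envelope.min_product[-1] > COUPLING_TOL
        else "non_coupled"
    )
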