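"""Deterministic toy yeast models with explicit NAD(H) bookkeeping.

Two small stoichiometric models emulate the qualitative redox physiology of
a Crabtree-positive yeast (``toy_cerevisiae``, TOY-SC) and a
Crabtree-negative pentose-fermenting yeast (``toy_stipitis``, TOY-SS), so
that the full analysis pipeline - shadow prices, phase planes, envelopes,
flux spans, deletion screens - is testable end to end without any
genome-scale download.  The generators are pure functions of their
:class:`ToySpec`: no randomness, bit-identical output on every call.

TOY-SC (Crabtree-positive pattern)
    Lumped glycolysis, fermentation to ethanol, a capacity-bounded glycerol
    shunt, lumped TCA, a P/O=1.5 respiratory chain and a biomass drain that
    consumes pyruvate, ATP and a little NADH.  Built so that ethanol
    production couples to growth under a binding oxygen bound, reducing
    capacity is in excess at every feasible oxygen-limited phenotype, and
    the count of small flux spans rises at low oxygen.

TOY-SS (Crabtree-negative pattern)
    Adds the mechanisms reported for efficient NAD(H) recycling: a
    mitochondrial NAD pool fed by the TCA cycle, a ubiquinone pool with a
    proton-translocating complex I (NDH1, site-1 ATP), a cytochrome path
    (COX, downstream ATP) and a non-phosphorylating alternative oxidase
    (AOX); an external NADH dehydrogenase (NDE) oxidising cytosolic NADH at
    lower ATP yield; an ATP-coupled transhydrogenation route (THD) turning
    cytosolic NADH into NADPH; a capacity-bounded polyol shunt; a lumped
    pentose-phosphate pathway as second NADPH source; and a biomass drain
    consuming NADPH instead of NADH, plus a maintenance ATP demand.  The
    interplay of the maintenance load (ATP-bound at low oxygen => excess)
    with the NADPH demand (transhydrogenation-bound near the line of
    optimality => limiting) yields excess reducing capacity only in a
    low-oxygen sub-region, and deleting the transhydrogenase (alone or with
    AOX and the polyol shunt) flips the model to the all-excess pattern.

All coefficients below are frozen calibration constants; the four headline
qualitative contrasts between the two toys are this module's contract and
are asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from redoxplane.model_core import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

GLC_UPTAKE_DEFAULT = 10.0  # mmol gDW^-1 h^-1, the flux-span reference uptake


@dataclass(frozen=True)
class ToySpec:
    """Calibration constants for one toy model.

    po_ratio
        ATP per NADH oxidised by the (lumped or cytochrome-path) respiratory
        chain; complex I adds ``ndh1_atp`` on top in TOY-SS.
    biomass_stoich
        mmol of pyruvate / ATP / NAD(P)H consumed per gDW of biomass; the
        redox key is ``"nadh"`` for TOY-SC and ``"nadph"`` for TOY-SS.
    redox_options
        The NAD(H)-recycling mechanisms: ``aox``, ``thd_bypass``,
        ``polyol_sink``.  All false for TOY-SC, all true for TOY-SS.
    maintenance_atp
        Growth-independent ATP drain (lower bound of ATPM), mmol gDW^-1 h^-1.
    """

    po_ratio: float = 1.5
    biomass_stoich: dict = field(
        default_factory=lambda: {"pyruvate": 30.0, "atp": 100.0, "nadh": 5.0}
    )
    redox_options: dict = field(
        default_factory=lambda: {"aox": False, "thd_bypass": False, "polyol_sink": False}
    )
    maintenance_atp: float = 0.0
    ndh1_atp: float = 1.0  # site-1 proton pumping, TOY-SS only
    thd_atp_cost: float = 1.0  # ATP per NADH transhydrogenated, TOY-SS only
    sink_cap: float = 0.05  # capacity of glycerol / polyol / AOX shunts
    nad_incorporation: float = 0.1  # NAD(H) built into biomass, mmol/gDW
    nad_synthesis_atp: float = 0.2  # ATP per NAD synthesised de novo

    def validate(self) -> None:
        if self.po_ratio <= 0:
            raise ValueError("po_ratio must be positive")
        if any(v <= 0 for v in self.biomass_stoich.values()):
            raise ValueError("all biomass coefficients must be positive")
        if self.maintenance_atp < 0:
            raise ValueError("maintenance_atp must be non-negative")


SC_SPEC = ToySpec()
SS_SPEC = ToySpec(
    biomass_stoich={"pyruvate": 10.0, "atp": 30.0, "nadph": 40.0},
    redox_options={"aox": True, "thd_bypass": True, "polyol_sink": True},
    maintenance_atp=10.0,
)


def _build(model_id: str, mets: list[tuple[str, str, str]], rxns: list[dict]) -> MetabolicModel:
    metabolites = [Metabolite(i, n, c) for i, n, c in mets]
    met_index = {m.id: k for k, m in enumerate(metabolites)}
    reactions, lbs, ubs, objs = [], [], [], []
    rows, cols, vals = [], [], []
    for j, r in enumerate(rxns):
        reactions.append(
            Reaction(r["id"], r.get("name", r["id"]), r["lb"] < 0, r.get("subsystem", ""))
        )
        lbs.append(r["lb"])
        ubs.append(r["ub"])
        objs.append(r.get("objective", 0.0))
        for met, coeff in r["stoich"].items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coeff))
    S = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(reactions))
    )
    return MetabolicModel(
        model_id=model_id,
        metabolites=metabolites,
        reactions=reactions,
        S=S,
        lower_bounds=np.array(lbs, dtype=float),
        upper_bounds=np.array(ubs, dtype=float),
        objective_coeffs=np.array(objs, dtype=float),
    )


def toy_cerevisiae(spec: ToySpec = SC_SPEC) -> MetabolicModel:
    """TOY-SC: single-compartment Crabtree-positive toy (~12 reactions)."""
    spec.validate()
    if any(spec.redox_options.values()):
        raise ValueError("TOY-SC requires all redox_options false")
    if "nadh" not in spec.biomass_stoich:
        raise ValueError("TOY-SC biomass must consume nadh")
    a = spec.biomass_stoich["pyruvate"]
    b = spec.biomass_stoich["atp"]
    c = spec.biomass_stoich["nadh"]
    po = spec.po_ratio
    B = DEFAULT_BOUND

    mets = [
        ("glc_c", "D-glucose", "c"),
        ("pyr_c", "pyruvate", "c"),
        ("eth_c", "ethanol", "c"),
        ("glyc_c", "glycerol", "c"),
        ("co2_c", "carbon dioxide", "c"),
        ("o2_c", "oxygen", "c"),
        ("atp_c", "ATP", "c"),
        ("nadh_c", "NADH", "c"),
        ("nad_c", "NAD+", "c"),
    ]
    rxns = [
        dict(id="EX_glc", name="glucose exchange", stoich={"glc_c": -1}, lb=-GLC_UPTAKE_DEFAULT, ub=B),
        dict(id="EX_o2", name="oxygen exchange", stoich={"o2_c": -1}, lb=-B, ub=B),
        dict(id="EX_eth", name="ethanol exchange", stoich={"eth_c": -1}, lb=0, ub=B),
        dict(id="EX_glyc", name="glycerol exchange", stoich={"glyc_c": -1}, lb=0, ub=B),
        dict(id="EX_co2", name="CO2 exchange", stoich={"co2_c": -1}, lb=0, ub=B),
        dict(
            id="GLYCOLYSIS",
            name="lumped glycolysis",
            stoich={"glc_c": -1, "nad_c": -2, "pyr_c": 2, "nadh_c": 2, "atp_c": 2},
            lb=0, ub=B, subsystem="glycolysis",
        ),
        dict(
            id="FERM",
            name="pyruvate fermentation to ethanol",
            stoich={"pyr_c": -1, "nadh_c": -1, "eth_c": 1, "co2_c": 1, "nad_c": 1},
            lb=0, ub=B, subsystem="fermentation",
        ),
        dict(
            id="GLYCEROL",
            name="glycerol shunt (capacity-bounded redox sink)",
            stoich={"pyr_c": -1, "nadh_c": -1, "glyc_c": 1, "nad_c": 1},
            lb=0, ub=spec.sink_cap, subsystem="fermentation",
        ),
        dict(
            id="TCA",
            name="lumped TCA cycle",
            stoich={"pyr_c": -1, "nad_c": -4, "co2_c": 3, "nadh_c": 4, "atp_c": 1},
            lb=0, ub=B, subsystem="TCA",
        ),
        dict(
            id="RESP",
            name=f"respiratory chain (P/O {po})",
            stoich={"nadh_c": -1, "o2_c": -0.5, "nad_c": 1, "atp_c": po},
            lb=0, ub=B, subsystem="oxidative phosphorylation",
        ),
        dict(
            id="BIOMASS",
            name="biomass drain",
            # c NADH are oxidised back to NAD by anabolism; d more NAD(H)
            # are incorporated into biomass, the pool's physiological sink
            stoich={
                "pyr_c": -a,
                "atp_c": -b,
                "nadh_c": -(c + spec.nad_incorporation),
                "nad_c": c,
            },
            lb=0, ub=B, objective=1.0, subsystem="biomass",
        ),
        dict(
            id="NADSYN",
            name="NAD de novo synthesis (lumped, ATP cost)",
            stoich={"atp_c": -spec.nad_synthesis_atp, "nad_c": 1},
            lb=0, ub=B, subsystem="cofactor synthesis",
        ),
        dict(
            id="ATPM",
            name="ATP maintenance",
            stoich={"atp_c": -1},
            lb=spec.maintenance_atp, ub=B, subsystem="maintenance",
        ),
    ]
    return _build("TOY-SC", mets, rxns)


def toy_stipitis(spec: ToySpec = SS_SPEC) -> MetabolicModel:
    """TOY-SS: two-pool Crabtree-negative toy with a branched chain."""
    spec.validate()
    if not all(spec.redox_options.values()):
        raise ValueError("TOY-SS requires all redox_options true")
    if "nadph" not in spec.biomass_stoich:
        raise ValueError("TOY-SS biomass must consume nadph")
    a = spec.biomass_stoich["pyruvate"]
    b = spec.biomass_stoich["atp"]
    c = spec.biomass_stoich["nadph"]
    po = spec.po_ratio
    B = DEFAULT_BOUND

    mets = [
        ("glc_c", "D-glucose", "c"),
        ("pyr_c", "pyruvate", "c"),
        ("eth_c", "ethanol", "c"),
        ("polyol_c", "polyol (arabitol/ribitol pool)", "c"),
        ("co2_c", "carbon dioxide", "c"),
        ("o2_c", "oxygen", "c"),
        ("atp_c", "ATP", "c"),
        ("nadh_c", "NADH (cytosol)", "c"),
        ("nad_c", "NAD+ (cytosol)", "c"),
        ("nadph_c", "NADPH", "c"),
        ("nadh_m", "NADH (mitochondrion)", "m"),
        ("nad_m", "NAD+ (mitochondrion)", "m"),
        ("q_m", "ubiquinone", "m"),
        ("qh2_m", "ubiquinol", "m"),
    ]
    rxns = [
        dict(id="EX_glc", name="glucose exchange", stoich={"glc_c": -1}, lb=-GLC_UPTAKE_DEFAULT, ub=B),
        dict(id="EX_o2", name="oxygen exchange", stoich={"o2_c": -1}, lb=-B, ub=B),
        dict(id="EX_eth", name="ethanol exchange", stoich={"eth_c": -1}, lb=0, ub=B),
        dict(id="EX_polyol", name="polyol exchange", stoich={"polyol_c": -1}, lb=0, ub=B),
        dict(id="EX_co2", name="CO2 exchange", stoich={"co2_c": -1}, lb=0, ub=B),
        dict(
            id="GLYCOLYSIS",
            name="lumped glycolysis",
            stoich={"glc_c": -1, "nad_c": -2, "pyr_c": 2, "nadh_c": 2, "atp_c": 2},
            lb=0, ub=B, subsystem="glycolysis",
        ),
        dict(
            id="PPP",
            name="lumped pentose phosphate pathway",
            stoich={
                "glc_c": -1,
                "nad_c": -5.0 / 3.0,
                "nadph_c": 2,
                "co2_c": 1,
                "pyr_c": 5.0 / 3.0,
                "nadh_c": 5.0 / 3.0,
                "atp_c": 2.0 / 3.0,
            },
            lb=0, ub=B, subsystem="pentose phosphate",
        ),
        dict(
            id="FERM",
            name="pyruvate fermentation to ethanol",
            stoich={"pyr_c": -1, "nadh_c": -1, "eth_c": 1, "co2_c": 1, "nad_c": 1},
            lb=0, ub=B, subsystem="fermentation",
        ),
        dict(
            id="POLYOL",
            name="polyol shunt (capacity-bounded redox sink)",
            stoich={"pyr_c": -1, "nadh_c": -1, "polyol_c": 1, "nad_c": 1},
            lb=0, ub=spec.sink_cap, subsystem="fermentation",
        ),
        dict(
            id="THD",
            name="ATP-coupled NADH->NADPH transhydrogenation (TCA bypass)",
            stoich={
                "nadh_c": -1,
                "atp_c": -spec.thd_atp_cost,
                "nad_c": 1,
                "nadph_c": 1,
            },
            lb=0, ub=B, subsystem="redox bypass",
        ),
        dict(
            id="TCA",
            name="lumped TCA cycle (mitochondrial NAD pool)",
            stoich={"pyr_c": -1, "nad_m": -4, "co2_c": 3, "nadh_m": 4, "atp_c": 1},
            lb=0, ub=B, subsystem="TCA",
        ),
        dict(
            id="NDH1",
            name="proton-translocating NADH dehydrogenase (complex I)",
            stoich={"nadh_m": -1, "q_m": -1, "nad_m": 1, "qh2_m": 1, "atp_c": spec.ndh1_atp},
            lb=0, ub=B, subsystem="oxidative phosphorylation",
        ),
        dict(
            id="NDE",
            name="external (cytosolic-facing) NADH dehydrogenase",
            stoich={"nadh_c": -1, "q_m": -1, "nad_c": 1, "qh2_m": 1},
            lb=0, ub=B, subsystem="oxidative phosphorylation",
        ),
        dict(
            id="COX",
            name=f"cytochrome path, ubiquinol oxidase (P/O {po})",
            stoich={"qh2_m": -1, "o2_c": -0.5, "q_m": 1, "atp_c": po},
            lb=0, ub=B, subsystem="oxidative phosphorylation",
        ),
        dict(
            id="AOX",
            name="alternative oxidase (non-phosphorylating)",
            stoich={"qh2_m": -1, "o2_c": -0.5, "q_m": 1},
            lb=0, ub=spec.sink_cap, subsystem="oxidative phosphorylation",
        ),
        dict(
            id="BIOMASS",
            name="biomass drain (NADPH-consuming)",
            stoich={
                "pyr_c": -a,
                "atp_c": -b,
                "nadph_c": -c,
                "nadh_c": -spec.nad_incorporation,
            },
            lb=0, ub=B, objective=1.0, subsystem="biomass",
        ),
        dict(
            id="NADSYN",
            name="NAD de novo synthesis (lumped, ATP cost)",
            stoich={"atp_c": -spec.nad_synthesis_atp, "nad_c": 1},
            lb=0, ub=B, subsystem="cofactor synthesis",
        ),
        dict(
            id="NADTM",
            name="mitochondrial NAD+ transporter (oxidised form only)",
            stoich={"nad_c": -1, "nad_m": 1},
            lb=-B, ub=B, subsystem="transport",
        ),
        dict(
            id="ATPM",
            name="ATP maintenance",
            stoich={"atp_c": -1},
            lb=spec.maintenance_atp, ub=B, subsystem="maintenance",
        ),
    ]
    return _build("TOY-SS", mets, rxns)


#: the NADH-recycling routes whose deletion flips TOY-SS to the
#: Crabtree-positive availability pattern (the transhydrogenase alone
#: suffices; AOX and the polyol shunt are included for symmetry with the
#: a-priori reasoning about recycling mechanisms)
SS_RECYCLING_SET = ("AOX", "THD", "POLYOL")

#: a-priori deletion preset names resolvable on TOY-SS
SS_PRESET_IDS = {"NDH1": "NDH1", "AOX": "AOX", "COX": "COX"}
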