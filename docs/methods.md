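# Methods

## Model and objective

All analyses operate on stoichiometric models at steady state: find fluxes
`v` maximising the biomass flux `Z = c'v` subject to `S v = 0` and bounds
`l <= v <= u` (mmol gDW⁻¹ h⁻¹; the biomass column in h⁻¹). Exchange columns
follow the BiGG convention — one negative entry per column, negative flux is
uptake — and quoted uptake rates are magnitudes applied as negative lower
bounds, with 1000 standing in for "unbounded" (large enough never to bind in
any regime analysed here).

The LP solver is HiGHS via `scipy.optimize.linprog`, single-threaded with
primal/dual feasibility tolerances of 1e-9 and deterministic behaviour; the
resolved solver configuration is recorded in every solution object. HiGHS's
presolve mis-declares infeasibility when a bound band is as tight as the
feasibility tolerance, so all solves that pin a flux to a value (growth
fixed to `Z*` ± 1e-9 in envelopes, FVA and loop removal) run with presolve
disabled.

## Shadow prices and the reducing-capacity price γ_red

The shadow price γᵢ of metabolite *i* is the metabolite's mass-balance dual,
re-signed as the negative growth sensitivity to a small external supply of
*i*: γᵢ < 0 means supplying *i* raises growth (limiting), γᵢ > 0 means the
network would grow faster with *less* of it (excess). The composite

    γ_red = γ_NADH − γ_NAD

is the growth sensitivity to a net supply of reducing equivalents into one
NAD(H) pool: supplying NADH while withdrawing NAD is exactly a transfer of
reducing capacity, so γ_red is measurable by a *single* probe reaction
NAD → NADH. Classification uses ε = 1e-6 (excess above, limiting below,
neutral otherwise); finite-difference classifications use ε = 1e-5 because
difference quotients inherit solver noise of order (tolerance / probe).

Which compartment's pool γ_red refers to is a genuine choice in
multi-compartment models. The default is the cytosolic pair, because the
cytosolic redox state drives the glycolysis/fermentation branch point that
the whole analysis is about; `gamma_red_by_compartment` reports every
compartment so the choice is auditable.

**Degeneracy.** LP duals are non-unique exactly where phase planes change
basis, i.e. on the phase boundaries. Every FBA solve can therefore flag its
duals: the problem is re-solved twice under a deterministic ±1e-7 bound
jitter (relaxed and tightened — the two perturbations land on opposite sides
of a kink) and any metabolite whose dual moves by more than 1e-4 is marked
degenerate. Degenerate verdicts defer to the finite-difference probe
(`verify_fd` / `gamma_red_fd`): a temporary supply reaction with flux fixed
to 1e-3 mmol gDW⁻¹ h⁻¹ and a one-sided difference quotient. The probe
magnitude balances staying within one LP basis against numerical noise and
is configurable.

A one-sided supply probe is only feasible if the pool it feeds has a
physiological sink. Metabolites of strictly conserved internal pools (the
ubiquinone pair in the Crabtree-negative toy) admit no such probe; the probe
then reports infeasibility rather than a number, and the property tests
assert exactly that.

## Loop removal

Thermodynamically infeasible cycles carry no net exchange flux, so they can
be stripped *after* optimisation: with every exchange flux and the objective
pinned to their optimal values, the L1 norm of internal fluxes is minimised
(one extra LP with split auxiliary variables). This preserves `Z` and every
exchange to 1e-6 while collapsing futile cycles. It replaces mixed-integer
loop-law formulations deliberately: MILP duals are undefined, and the shadow
prices this package exists for require a well-posed LP dual. Duals are
therefore always taken from the plain LP and flux vectors may optionally be
loop-removed. The loopless FVA option applies the same post-process to each
variability extreme and can only narrow spans.

## Phase planes, line of optimality, availability pattern

A scan solves one FBA per point of a glucose × oxygen uptake grid (default
20 × 20 over (0.5–10) × (0.5–15) for the toys). The line of optimality at a
glucose uptake is the oxygen uptake of the *loop-removed* optimum under
unbounded oxygen — the oxygen:glucose ratio of fully respiratory metabolism;
loop removal matters here because redundant oxidase cycling would otherwise
inflate the oxygen demand. "Oxygen-limited" is geometric: strictly left of
the line. Pattern statistics additionally exclude points within one grid
step of the line, which is the degenerate locus; zero-growth points are
treated as infeasible because a growth sensitivity is meaningless at Z = 0.
The pattern summary reports the excess fraction over oxygen-limited points;
all-excess is the operational Crabtree-positive pattern, a strict subset the
Crabtree-negative one.

## Envelopes, coupling, flux spans

Production envelopes fix growth at 20 evenly spaced values in [0, Z*] with a
two-sided 1e-9 band (so the product minimum is well defined on a degenerate
optimal face) and minimise/maximise the product flux. A product is
growth-coupled when its minimum at maximal growth exceeds 1e-6.

FVA fixes growth at 100% of Z* (the flux range "at the same optimal biomass
production"; the fraction is configurable) and min/maximises every reaction.
Spans are binned S1 (> 10), S2 (1–10], S3 [0.01–1]; spans below 0.01 are
excluded as numerically negligible. Bin-edge assignment (S3 closed, S2/S1
half-open) is this package's decision. A span profile repeats FVA along
eight oxygen uptakes from 0.5 to the line-of-optimality oxygen at glucose
uptake 10; its invariance metric is max over bins of (max − min)/max of the
count, 0 for a perfectly invariant binned structure.

## Deletion analyses

Deletions are reaction-level (bounds pinned to zero); no gene–protein
mapping is attempted. The pattern screen evaluates candidate sets on a
coarse 8 × 8 grid and re-verifies survivors on the 20 × 20 grid; candidates
are pruned to internal, non-biomass reactions with nonzero span at the
reference state, which provably cannot be pattern-relevant otherwise. The
growth-coupled design search replaces a bilevel MILP formulation with a
documented stand-in: exhaustive single-deletion scoring (objective: minimum
product flux at maximal growth) followed by best-first local search
(add/swap one deletion, ≤ 3 total) iterated over a minimum-growth ladder
0.1–0.7 h⁻¹ in steps of 0.1, with lexicographic tie-breaking — fully
deterministic, and verified equal to exhaustive ≤3-subset enumeration on the
toy models. The NADH-sink modified model adds an irreversible pure drain
(NADH consumed, nothing produced — deliberately *not* an oxidase, which
would regenerate NAD) with flux forced into [0.1, 0.6] and a growth floor of
0.20 h⁻¹, biasing subsequent screens toward phenotypes that must compensate
scarce NADH.

## The synthetic toy models

The two generators are pure functions of a frozen `ToySpec`; they emulate
the *qualitative* redox physiology needed to exercise every pipeline stage,
not the numbers of any genome-scale reconstruction.

**TOY-SC** (Crabtree-positive): lumped glycolysis (2 ATP, 2 NADH, 2 pyruvate
per glucose), fermentation, a capacity-bounded glycerol shunt (0.05), lumped
TCA (4 NADH + 1 ATP per pyruvate), a P/O = 1.5 chain, and a biomass drain
consuming 30 pyruvate + 100 ATP + 5 NADH (oxidised back) + 0.1 NAD(H)
incorporated. Solving its vertex structure by hand shows the oxygen-limited
strip splits into an ATP-slack and an ATP-binding phase, and in *both* the
response to extra NADH is negative for these coefficients — excess
everywhere left of the line, with ethanol coupling under a binding oxygen
bound.

**TOY-SS** (Crabtree-negative): during design it became clear that a single
closed NADH/NAD pool cannot produce a *limiting* verdict at an
oxygen-binding optimum in any basis — when oxygen is marginally valuable,
oxidising NADH is marginally good, so a one-pool model is always in (weak)
excess there. The published subset pattern needs compartment structure, and
TOY-SS therefore carries the minimal version: a mitochondrial NAD pool fed
by TCA, a ubiquinone pool with proton-translocating complex I (NDH1, +1 ATP),
a cytochrome path (COX, +1.5 ATP per ubiquinol) and a capacity-bounded
non-phosphorylating alternative oxidase (AOX); an external NADH
dehydrogenase (NDE) oxidising cytosolic NADH at the lower yield; an
ATP-coupled transhydrogenation route (THD: NADH + 1 ATP → NAD + NADPH,
standing for the energy-linked NADH→NADPH bypass); a lumped pentose
phosphate pathway as second NADPH source; a polyol shunt; biomass consuming
10 pyruvate + 30 ATP + 40 NADPH; and 10 mmol gDW⁻¹ h⁻¹ maintenance ATP.

The pattern mechanism is then transparent: at low oxygen the maintenance
load keeps ATP binding, transhydrogenation costs scarce ATP (its cost of 1
exceeding the 2/3 ATP-per-glucose advantage of glycolysis over the PPP
route), and extra cytosolic NADH is a burden — excess. Nearer the line of
optimality ATP runs into slack, oxygen's marginal value shifts to carbon
oxidation (TCA disposes of surplus pyruvate without consuming cytosolic
NADH, sparing it for transhydrogenation to NADPH), and extra NADH then buys
NADPH — limiting. Deleting THD (alone, or with AOX and the polyol shunt)
removes the route that makes cytosolic NADH growth-useful, flipping the
model to the all-excess pattern; the NADPH supply survives through the PPP,
which is what keeps the flip mutant viable. The biomass NAD(H) incorporation
(0.1) plus an ATP-costing NAD synthesis reaction give the pools their
physiological turnover, which is also what makes single-metabolite supply
probes feasible.

What the toys do **not** emulate: realistic yields or growth rates,
xylose metabolism, proton/charge balancing, gene–reaction mapping, and the
thousands-of-reactions redundancy of genome-scale models. Passing the toy
suite therefore demonstrates correctness of the *methods* (duals, scans,
envelopes, spans, screens) on networks where every verdict is independently
checkable — by vertex enumeration, finite differences and a second solver
stack — not quantitative agreement with any published reconstruction.

## Problem sizes and determinism

Default sizes are chosen so the full toy pipeline stays interactive: 20 × 20
phase planes (≈ 1400 LPs with degeneracy probes), 8-point span profiles,
8 × 8 screening grids with 20 × 20 confirmation, 20-point envelopes. The
entire four-contrast suite is ≈ 2000 small LPs. Every stage is deterministic
for a fixed solver configuration; the only randomness anywhere is the seeded
drawing of uptake settings in the verification sweeps.

## Known limitations

- Shadow prices come from one optimal basis; the degeneracy flag plus
  finite-difference fallback mitigates but does not abolish dual
  non-uniqueness (one-sided probes measure a subgradient at kinks).
- The L1 post-process is not a full loop-law: it cannot exclude loop-carried
  flux from the *variability* bounds themselves, only from reported vectors.
- The local search is bounded, not exhaustive; equivalence with enumeration
  is asserted on the toys only.
- Genome-scale runs (iBB814/iMM904) are supported by the loaders and the
  pipeline but require the third-party model files, which are not bundled.
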